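"""Permutation null, sensitivity adjustment, enrichment and p-values."""

import itertools

import numpy as np
import pandas as pd
import pytest

import scmosaic as sm
from scmosaic import enrichment as en
from scmosaic import regions as rg
from scmosaic import callsets as cs
from scmosaic import synthetic_data as sd
from conftest import make_reference, small_config


def _toy_regionset(ref, boundaries):
    """Categorical regions splitting the genome at given global boundaries."""
    mask = rg.full_mask(ref)
    rows = []
    prev = 0
    for i, b in enumerate(list(boundaries) + [ref.total_length]):
        rows.append(("chr1", prev, b, f"r{i}"))
        prev = b
    ann = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    return rg.categorical_regions(ann, mask)


class TestAdjustAndNormalize:
    def test_unit_sensitivity_is_identity(self):
        obs = pd.Series([10.0, 20.0], index=["a", "b"])
        out = en.adjust_and_normalize(obs, pd.Series(1.0, index=obs.index))
        assert np.allclose(out["corrected"], obs)

    def test_worked_example(self):
        obs = pd.Series([50.0, 50.0], index=["a", "b"])
        W = pd.Series([0.5, 1.0], index=obs.index)
        out = en.adjust_and_normalize(obs, W)
        assert np.allclose(out["A"], [100.0, 50.0])
        assert np.allclose(out["corrected"], [200.0 / 3, 100.0 / 3])

    def test_total_is_conserved_for_any_sensitivity(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = rng.integers(2, 12)
            obs = pd.Series(rng.integers(0, 200, n).astype(float))
            W = pd.Series(rng.uniform(0.05, 1.0, n))
            out = en.adjust_and_normalize(obs, W)
            assert out["corrected"].sum() == pytest.approx(obs.sum(), abs=1e-9)

    def test_zero_sensitivity_with_observations_rejected(self):
        obs = pd.Series([5.0], index=["a"])
        with pytest.raises(ValueError):
            en.adjust_and_normalize(obs, pd.Series([0.0], index=["a"]))


def _snv_calls(ref, positions, cell="c1"):
    seq = ref.seqs["chr1"]
    rows = []
    for p in positions:
        r = chr(seq[p - 1])
        a = {"A": "G", "C": "T", "G": "A", "T": "C"}[r]
        rows.append(("chr1", p, r, a, cell, "i1", "SNV", "vaf"))
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "cell", "individual", "variant_class", "mode"]
    )
    return cs.annotate_channels(df, ref)


class TestPermutationNull:
    def _ref(self, n_kb=4):
        rng = np.random.default_rng(7)
        return make_reference("".join(rng.choice(list("ACGT"), n_kb * 1000)))

    def test_single_eligible_site_always_chosen(self):
        ref = self._ref()
        calls = _snv_calls(ref, [1500])
        key = en._call_keys(calls, "SNV")[0]
        elig = en.EligibleSites({int(key): np.array([1499])}, np.array([1499]))
        rs = _toy_regionset(ref, [2000])
        null = en.permute_calls(calls, rs, elig, n_iterations=50, seed=1)
        assert (null.counts[:, 0] == 1).all() and (null.counts[:, 1] == 0).all()

    def test_channel_spectrum_preserved_every_iteration(self):
        ref = self._ref()
        calls = _snv_calls(ref, [101, 502, 1203, 2504, 3105])
        elig = en.EligibleSites.snv_sites(ref)
        rs = _toy_regionset(ref, [2000])
        null = en.permute_calls(
            calls, rs, elig, n_iterations=40, seed=2, collect_channels=True
        )
        want = np.bincount(calls["sbs96_channel"], minlength=96)
        for it in range(null.n_iterations):
            got = null.channel_counts[it].sum(axis=0)
            assert (got == want).all()

    def test_counts_match_multinomial_expectation(self):
        ref = self._ref(n_kb=10)
        rng = np.random.default_rng(3)
        calls = _snv_calls(ref, sorted(rng.choice(np.arange(100, 9900), 60, replace=False)))
        elig = en.EligibleSites.snv_sites(ref)
        rs = _toy_regionset(ref, [3000, 7000])
        n_iter = 4000
        null = en.permute_calls(calls, rs, elig, n_iterations=n_iter, seed=4)
        expected = en.expected_null_counts(calls, rs, elig)
        total = null.counts.sum(axis=0)
        for r in range(3):
            mu = expected.iloc[r] * n_iter
            sd = np.sqrt(n_iter * expected.iloc[r])  # Poisson-scale bound
            assert abs(total[r] - mu) <= 4 * sd

    def test_exact_null_matches_exhaustive_enumeration(self):
        """On a toy genome with <=5 mutations, the analytic null mean (and
        hence the enrichment ratio) equals brute-force enumeration over all
        context-matching placements to 1e-12."""
        ref = self._ref(n_kb=2)
        calls = _snv_calls(ref, [151, 502, 903, 1204, 1555])
        rs = _toy_regionset(ref, [1000])
        elig = en.EligibleSites.snv_sites(ref)
        keys = en._call_keys(calls, "SNV")
        site_lists = [elig.sites_for(int(k))[:6] for k in keys]  # cap for enumeration
        capped = en.EligibleSites(
            {int(k): s for k, s in zip(keys, site_lists)}, elig.fallback
        )
        # brute force: every combination of placements, mean count per region
        n_reg = len(rs.ids)
        totals = np.zeros(n_reg)
        n_comb = 0
        for combo in itertools.product(*site_lists):
            codes = rs.region_of_global(np.array(combo))
            for c in codes[codes >= 0]:
                totals[c] += 1
            n_comb += 1
        brute = totals / n_comb
        analytic = en.expected_null_counts(calls, rs, capped)
        assert np.allclose(analytic.to_numpy(), brute, atol=1e-12)
        corrected = pd.Series([3.0, 2.0], index=rs.ids)
        ok = brute > 0
        E_analytic = (corrected / analytic).to_numpy()[ok]
        E_brute = corrected.to_numpy()[ok] / brute[ok]
        assert np.allclose(E_analytic, E_brute, atol=1e-12)


class TestEnrichmentAndP:
    def _null(self, rng, n_iter=2000, mu=(50, 100)):
        counts = np.column_stack([rng.poisson(m, n_iter) for m in mu])
        return en.PermutationNull(["a", "b"], counts)

    def test_corrected_equal_to_null_mean_gives_unit_enrichment(self):
        rng = np.random.default_rng(5)
        null = self._null(rng)
        corrected = pd.Series(null.mean(), index=["a", "b"])
        res = en.enrichment_and_p(corrected, null)
        assert np.allclose(res["enrichment"], 1.0)

    def test_p_floored_at_reciprocal_iterations(self):
        rng = np.random.default_rng(6)
        null = self._null(rng, n_iter=10_000)
        res = en.enrichment_and_p(pd.Series([500.0, 100.0], index=["a", "b"]), null)
        assert res.loc["a", "p"] == pytest.approx(1.0 / 10_000)

    def test_zero_null_mean_rejected(self):
        null = en.PermutationNull(["a"], np.zeros((10, 1), dtype=int))
        with pytest.raises(ValueError):
            en.enrichment_and_p(pd.Series([1.0], index=["a"]), null)


def _study(seed, detection=None, region_bias=None, n_cells=2, age=60.0):
    cfg = small_config(
        seed=seed, simulate_indels=False, germline_spacing=300,
        cohort=[sd.CohortEntry("X1", age, {"OL": n_cells})],
    )
    if detection:
        cfg.detection = detection
    if region_bias:
        cfg.region_bias = region_bias
    bundle = sm.generate_reference(cfg)
    cohort = sm.generate_cohort_calls(cfg, bundle)
    ref = bundle.reference
    mask = rg.full_mask(ref)
    win = rg.tile_1kb(mask)
    vals = rg.map_quantitative(bundle.tracks["covA"], win, ref)
    rs = rg.quantile_bins(vals, mask, n_bins=10)
    elig = en.EligibleSites.snv_sites(ref, mask)
    calls = cs.annotate_channels(cohort.calls, ref)
    return cfg, bundle, cohort, calls, rs, elig


class TestPipelineProperties:
    def test_mutagenesis_bias_detected_after_correction(self):
        """1.5x mutagenesis in one decile, uniform detection: corrected
        enrichment lands in [1.4, 1.6] with >= 2,000 mutations."""
        cfg, bundle, cohort, calls, rs, elig = _study(
            seed=51, region_bias={6: 1.5}, n_cells=3, age=80.0
        )
        assert len(calls) >= 2000
        res = en.enrichment_analysis(
            calls, cohort.germline, cohort.profiles, rs, elig,
            bundle.reference, n_iterations=1500, seed=9,
        )
        assert 1.4 <= res.loc[6, "enrichment"] <= 1.6

    def test_detection_bias_removed_by_correction(self):
        """Halved detection in one decile, uniform mutagenesis: corrected
        enrichment is consistent with 1 while uncorrected is ~0.5."""
        det = sd.DetectionModel(baseline=0.8, rescue_fraction=0.2,
                                region_multipliers={3: 0.5})
        cfg, bundle, cohort, calls, rs, elig = _study(
            seed=52, detection=det, n_cells=3, age=80.0
        )
        res = en.enrichment_analysis(
            calls, cohort.germline, cohort.profiles, rs, elig,
            bundle.reference, n_iterations=1500, seed=10,
        )
        assert res.loc[3, "uncorrected_enrichment"] == pytest.approx(0.52, abs=0.08)
        assert res.loc[3, "p"] > 0.05  # inside the 95% permutation band
        assert abs(res.loc[3, "enrichment"] - 1.0) < 0.1


class TestSignatureExposureEnrichment:
    def test_empty_region_has_zero_exposures(self):
        from scmosaic.signatures import synthetic_sbs_catalog

        cfg, bundle, cohort, calls, _, elig = _study(seed=53)
        ref = bundle.reference
        # 3-quantile regions; drop all calls from region 1 beforehand
        mask = rg.full_mask(ref)
        win = rg.tile_1kb(mask)
        vals = rg.map_quantitative(bundle.tracks["covA"], win, ref)
        rs3 = rg.quantile_bins(vals, mask, n_bins=3)
        keep = rg.assign_regions(calls, rs3, ref) != 1
        res = en.signature_exposure_enrichment(
            calls[keep], synthetic_sbs_catalog(), rs3, elig, ref,
            n_iterations=50, seed=11,
        )
        r1 = res[res["region"] == 1]
        assert (r1["exposure"] == 0).all()
        assert r1["low_count"].all()

    def test_permuted_exposures_sum_to_permuted_counts(self):
        from scmosaic.signatures import synthetic_sbs_catalog, fit_exposures

        cfg, bundle, cohort, calls, _, elig = _study(seed=54)
        ref = bundle.reference
        mask = rg.full_mask(ref)
        win = rg.tile_1kb(mask)
        vals = rg.map_quantitative(bundle.tracks["covA"], win, ref)
        rs3 = rg.quantile_bins(vals, mask, n_bins=3)
        null = en.permute_calls(
            calls[calls["mode"] == "vaf"], rs3, elig, n_iterations=5, seed=12,
            collect_channels=True,
        )
        catalog = synthetic_sbs_catalog()
        for it in range(null.n_iterations):
            for r in range(3):
                spec = null.channel_counts[it, r].astype(float)
                exp, resid = fit_exposures(spec, catalog)
                assert exp.sum() <= spec.sum() + resid + 1e-6
                assert abs(exp.sum() - spec.sum()) <= resid + 0.05 * spec.sum() + 1e-6
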