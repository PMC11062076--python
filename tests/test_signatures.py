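"""Spectra, NNLS exposure fitting and exposure aging."""

import numpy as np
import pandas as pd
import pytest

import scmosaic as sm
from scmosaic import signatures as sg
from scmosaic import callsets as cs
from conftest import make_reference


class TestCatalogs:
    @pytest.mark.parametrize("factory", [sg.synthetic_sbs_catalog, sg.synthetic_id_catalog])
    def test_columns_are_unit_distributions(self, factory):
        cat = factory()
        assert np.allclose(cat.matrix.sum(axis=0), 1.0, atol=1e-9)
        assert (cat.matrix >= 0).all()

    def test_catalog_tsv_round_trip(self, tmp_path):
        cat = sg.synthetic_sbs_catalog()
        p = tmp_path / "cat.tsv"
        cat.to_frame().to_csv(p, sep="\t")
        loaded = sg.load_catalog(p, kind="SBS96")
        assert loaded.names == cat.names
        assert np.allclose(loaded.matrix, cat.matrix)


class TestBuildSpectrum:
    def _ref_and_calls(self, n=10):
        ref = make_reference("GACGT" * 40)
        rows = [("chr1", 8, "C", "T", "c1", "i1", "SNV", "vaf") for _ in range(n)]
        calls = pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "cell", "individual",
                           "variant_class", "mode"]
        )
        return ref, cs.annotate_channels(calls, ref)

    def test_identical_calls_fill_one_channel_scaled_to_burden(self):
        ref, calls = self._ref_and_calls(10)
        spec = sg.build_spectrum(calls, kind="SBS96", scale=2.0)
        assert spec.values.sum() == pytest.approx(20.0)
        assert (spec.values > 0).sum() == 1

    def test_rescue_calls_excluded(self):
        ref, calls = self._ref_and_calls(10)
        calls.loc[:4, "mode"] = "rescue"
        spec = sg.build_spectrum(calls, kind="SBS96", scale=1.0)
        assert spec.values.sum() == pytest.approx(5.0)

    def test_id83_correction_divides_channels(self):
        ref = make_reference("GATGG" * 20)
        rows = [("chr1", 2, "AT", "A", "c1", "i1", "indel", "vaf") for _ in range(8)]
        calls = cs.annotate_channels(
            pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "cell",
                                        "individual", "variant_class", "mode"]),
            ref,
        )
        ident = sg.build_spectrum(calls, kind="ID83", scale=1.0)
        corr = np.ones(83)
        ch = int(calls["id83_channel"][0])
        corr[ch] = 0.5
        halved = sg.build_spectrum(calls, kind="ID83", scale=1.0, id83_correction=corr)
        assert halved.values[ch] == pytest.approx(2 * ident.values[ch])

    def test_nonpositive_scale_rejected(self):
        ref, calls = self._ref_and_calls()
        with pytest.raises(ValueError):
            sg.build_spectrum(calls, kind="SBS96", scale=0.0)


class TestFitExposures:
    def test_pure_signature_recovered_exactly(self):
        cat = sg.synthetic_sbs_catalog()
        exp, resid = sg.fit_exposures(100 * cat.column("SBS16"), cat)
        assert exp["SBS16"] == pytest.approx(100.0, rel=1e-9)
        assert exp.drop("SBS16").abs().max() < 1e-9
        assert resid < 1e-9

    def test_zero_spectrum_gives_zero_exposures(self):
        cat = sg.synthetic_sbs_catalog()
        exp, resid = sg.fit_exposures(np.zeros(96), cat)
        assert (exp == 0).all() and resid == 0

    def test_noisy_mixture_recovered_within_five_percent(self):
        cat = sg.synthetic_sbs_catalog()
        truth = 6000 * cat.column("SBS5") + 4000 * cat.column("SBS1")
        rng = np.random.default_rng(0)
        est = np.zeros(2)
        n_seeds = 20
        for _ in range(n_seeds):
            exp, _ = sg.fit_exposures(rng.poisson(truth).astype(float), cat)
            est += [exp["SBS5"], exp["SBS1"]]
        est /= n_seeds
        assert est[0] == pytest.approx(6000, rel=0.05)
        assert est[1] == pytest.approx(4000, rel=0.05)

    def test_matches_brute_force_grid_on_two_signatures(self):
        cat_full = sg.synthetic_sbs_catalog()
        cat = sg.SignatureCatalog(
            ["SBS1", "SBS16"],
            np.column_stack([cat_full.column("SBS1"), cat_full.column("SBS16")]),
        )
        rng = np.random.default_rng(1)
        spec = rng.poisson(30 * cat.column("SBS1") + 70 * cat.column("SBS16") + 0.2).astype(float)
        exp, _ = sg.fit_exposures(spec, cat)
        total = spec.sum()
        step = 0.01 * total
        grid = np.arange(0, 2 * total, step)
        best, best_err = None, np.inf
        for x1 in grid:
            # inner coordinate solved on the same grid
            for x2 in grid[:120]:
                err = np.linalg.norm(spec - x1 * cat.matrix[:, 0] - x2 * cat.matrix[:, 1])
                if err < best_err:
                    best, best_err = (x1, x2), err
        assert abs(exp.iloc[0] - best[0]) <= step
        assert abs(exp.iloc[1] - best[1]) <= step

    def test_complete_catalog_noiseless_mixture_conserves_mass(self):
        cat = sg.synthetic_sbs_catalog()
        weights = np.array([10.0, 20.0, 5.0, 40.0, 25.0])
        spec = cat.matrix @ weights
        exp, resid = sg.fit_exposures(spec, cat)
        assert exp.sum() == pytest.approx(spec.sum(), abs=1e-9)


class TestCosine:
    def test_self_similarity_is_one(self):
        v = np.arange(96, dtype=float)
        assert sg.cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        a, b = np.zeros(96), np.zeros(96)
        a[:10] = 1
        b[20:30] = 1
        assert sg.cosine_similarity(a, b) == 0.0

    def test_closed_form_example(self):
        a, b = np.zeros(96), np.zeros(96)
        a[:2] = 1.0
        b[0] = 1.0
        assert sg.cosine_similarity(a, b) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_flagged_as_zero(self):
        assert sg.cosine_similarity(np.zeros(96), np.ones(96)) == 0.0

    def test_kind_mismatch_rejected(self):
        s1 = sg.Spectrum("SBS96", np.ones(96))
        s2 = sg.Spectrum("ID83", np.ones(83))
        with pytest.raises(ValueError):
            sg.cosine_similarity(s1, s2)


class TestExposureAging:
    def _profiles(self, ages, cells_per=2):
        rows = []
        for i, age in enumerate(ages):
            for k in range(cells_per):
                rows.append(
                    {"cell": f"i{i}_c{k}", "individual": f"i{i}", "age": age,
                     "cell_type": "OL", "outlier": "none"}
                )
        return pd.DataFrame(rows)

    def test_exactly_linear_exposures_recovered_exactly(self):
        prof = self._profiles([5, 25, 45, 65, 85])
        expo = pd.DataFrame(
            {"SBSx": 10 + 2.5 * prof["age"].to_numpy()}, index=prof["cell"]
        )
        models = sg.exposure_aging(expo, prof)
        assert models["SBSx"].slope["OL"] == pytest.approx(2.5, abs=1e-6)

    def test_zero_rate_signature_ci_covers_zero(self):
        rng = np.random.default_rng(2)
        prof = self._profiles([5, 25, 45, 65, 85], cells_per=3)
        expo = pd.DataFrame({"SBSy": rng.normal(50, 5, len(prof))}, index=prof["cell"])
        m = sg.exposure_aging(expo, prof)["SBSy"]
        lo, hi = m.slope_ci["OL"]
        assert lo <= 0.0 <= hi


def test_transcribed_strand_bias_detects_planted_asymmetry():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), 20_000))
    ref = make_reference(seq)
    genes = pd.DataFrame(
        {"chrom": ["chr1"] * 2, "start": [1000, 11_000], "end": [9000, 19_000],
         "name": ["g1", "g2"], "strand": ["+", "+"]}
    )
    # plant T>C mutations with ref T (on '+' genes: untranscribed strand)
    rows = []
    for cell in range(8):
        t_pos = [p for p in rng.integers(1001, 9000, 400) if seq[p - 1] == "T"][:30]
        for p in t_pos:
            rows.append(("chr1", int(p), "T", "C", f"c{cell}", "i1", "SNV", "vaf"))
    calls = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "cell", "individual",
                       "variant_class", "mode"]
    )
    p, per_cell = sg.transcribed_strand_bias(calls, genes)
    assert p < 0.01
    assert per_cell[False].sum() > 0 and per_cell.get(True, pd.Series(0)).sum() == 0
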