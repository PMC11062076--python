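"""Generator contracts: determinism, construction invariants and
statistical calibration of the synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

import scmosaic as sm
from scmosaic import synthetic_data as sd
from conftest import small_config


class TestReference:
    def test_same_seed_gives_byte_identical_fasta(self, tmp_path):
        cfg = small_config(seed=3)
        b1 = sm.generate_reference(cfg)
        b2 = sm.generate_reference(small_config(seed=3))
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        b1.reference.to_fasta(p1)
        b2.reference.to_fasta(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_chromosome_count_and_length(self):
        cfg = small_config(seed=1, genome_length=500_000, n_chromosomes=2)
        b = sm.generate_reference(cfg)
        assert b.reference.lengths == {"chr1": 500_000, "chr2": 500_000}

    def test_gene_fraction_near_target(self):
        cfg = small_config(seed=2, gene_fraction=0.4)
        b = sm.generate_reference(cfg)
        covered = (b.genes["end"] - b.genes["start"]).sum()
        frac = covered / b.reference.total_length
        assert 0.35 <= frac <= 0.45

    def test_tracks_cover_genome_and_are_positive(self, bundle_small):
        for name, tr in bundle_small.tracks.items():
            assert (tr["value"] > 0).all()
            assert (tr["end"] - tr["start"]).sum() == bundle_small.reference.total_length

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError):
            sm.generate_reference(small_config(genome_length=50_000))


class TestCohort:
    def test_determinism_of_calls(self, bundle_small):
        c1 = sm.generate_cohort_calls(small_config(), bundle_small)
        c2 = sm.generate_cohort_calls(small_config(), bundle_small)
        pd.testing.assert_frame_equal(c1.calls, c2.calls)
        pd.testing.assert_frame_equal(c1.profiles, c2.profiles)

    def test_flat_aging_recovers_intercept(self, bundle_small):
        cfg = small_config(seed=21, simulate_indels=False)
        cfg.aging_snv = {ct: sd.AgingParams(0.0, 100.0, 0.0) for ct in ("OL", "neuron")}
        cohort = sm.generate_cohort_calls(cfg, bundle_small)
        tb = cohort.truth["true_burden"]
        n = len(tb)
        se = np.sqrt(100.0 / n)
        assert abs(tb["true_snv"].mean() - 100.0) <= 3 * se

    def test_detection_thinning_matches_binomial(self, bundle_small):
        cfg = small_config(seed=22, simulate_indels=False)
        cfg.detection = sd.DetectionModel(baseline=0.5, rescue_fraction=0.0)
        cohort = sm.generate_cohort_calls(cfg, bundle_small)
        n_true = cohort.truth["true_burden"]["true_snv"].sum()
        n_obs = len(cohort.calls)
        se = np.sqrt(0.25 * n_true)
        assert abs(n_obs - 0.5 * n_true) <= 3 * se

    def test_observed_calls_subset_of_truth(self, cohort_small, reference_small):
        ref = reference_small
        for cell, grp in cohort_small.calls[cohort_small.calls["variant_class"] == "SNV"].groupby("cell"):
            gpos = ref.to_global(grp["chrom"].to_numpy(), grp["pos"].to_numpy())
            truth = set(cohort_small.truth["true_positions"][cell]["SNV"])
            assert set(gpos) <= truth

    def test_germline_controls_density_and_flags(self, cohort_small):
        g = cohort_small.germline
        assert set(g["variant_class"]) == {"SNV", "indel"}
        assert (~g.loc[~g["passes_min_depth"], "called"]).all()

    def test_rescue_fraction_splits_modes(self, bundle_small):
        cfg = small_config(seed=23, simulate_indels=False)
        cfg.detection = sd.DetectionModel(baseline=0.9, rescue_fraction=0.3)
        cohort = sm.generate_cohort_calls(cfg, bundle_small)
        frac = (cohort.calls["mode"] == "rescue").mean()
        se = np.sqrt(0.3 * 0.7 / len(cohort.calls))
        assert abs(frac - 0.3) <= 4 * se

    def test_lineage_pair_truth_has_exact_shared_burden(self, bundle_small):
        cfg = small_config(seed=24, simulate_indels=False)
        cfg.lineage_pairs = [sd.LineagePair("S2", 263)]
        cohort = sm.generate_cohort_calls(cfg, bundle_small)
        (pair_key,) = cohort.truth["shared_sets"].keys()
        assert len(cohort.truth["shared_sets"][pair_key]) == 263

    def test_unknown_individual_in_lineage_pair_rejected(self):
        cfg = small_config()
        cfg.lineage_pairs = [sd.LineagePair("nobody", 10)]
        with pytest.raises(ValueError, match="unknown individual"):
            cfg.validate()

    def test_detection_probability_bounds_enforced(self):
        cfg = small_config()
        cfg.detection = sd.DetectionModel(baseline=0.6, region_multipliers={1: 2.0})
        with pytest.raises(ValueError, match="detection probability"):
            cfg.validate()

    def test_region_detection_calibration(self, bundle_small):
        """Empirical detection per covariate decile matches configuration."""
        cfg = small_config(seed=25, simulate_indels=False)
        cfg.detection = sd.DetectionModel(
            baseline=0.6, rescue_fraction=0.0, region_multipliers={2: 0.5, 9: 1.2}
        )
        cohort = sm.generate_cohort_calls(cfg, bundle_small)
        ref = bundle_small.reference
        det_mult = cohort.truth["window_detection_multiplier"]
        obs_g = {
            cell: set(ref.to_global(g["chrom"].to_numpy(), g["pos"].to_numpy()))
            for cell, g in cohort.calls.groupby("cell")
        }
        for mult in (0.5, 1.0, 1.2):
            n_true = n_obs = 0
            for cell, pos in cohort.truth["true_positions"].items():
                gpos = pos["SNV"]
                sel = det_mult[gpos // 1000] == mult
                n_true += sel.sum()
                n_obs += sum(1 for g in gpos[sel] if g in obs_g.get(cell, set()))
            p = 0.6 * mult
            se = np.sqrt(p * (1 - p) * n_true)
            assert abs(n_obs - p * n_true) <= 3 * se, mult


class TestTumors:
    def _config(self, **model_kw):
        cfg = small_config(seed=31, simulate_indels=False)
        cfg.tumor_model = {"T1": sd.TumorTypeModel(**model_kw)}
        return cfg

    def test_no_hypermutators_all_within_fence(self, bundle_small):
        cfg = self._config(n_samples=30, mean_burden=500, hypermutator_fraction=0.0)
        cat = sm.generate_tumor_catalog(cfg, bundle_small)
        counts = cat.groupby("sample").size().to_numpy()
        q1, q3 = np.percentile(counts, [25, 75])
        assert counts.max() <= q3 + 1.5 * (q3 - q1)

    def test_hypermutators_exceed_fence(self, bundle_small):
        cfg = self._config(
            n_samples=50, mean_burden=500, hypermutator_fraction=0.1, hypermutator_fold=20
        )
        cat = sm.generate_tumor_catalog(cfg, bundle_small)
        counts = cat.groupby("sample").size()
        q1, q3 = np.percentile(counts, [25, 75])
        fence = q3 + 1.5 * (q3 - q1)
        assert (counts > fence).sum() == 5  # round(0.1 * 50) by construction

    def test_uncoupled_density_uncorrelated_with_covariate(self, bundle_small):
        cfg = self._config(n_samples=4, mean_burden=20_000, coupling=0.0)
        cat = sm.generate_tumor_catalog(cfg, bundle_small)
        ref = bundle_small.reference
        gpos = ref.to_global(cat["chrom"].to_numpy(), cat["pos"].to_numpy())
        dens = np.bincount(gpos // 1000, minlength=ref.total_length // 1000)
        cov = bundle_small.tracks["covA"]["value"].to_numpy()
        r = np.corrcoef(dens, cov)[0, 1]
        assert abs(r) < 0.1

    def test_coupled_density_tracks_covariate(self, bundle_small):
        cfg = self._config(n_samples=4, mean_burden=20_000, coupling=1.0)
        cat = sm.generate_tumor_catalog(cfg, bundle_small)
        ref = bundle_small.reference
        gpos = ref.to_global(cat["chrom"].to_numpy(), cat["pos"].to_numpy())
        dens = np.bincount(gpos // 1000, minlength=ref.total_length // 1000)
        z = bundle_small.tracks["covA"]["value"].to_numpy()
        z = (z - z.mean()) / z.std()
        r = np.corrcoef(dens, np.exp(z))[0, 1]
        assert r > 0.5
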