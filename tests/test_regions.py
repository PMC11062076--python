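"""Masking, tiling, covariate mapping and region construction."""

import numpy as np
import pandas as pd
import pytest

import scmosaic as sm
from scmosaic import regions as rg
from conftest import make_reference


def _ref(n_kb=20, name="chr1"):
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), n_kb * 1000))
    return make_reference(seq, name)


def _depth(ref, bulk=(30.0, 30.0), sc=30.0):
    n = ref.total_length // 100
    return pd.DataFrame(
        {
            "chrom": ref.contigs[0],
            "start": np.arange(n) * 100,
            "bulk_1": np.full(n, bulk[0]),
            "bulk_2": np.full(n, bulk[1]),
            "sc_mean": np.full(n, float(sc)),
        }
    )


class TestMask:
    def test_any_shallow_bulk_sample_blocks_accessibility(self):
        ref = _ref()
        d = _depth(ref)
        d.loc[0, "bulk_2"] = 4.0
        mask = rg.build_mask(d, ref)
        assert not mask.bulk_accessible[0]
        assert mask.bulk_accessible[1:].all()

    def test_adequate_depth_below_upper_cut_is_alignable(self):
        ref = _ref()
        d = _depth(ref)
        d.loc[5, "sc_mean"] = 5.0  # below single-cell minimum
        mask = rg.build_mask(d, ref)
        assert not mask.alignable[5]

    def test_exactly_top_2p5_percent_removed_by_upper_cut(self):
        ref = _ref(n_kb=40)  # 400 windows
        d = _depth(ref)
        rng = np.random.default_rng(1)
        d["sc_mean"] = rng.uniform(10, 50, len(d))
        mask = rg.build_mask(d, ref)
        n = len(d)
        assert (~mask.alignable).sum() == int(round(0.025 * n))

    def test_mismatched_tiling_rejected(self):
        ref = _ref()
        d = _depth(ref).iloc[:-5]
        with pytest.raises(ValueError, match="windows"):
            rg.build_mask(d, ref)


class TestTiling:
    def test_1kb_retention_boundary_at_two_subwindows(self):
        ref = _ref()
        mask = rg.full_mask(ref)
        mask.alignable[:2] = False  # 2 bad sub-windows in first 1 kb window
        mask.alignable[10:13] = False  # 3 bad in second
        t = rg.tile_1kb(mask)
        assert bool(t.loc[0, "retained"]) is True
        assert bool(t.loc[1, "retained"]) is False

    def test_fully_alignable_keeps_everything(self):
        t = rg.tile_1kb(rg.full_mask(_ref()))
        assert t["retained"].all()

    def test_fully_unalignable_keeps_nothing(self):
        mask = rg.full_mask(_ref())
        mask.alignable[:] = False
        t = rg.tile_1kb(mask)
        assert not t["retained"].any()


class TestQuantitativeMapping:
    def test_constant_track_maps_to_constant(self):
        ref = _ref()
        mask = rg.full_mask(ref)
        win = rg.tile_1kb(mask)
        track = pd.DataFrame(
            {"chrom": "chr1", "start": [0], "end": [ref.total_length], "value": [7.5]}
        )
        vals = rg.map_quantitative(track, win, ref)
        assert np.allclose(vals, 7.5)

    def test_mean_mapping_is_linear_in_track(self):
        ref = _ref()
        win = rg.tile_1kb(rg.full_mask(ref))
        rng = np.random.default_rng(2)
        n = ref.total_length // 1000
        base = pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(n) * 1000,
             "end": np.arange(1, n + 1) * 1000, "value": rng.uniform(0, 5, n)}
        )
        v1 = rg.map_quantitative(base, win, ref)
        scaled = base.assign(value=3.0 * base["value"])
        v3 = rg.map_quantitative(scaled, win, ref)
        assert np.allclose(v3, 3.0 * v1)

    def test_overlapping_genes_take_maximum_expression(self):
        ref = _ref()
        win = rg.tile_1kb(rg.full_mask(ref))
        genes = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 500], "end": [1000, 1500],
             "name": ["g1", "g2"], "value": [5.0, 9.0]}
        )
        vals = rg.map_quantitative(None, win, ref, kind="expression", genes=genes)
        # window 0: 500 bp at 5 and 500 bp at max(5,9)=9
        assert vals.loc[0] == pytest.approx((500 * 5 + 500 * 9) / 1000)

    def test_windows_below_transcript_coverage_dropped(self):
        ref = _ref()
        win = rg.tile_1kb(rg.full_mask(ref))
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [150], "name": ["g1"], "value": [4.0]}
        )
        vals = rg.map_quantitative(None, win, ref, kind="expression", genes=genes)
        assert 0 not in vals.index  # 15% < 20% coverage

    def test_unknown_contig_rejected(self):
        ref = _ref()
        win = rg.tile_1kb(rg.full_mask(ref))
        track = pd.DataFrame({"chrom": ["chrZ"], "start": [0], "end": [100], "value": [1.0]})
        with pytest.raises(ValueError, match="contigs"):
            rg.map_quantitative(track, win, ref)


class TestQuantileBins:
    def _values(self, vals):
        return pd.Series(vals, index=np.arange(len(vals)))

    def test_distinct_values_fill_deciles_in_order(self):
        ref = _ref(n_kb=10)
        mask = rg.full_mask(ref)
        rs = rg.quantile_bins(self._values(np.arange(1.0, 11.0)), mask, n_bins=10)
        codes = rs.region_of_global(np.arange(10) * 1000)
        assert list(codes) == list(range(10))

    def test_ties_broken_by_genomic_order(self):
        ref = _ref(n_kb=10)
        mask = rg.full_mask(ref)
        rs = rg.quantile_bins(self._values(np.ones(10)), mask, n_bins=5)
        codes = rs.region_of_global(np.arange(10) * 1000)
        assert list(codes) == [0, 0, 1, 1, 2, 2, 3, 3, 4, 4]

    def test_reverse_flips_ranks(self):
        ref = _ref(n_kb=10)
        mask = rg.full_mask(ref)
        rs = rg.quantile_bins(self._values(np.arange(1.0, 11.0)), mask, n_bins=10, reverse=True)
        assert rs.region_of_global(np.array([0]))[0] == 9  # value 1 -> rank 10
        assert rs.ids[rs.region_of_global(np.array([0]))[0]] == 10

    def test_equal_window_counts_up_to_one(self):
        ref = _ref(n_kb=20)  # 20 windows into 3 bins
        mask = rg.full_mask(ref)
        rng = np.random.default_rng(3)
        rs = rg.quantile_bins(self._values(rng.uniform(0, 1, 20)), mask, n_bins=3)
        counts = np.zeros(3, dtype=int)
        np.add.at(counts, rs.codes, (rs.ends - rs.starts) // 1000)
        assert counts.max() - counts.min() <= 1

    def test_fewer_windows_than_bins_rejected(self):
        with pytest.raises(ValueError):
            rg.quantile_bins(self._values([1.0, 2.0]), rg.full_mask(_ref()), n_bins=10)


class TestCategoricalRegions:
    def test_unalignable_windows_subtracted(self):
        ref = _ref()
        mask = rg.full_mask(ref)
        mask.alignable[10:20] = False  # bases 1000-2000
        ann = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [2500], "state": ["s1"]})
        rs = rg.categorical_regions(ann, mask)
        assert rs.alignable_bp["s1"] == 2000 - 1000
        codes = rs.region_of_global(np.array([600, 1500, 2200]))
        assert list(codes) == [0, -1, 0]

    def test_overlapping_states_rejected(self):
        ann = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 500], "end": [1000, 1500],
             "state": ["a", "b"]}
        )
        with pytest.raises(ValueError, match="overlap"):
            rg.categorical_regions(ann, rg.full_mask(_ref()))

    def test_genic_and_intergenic_partition_alignable_genome(self):
        ref = _ref()
        mask = rg.full_mask(ref)
        mask.alignable[50:60] = False
        genes = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "start": [2000, 3000], "end": [3500, 8000],
             "name": ["g1", "g2"], "strand": ["+", "-"]}
        )
        rs = rg.genic_intergenic(genes, mask)
        total = sum(rs.alignable_bp.values())
        assert total == int(mask.alignable.sum()) * 100
        # overlapping genes merged: genic alignable length = 6000 minus masked overlap
        masked_in_genic = ((np.arange(50, 60) * 100 >= 2000) & (np.arange(50, 60) * 100 < 8000)).sum() * 100
        assert rs.alignable_bp["genic"] == 6000 - masked_in_genic

    def test_quantile_partition_conserves_alignable_bp(self):
        ref = _ref(n_kb=30)
        mask = rg.full_mask(ref)
        mask.alignable[7] = False
        win = rg.tile_1kb(mask)
        rng = np.random.default_rng(4)
        vals = pd.Series(rng.uniform(0, 1, int(win["retained"].sum())),
                         index=win[win["retained"]]["gidx"])
        rs = rg.quantile_bins(vals, mask, n_bins=5)
        assert sum(rs.alignable_bp.values()) == int(mask.alignable.sum()) * 100
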