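"""Genome masking, tiling and region construction.

The genome is tiled with non-overlapping 100 bp windows; windows are
*bulk-accessible* when every bulk sample reaches a minimum mean depth and
*alignable* when the cross-cell mean depth is adequate but not extreme.
Quantitative covariates are summarized over 1 kb windows (10 sub-windows;
windows with >2 unalignable sub-windows are discarded) and discretized
into equal-count quantile regions; categorical annotations become regions
by subtracting unalignable windows from each state's interval union.

Coordinates are BED-style 0-based half-open internally; 1-based call
positions are converted on ingest.  Global coordinates concatenate contigs
in reference order, which requires contig lengths to be multiples of the
window size (true of the synthetic genomes this package generates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contexts import Reference

log = logging.getLogger(__name__)

BULK_MIN_DEPTH = 5.0
SC_MIN_DEPTH = 6.0
TOP_DEPTH_FRACTION = 0.025
MAX_UNALIGNABLE_SUBWINDOWS = 2  # per 1 kb window


def _check_tiling(ref: Reference, size: int) -> None:
    for c, ln in ref.lengths.items():
        if ln % size:
            raise ValueError(f"contig {c} length {ln} is not a multiple of {size}")


@dataclass
class GenomeMask:
    """Per-100 bp-window accessibility flags on the whole genome."""

    reference: Reference
    bulk_accessible: np.ndarray  # bool, one per global 100 bp window
    alignable: np.ndarray
    window_size: int = 100

    @property
    def n_windows(self) -> int:
        return len(self.alignable)

    def window_of_global(self, gpos: np.ndarray) -> np.ndarray:
        return np.asarray(gpos, dtype=np.int64) // self.window_size


def build_mask(depth: pd.DataFrame, reference: Reference) -> GenomeMask:
    """Mask from 100 bp depth summaries.

    `depth` columns: ``chrom, start``, one or more ``bulk_*`` columns and a
    single-cell cross-cell mean column ``sc_mean``.  A window is
    bulk-accessible iff every bulk sample's mean depth >= 5; alignable iff
    the cross-cell mean depth >= 6 and the window is not among the top 2.5%
    of windows by mean depth (rank-based upper cut).
    """
    _check_tiling(reference, 100)
    n_expected = reference.total_length // 100
    if len(depth) != n_expected:
        raise ValueError(f"depth matrix has {len(depth)} windows, expected {n_expected}")
    off = np.array([reference.offset(c) for c in depth["chrom"]])
    order = np.argsort(off + depth["start"].to_numpy(), kind="stable")
    depth = depth.iloc[order]
    bulk_cols = [c for c in depth.columns if c.startswith("bulk")]
    if not bulk_cols:
        raise ValueError("no bulk depth columns")
    bulk_ok = np.ones(len(depth), dtype=bool)
    for c in bulk_cols:
        bulk_ok &= depth[c].to_numpy() >= BULK_MIN_DEPTH
    sc = depth["sc_mean"].to_numpy(dtype=float)
    n_top = int(round(TOP_DEPTH_FRACTION * len(sc)))
    too_deep = np.zeros(len(sc), dtype=bool)
    if n_top > 0:
        too_deep[np.argsort(sc, kind="stable")[-n_top:]] = True
    alignable = (sc >= SC_MIN_DEPTH) & ~too_deep
    return GenomeMask(reference, bulk_ok, alignable)


def full_mask(reference: Reference) -> GenomeMask:
    """Everything accessible/alignable; for analyses without depth data."""
    n = reference.total_length // 100
    return GenomeMask(reference, np.ones(n, bool), np.ones(n, bool))


def tile_1kb(mask: GenomeMask) -> pd.DataFrame:
    """Non-overlapping 1 kb windows with retention flags.

    Columns: chrom, start, gidx (global 1 kb index), n_unalignable,
    retained (<= 2 unalignable 100 bp sub-windows).
    """
    ref = mask.reference
    _check_tiling(ref, 1000)
    unalign = (~mask.alignable).reshape(-1, 10).sum(axis=1)
    gidx = np.arange(len(unalign))
    chroms, starts = [], []
    for c in ref.contigs:
        n = len(ref.seqs[c]) // 1000
        chroms += [c] * n
        starts.append(np.arange(n) * 1000)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.concatenate(starts),
            "gidx": gidx,
            "n_unalignable": unalign,
            "retained": unalign <= MAX_UNALIGNABLE_SUBWINDOWS,
        }
    )


def tile_1mb(mask: GenomeMask, max_unalignable_fraction: float = 0.2) -> pd.DataFrame:
    """1 Mb tiling with the proportional retention rule (>20% unalignable
    100 bp sub-windows drops the window)."""
    ref = mask.reference
    size = 1_000_000
    rows = []
    g = 0
    for c in ref.contigs:
        ln = len(ref.seqs[c])
        for s in range(0, ln - size + 1, size):
            w0 = (ref.offset(c) + s) // 100
            sub = mask.alignable[w0 : w0 + size // 100]
            frac_un = 1.0 - sub.mean()
            rows.append((c, s, g, frac_un, frac_un <= max_unalignable_fraction))
            g += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "gidx", "unalignable_fraction", "retained"])


# ---------------------------------------------------------------------------
# covariate mapping


def map_quantitative(
    track: pd.DataFrame,
    windows: pd.DataFrame,
    reference: Reference,
    kind: str = "mean_over_window",
    genes: pd.DataFrame | None = None,
    min_transcript_fraction: float = 0.2,
) -> pd.Series:
    """One value per retained 1 kb window.

    kind="mean_over_window": average bedGraph signal over each window
    (uncovered basepairs count as 0).  kind="expression": per-basepair
    value is the maximum expression among overlapping genes (0 outside
    genes); windows with less than `min_transcript_fraction` of their
    basepairs covered by a transcript are dropped; remaining windows
    average over their 1,000 bp.  Returns a Series indexed by gidx.
    """
    ret = windows[windows["retained"]]
    if kind == "mean_over_window":
        unknown = set(track["chrom"]) - set(reference.contigs)
        if unknown:
            raise ValueError(f"track contigs not in reference: {sorted(unknown)}")
        sums = np.zeros(reference.total_length // 1000)
        for chrom, grp in track.groupby("chrom", sort=False):
            off = reference.offset(chrom)
            for s, e, v in zip(grp["start"], grp["end"], grp["value"]):
                gs, ge = off + int(s), off + int(e)
                w0, w1 = gs // 1000, (ge - 1) // 1000
                for w in range(w0, w1 + 1):
                    lo = max(gs, w * 1000)
                    hi = min(ge, (w + 1) * 1000)
                    sums[w] += v * (hi - lo)
        return pd.Series(sums[ret["gidx"].to_numpy()] / 1000.0, index=ret["gidx"])
    if kind == "expression":
        if genes is None:
            raise ValueError("expression mapping needs a gene table with a value column")
        vals = {}
        for chrom in reference.contigs:
            ln = len(reference.seqs[chrom])
            per_bp = np.zeros(ln)
            covered = np.zeros(ln, dtype=bool)
            for _, g in genes[genes["chrom"] == chrom].iterrows():
                s, e = int(g["start"]), int(g["end"])
                per_bp[s:e] = np.maximum(per_bp[s:e], float(g["value"]))
                covered[s:e] = True
            vals[chrom] = (per_bp, covered)
        out_idx, out_val = [], []
        for _, w in ret.iterrows():
            per_bp, covered = vals[w["chrom"]]
            s = int(w["start"])
            frac = covered[s : s + 1000].mean()
            if frac < min_transcript_fraction:
                continue
            out_idx.append(w["gidx"])
            out_val.append(per_bp[s : s + 1000].mean())
        return pd.Series(out_val, index=out_idx)
    raise ValueError(f"unknown mapping kind {kind!r}")


# ---------------------------------------------------------------------------
# region sets


@dataclass
class RegionSet:
    """Named disjoint genomic regions with fast point lookup.

    Intervals are global 0-based half-open, sorted, non-overlapping, each
    carrying a region code (index into `ids`).
    """

    name: str
    mode: str  # quantile | categorical
    ids: list
    starts: np.ndarray
    ends: np.ndarray
    codes: np.ndarray
    alignable_bp: dict = field(default_factory=dict)
    reference: Reference | None = None

    def region_of_global(self, gpos: np.ndarray) -> np.ndarray:
        """Region code per position; -1 outside all regions."""
        gpos = np.asarray(gpos, dtype=np.int64)
        i = np.searchsorted(self.starts, gpos, side="right") - 1
        ok = (i >= 0) & (gpos < self.ends[np.maximum(i, 0)])
        return np.where(ok, self.codes[np.maximum(i, 0)], -1)

    def label_of_code(self, code: int):
        return self.ids[code]

    def to_bed(self) -> pd.DataFrame:
        chroms, pos = self.reference.from_global(self.starts)
        _, epos = self.reference.from_global(self.ends - 1)
        return pd.DataFrame(
            {
                "chrom": chroms,
                "start": pos - 1,
                "end": epos,
                "name": [self.ids[c] for c in self.codes],
            }
        )

    def summary(self) -> pd.DataFrame:
        bp = np.zeros(len(self.ids))
        np.add.at(bp, self.codes, self.ends - self.starts)
        return pd.DataFrame(
            {
                "region": self.ids,
                "total_bp": bp.astype(int),
                "alignable_bp": [self.alignable_bp.get(r, 0) for r in self.ids],
            }
        )


def _merge_windows_to_regions(
    name: str,
    mode: str,
    ids: list,
    window_gidx: np.ndarray,
    window_code: np.ndarray,
    mask: GenomeMask,
    window_size: int = 1000,
) -> RegionSet:
    order = np.argsort(window_gidx, kind="stable")
    g = window_gidx[order]
    c = window_code[order]
    starts, ends, codes = [], [], []
    for i in range(len(g)):
        s = g[i] * window_size
        if starts and ends[-1] == s and codes[-1] == c[i]:
            ends[-1] = s + window_size
        else:
            starts.append(s)
            ends.append(s + window_size)
            codes.append(c[i])
    starts = np.array(starts, dtype=np.int64)
    ends = np.array(ends, dtype=np.int64)
    codes = np.array(codes, dtype=np.int64)
    align_bp = {}
    for k, rid in enumerate(ids):
        sel = codes == k
        bp = 0
        for s, e in zip(starts[sel], ends[sel]):
            bp += int(mask.alignable[s // 100 : e // 100].sum()) * 100
        align_bp[rid] = bp
    return RegionSet(name, mode, ids, starts, ends, codes, align_bp, mask.reference)


def quantile_bins(
    values: pd.Series,
    mask: GenomeMask,
    n_bins: int = 10,
    reverse: bool = False,
    name: str = "covariate",
) -> RegionSet:
    """Equal-count quantile regions from per-1 kb-window covariate values.

    Ties are broken by genomic order (window index), making the assignment
    deterministic.  `reverse=True` flips ranks so Q1 holds the largest
    values (used for replication timing, where Q1 means earliest).
    """
    gidx = values.index.to_numpy(dtype=np.int64)
    vals = values.to_numpy(dtype=float)
    if len(vals) < n_bins:
        raise ValueError("fewer windows than bins")
    order = np.lexsort((gidx, vals))
    rank = np.empty(len(vals), dtype=np.int64)
    rank[order] = np.arange(len(vals))
    q = rank * n_bins // len(vals) + 1
    if reverse:
        q = n_bins + 1 - q
    ids = list(range(1, n_bins + 1))
    return _merge_windows_to_regions(name, "quantile", ids, gidx, q - 1, mask)


def categorical_regions(
    annotation: pd.DataFrame,
    mask: GenomeMask,
    name: str = "annotation",
    allow_overlap: bool = False,
) -> RegionSet:
    """Regions from a BED-like state annotation (chrom, start, end, state).

    Unalignable 100 bp windows are subtracted from each state's interval
    union.  Overlapping intervals raise unless `allow_overlap` (first state
    in sort order wins on the overlap).
    """
    ref = mask.reference
    ann = annotation.sort_values(["chrom", "start"], kind="stable")
    prev_end: dict[str, int] = {}
    for _, r in ann.iterrows():
        if r["chrom"] in prev_end and int(r["start"]) < prev_end[r["chrom"]]:
            if not allow_overlap:
                raise ValueError("overlapping states in annotation; pass allow_overlap=True")
        prev_end[r["chrom"]] = max(prev_end.get(r["chrom"], 0), int(r["end"]))
    ids = sorted(ann["state"].unique())
    code_of = {s: i for i, s in enumerate(ids)}
    starts, ends, codes = [], [], []
    claimed_until: dict[str, int] = {}
    for _, r in ann.iterrows():
        chrom = r["chrom"]
        off = ref.offset(chrom)
        s = off + max(int(r["start"]), claimed_until.get(chrom, 0) - off)
        e = off + int(r["end"])
        claimed_until[chrom] = e
        if e <= s:
            continue
        # subtract unalignable 100 bp windows
        w0, w1 = s // 100, (e + 99) // 100
        ok = mask.alignable[w0:w1]
        run_start = None
        for w in range(w0, w1):
            good = ok[w - w0]
            lo, hi = max(s, w * 100), min(e, (w + 1) * 100)
            if good and run_start is None:
                run_start = lo
            if (not good or w == w1 - 1) and run_start is not None:
                run_end = lo if not good else hi
                if run_end > run_start:
                    starts.append(run_start)
                    ends.append(run_end)
                    codes.append(code_of[r["state"]])
                run_start = None
    order = np.argsort(starts, kind="stable")
    starts = np.array(starts, dtype=np.int64)[order]
    ends = np.array(ends, dtype=np.int64)[order]
    codes = np.array(codes, dtype=np.int64)[order]
    align_bp: dict = {rid: 0 for rid in ids}
    for s, e, c in zip(starts, ends, codes):
        align_bp[ids[c]] += int(e - s)
    return RegionSet(name, "categorical", ids, starts, ends, codes, align_bp, ref)


def genic_intergenic(genes: pd.DataFrame, mask: GenomeMask) -> RegionSet:
    """Two-state partition: union of gene intervals vs its complement,
    both minus unalignable windows."""
    ref = mask.reference
    rows = []
    for chrom in ref.contigs:
        ln = len(ref.seqs[chrom])
        ivals = genes[genes["chrom"] == chrom][["start", "end"]].sort_values("start")
        merged: list[list[int]] = []
        for _, (s, e) in ivals.iterrows():
            s, e = int(s), int(e)
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        pos = 0
        for s, e in merged:
            if s > pos:
                rows.append((chrom, pos, s, "intergenic"))
            rows.append((chrom, s, e, "genic"))
            pos = e
        if pos < ln:
            rows.append((chrom, pos, ln, "intergenic"))
    ann = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    return categorical_regions(ann, mask, name="genic")


def assign_regions(
    df: pd.DataFrame, regionset: RegionSet, reference: Reference
) -> pd.Series:
    """Region label per row of a (chrom, pos [1-based]) table; NaN outside."""
    gpos = reference.to_global(df["chrom"].to_numpy(), df["pos"].to_numpy())
    codes = regionset.region_of_global(gpos)
    labels = pd.Series(
        [regionset.ids[c] if c >= 0 else np.nan for c in codes], index=df.index
    )
    return labels
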