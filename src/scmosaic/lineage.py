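"""Shared-mutation analysis of cell pairs and MRCA dating.

A mutation called in at least one cell of a pair is *shared* when two or
more supporting reads appear in the other cell; *private* when the other
cell shows zero supporting reads at adequate depth (>= 6); otherwise
*indeterminate*.  Applying the same rules to germline heterozygous SNPs —
which are truly shared — measures the misclassification fraction f, and
the dropout-corrected shared count is N = s / (1 - f).  Mapping the
burden-scaled shared count N*S onto the cell type's aging trend line
dates the pair's most recent common ancestor: T = (N*S - I) / R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .burden import AgingModel

log = logging.getLogger(__name__)

SHARED_MIN_SUPPORT = 2
PRIVATE_MIN_DEPTH = 6


@dataclass
class PairClassification:
    cell_a: str
    cell_b: str
    labels: pd.DataFrame  # chrom, pos, called_in, label
    s: int
    private_a: int
    private_b: int
    indeterminate: int
    f: float | None = None
    N: float | None = None


@dataclass
class MrcaEstimate:
    T: float
    interval: tuple[float, float]
    clipped: bool
    N: float
    scaling: float
    intercept: float
    rate: float
    caveat: str = (
        "interval reflects trend-line CI bound combinations, not a statistical CI"
    )


def _support_lookup(support: pd.DataFrame, cell: str) -> pd.DataFrame:
    sub = support[support["cell"] == cell]
    return sub.set_index(["chrom", "pos"])[["alt_reads", "depth"]]


def classify_pair(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    support: pd.DataFrame,
    cell_a: str | None = None,
    cell_b: str | None = None,
) -> PairClassification:
    """Label the union of two cells' calls as shared / private / indeterminate.

    `support` carries cross-cell read counts: columns
    ``chrom, pos, cell, alt_reads, depth`` where `cell` is the cell in
    which the reads were counted.  Sites without a support row in the
    partner cell are indeterminate (with a warning).
    """
    cell_a = cell_a or calls_a["cell"].iloc[0]
    cell_b = cell_b or calls_b["cell"].iloc[0]
    sup = {cell_a: _support_lookup(support, cell_a), cell_b: _support_lookup(support, cell_b)}
    sites: dict[tuple, dict] = {}
    for df, cell in ((calls_a, cell_a), (calls_b, cell_b)):
        for _, r in df.iterrows():
            key = (r["chrom"], int(r["pos"]))
            sites.setdefault(key, {"called": set()})["called"].add(cell)
    n_missing = 0
    rows = []
    for key, info in sites.items():
        called = info["called"]
        partner_meas = []
        for cell in (cell_a, cell_b):
            if cell in called:
                other = cell_b if cell == cell_a else cell_a
                try:
                    m = sup[other].loc[key]
                except KeyError:
                    m = None
                partner_meas.append(m)
        if any(m is None for m in partner_meas):
            n_missing += 1
            label = "indeterminate"
        elif any(int(m["alt_reads"]) >= SHARED_MIN_SUPPORT for m in partner_meas):
            label = "shared"
        elif all(
            int(m["alt_reads"]) == 0 and int(m["depth"]) >= PRIVATE_MIN_DEPTH
            for m in partner_meas
        ):
            label = "private"
        else:
            label = "indeterminate"
        rows.append(
            {
                "chrom": key[0],
                "pos": key[1],
                "called_in": ",".join(sorted(called)),
                "label": label,
            }
        )
    if n_missing:
        log.warning("%d sites lacked cross-support rows; labelled indeterminate", n_missing)
    labels = pd.DataFrame(rows)
    shared = int((labels["label"] == "shared").sum())
    priv = labels[labels["label"] == "private"]
    return PairClassification(
        cell_a,
        cell_b,
        labels,
        s=shared,
        private_a=int((priv["called_in"] == cell_a).sum()),
        private_b=int((priv["called_in"] == cell_b).sum()),
        indeterminate=int((labels["label"] == "indeterminate").sum()),
    )


def misclassification_fraction(hsnp_labels: pd.DataFrame | pd.Series) -> float:
    """f = (private + indeterminate hSNPs) / total hSNPs.

    hSNPs are germline and thus truly shared; any other label measures
    pair-specific dropout.  Requires >= 100 classified hSNPs.
    """
    labels = hsnp_labels["label"] if isinstance(hsnp_labels, pd.DataFrame) else hsnp_labels
    n = len(labels)
    if n < 100:
        raise ValueError(f"need at least 100 classified hSNPs, got {n}")
    f = float((labels != "shared").mean())
    if f >= 1.0:
        raise ValueError("all hSNPs misclassified; degenerate pair")
    return f


def classify_hsnps(
    hsnp_sites: pd.DataFrame, support: pd.DataFrame, cell_a: str, cell_b: str
) -> pd.DataFrame:
    """Classify germline het sites with the somatic sharing rules.

    A site is shared when either cell shows >= 2 supporting reads; private
    when both show 0 reads at depth >= 6; else indeterminate.
    """
    sup_a = _support_lookup(support, cell_a)
    sup_b = _support_lookup(support, cell_b)
    rows = []
    for _, r in hsnp_sites.drop_duplicates(["chrom", "pos"]).iterrows():
        key = (r["chrom"], int(r["pos"]))
        ms = []
        for sup in (sup_a, sup_b):
            try:
                ms.append(sup.loc[key])
            except KeyError:
                ms.append(None)
        if any(m is None for m in ms):
            label = "indeterminate"
        elif any(int(m["alt_reads"]) >= SHARED_MIN_SUPPORT for m in ms):
            label = "shared"
        elif all(
            int(m["alt_reads"]) == 0 and int(m["depth"]) >= PRIVATE_MIN_DEPTH for m in ms
        ):
            label = "private"
        else:
            label = "indeterminate"
        rows.append({"chrom": key[0], "pos": key[1], "label": label})
    return pd.DataFrame(rows)


def correct_shared(s: float, f: float) -> float:
    """Dropout-corrected shared count N = s / (1 - f)."""
    if not 0.0 <= f < 1.0:
        raise ValueError("misclassification fraction must be in [0, 1)")
    return s / (1.0 - f)


def mrca_time(
    N: float,
    scaling: float,
    aging: AgingModel,
    cell_type: str,
    subject_age: float | None = None,
) -> MrcaEstimate:
    """Date the MRCA by inverting the aging trend: T = (N*S - I) / R.

    The interval takes the min/max of (N*S - I')/R' over all combinations
    of the intercept and rate 95% CI bounds; it is an uncertainty probe,
    not a confidence interval.  T is clipped to [0, subject age] with the
    clipping recorded.
    """
    R = aging.slope[cell_type]
    I = aging.intercept[cell_type]
    if R <= 0:
        raise ValueError("aging rate must be positive to date an MRCA")
    burden = N * scaling
    T = (burden - I) / R
    combos = [
        (burden - i_) / r_
        for i_ in aging.intercept_ci[cell_type]
        for r_ in aging.slope_ci[cell_type]
        if r_ > 0
    ]
    if not combos:
        raise ValueError("no positive rate in the CI combinations")
    lo, hi = min(combos), max(combos)
    clipped = False
    upper = subject_age if subject_age is not None else np.inf
    T_clip = min(max(T, 0.0), upper)
    if T_clip != T:
        clipped = True
        log.info("MRCA time %.2f clipped to %.2f", T, T_clip)
    lo = min(max(lo, 0.0), upper)
    hi = min(max(hi, 0.0), upper)
    return MrcaEstimate(
        T=T_clip,
        interval=(lo, hi),
        clipped=clipped,
        N=N,
        scaling=scaling,
        intercept=I,
        rate=R,
    )


def find_related_pairs(
    pair_shared_counts: pd.DataFrame,
    k: float = 5.0,
    absolute_fallback: int = 20,
) -> pd.DataFrame:
    """Flag within-individual pairs with unusually many shared mutations.

    `pair_shared_counts` columns: ``cell_a, cell_b, s``.  A pair is flagged
    when s exceeds the cohort mean + k * MAD of shared counts; with a
    single pair (no cohort distribution) the absolute fallback threshold
    applies.  Flagged pairs are candidate lineage relatives; their
    duplicate calls are exempt from recurrence downsampling for this
    analysis only.
    """
    df = pair_shared_counts.copy()
    s = df["s"].to_numpy(dtype=float)
    if len(df) < 2:
        df["related"] = df["s"] >= absolute_fallback
        df["threshold"] = float(absolute_fallback)
        return df
    mad = np.median(np.abs(s - np.median(s)))
    thr = s.mean() + k * max(mad, 1.0)
    df["related"] = s > thr
    df["threshold"] = thr
    return df
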