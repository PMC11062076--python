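"""Per-cell somatic call tables: ingest, validation, recurrence filtering
and single-cell QC metrics.

A call table is a tidy DataFrame with columns
``chrom, pos, ref, alt, cell, individual, variant_class, mode`` plus the
channel columns ``sbs96_channel`` / ``id83_channel`` once annotated against
a reference.  A profile table has one row per cell with demographics, call
counts (V = VAF-based, M = signature-rescued), burden scaling factors and
global sensitivities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contexts import Reference, sbs96_channels, id83_channels

log = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "pos", "ref", "alt", "cell", "individual", "variant_class", "mode"]

MAX_INDEL_BP = 30


@dataclass
class QCMetrics:
    mapd: float | None
    expected_fp_snv: float
    expected_fp_indel: float
    fdr_snv: float | None
    fdr_indel: float | None


def read_calls(path, reference: Reference | None = None, profiles: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and validate a TSV call table; annotate channels if a reference
    is given.  Rows naming cells absent from `profiles` are rejected."""
    calls = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ("chrom", "pos", "ref", "alt", "cell", "mode") if c not in calls]
    if missing:
        raise ValueError(f"call table missing columns: {missing}")
    return validate_calls(calls, reference=reference, profiles=profiles)


def validate_calls(
    calls: pd.DataFrame,
    reference: Reference | None = None,
    profiles: pd.DataFrame | None = None,
) -> pd.DataFrame:
    calls = calls.copy()
    if (calls["pos"] <= 0).any():
        raise ValueError("positions must be 1-based and positive")
    if (calls["ref"] == calls["alt"]).any():
        raise ValueError("ref and alt alleles must differ")
    if "variant_class" not in calls:
        calls["variant_class"] = np.where(
            (calls["ref"].str.len() == 1) & (calls["alt"].str.len() == 1), "SNV", "indel"
        )
    indel_len = (calls["ref"].str.len() - calls["alt"].str.len()).abs()
    if (indel_len[calls["variant_class"] == "indel"] > MAX_INDEL_BP).any():
        raise ValueError(f"indels longer than {MAX_INDEL_BP} bp are out of scope")
    if profiles is not None:
        known = set(profiles["cell"])
        bad = ~calls["cell"].isin(known)
        if bad.any():
            log.warning("rejecting %d calls from unknown cells", int(bad.sum()))
            calls = calls[~bad].copy()
        if "individual" not in calls:
            calls = calls.merge(profiles[["cell", "individual"]], on="cell", how="left")
    if reference is not None:
        unknown = set(calls["chrom"]) - set(reference.contigs)
        if unknown:
            raise ValueError(f"contigs not in reference: {sorted(unknown)}")
        calls = annotate_channels(calls, reference)
    return calls.reset_index(drop=True)


def annotate_channels(calls: pd.DataFrame, reference: Reference) -> pd.DataFrame:
    """Attach SBS96 / ID83 channel columns computed from the reference."""
    calls = calls.copy()
    snv = calls["variant_class"] == "SNV"
    sbs = np.full(len(calls), -1, dtype=np.int16)
    if snv.any():
        sub = calls[snv]
        sbs[snv.to_numpy()] = sbs96_channels(
            reference,
            sub["chrom"].to_numpy(),
            sub["pos"].to_numpy(),
            sub["ref"].to_numpy(),
            sub["alt"].to_numpy(),
        )
    id83 = np.full(len(calls), -1, dtype=np.int16)
    ind = ~snv
    if ind.any():
        sub = calls[ind]
        id83[ind.to_numpy()] = id83_channels(
            reference,
            sub["chrom"].to_numpy(),
            sub["pos"].to_numpy(),
            sub["ref"].to_numpy(),
            sub["alt"].to_numpy(),
        )
    calls["sbs96_channel"] = sbs
    calls["id83_channel"] = id83
    return calls


def read_profiles(path) -> pd.DataFrame:
    profiles = pd.read_csv(path, sep="\t")
    required = {"cell", "individual", "age", "cell_type"}
    missing = required - set(profiles.columns)
    if missing:
        raise ValueError(f"profile table missing columns: {sorted(missing)}")
    if "outlier" not in profiles:
        profiles["outlier"] = "none"
    return profiles


# ---------------------------------------------------------------------------
# recurrence filtering


def filter_recurrent(
    calls: pd.DataFrame,
    within_cell_cluster_bp: int = 50,
    group_by: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove duplicate and clustered calls.

    VAF-based and rescued calls are considered together.  An exact
    duplicate (same chrom/pos/ref/alt) confined to one individual keeps a
    single representative; a duplicate spanning two or more individuals is
    removed entirely.  Within one cell, every call within
    `within_cell_cluster_bp` (inclusive) of another call in that cell is
    removed.  Filtering is applied separately per `group_by` column value
    (e.g. per cell type) when given.

    Returns (retained calls, removal log); the removal log has the input
    rows that were dropped plus a ``reason`` column in
    {cross_individual_duplicate, within_individual_duplicate, cluster}.
    """
    if group_by is None:
        return _filter_group(calls, within_cell_cluster_bp)
    kept_parts, removed_parts = [], []
    for _, grp in calls.groupby(group_by, sort=False):
        k, r = _filter_group(grp, within_cell_cluster_bp)
        kept_parts.append(k)
        removed_parts.append(r)
    kept = pd.concat(kept_parts) if kept_parts else calls.iloc[0:0]
    removed = pd.concat(removed_parts) if removed_parts else calls.iloc[0:0]
    return kept.reset_index(drop=True), removed.reset_index(drop=True)


def _filter_group(calls: pd.DataFrame, cluster_bp: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    calls = calls.reset_index(drop=True)
    reason = pd.Series(pd.NA, index=calls.index, dtype=object)
    key = ["chrom", "pos", "ref", "alt"]
    grp = calls.groupby(key, sort=False)
    n_ind = grp["individual"].transform("nunique")
    dup_size = grp["cell"].transform("size")
    cross = n_ind >= 2
    reason[cross] = "cross_individual_duplicate"
    # one representative per within-individual duplicate (first by cell name)
    within = (~cross) & (dup_size > 1)
    if within.any():
        sub = calls[within].sort_values(key + ["cell"], kind="stable")
        rep = sub.groupby(key, sort=False).head(1).index
        drop = sub.index.difference(rep)
        reason[drop] = "within_individual_duplicate"
    surviving = reason.isna()
    # cluster filter: per cell, any call within <= cluster_bp of another
    surv = calls[surviving]
    for (_, _), sub in surv.groupby(["cell", "chrom"], sort=False):
        pos = sub["pos"].sort_values()
        d = pos.diff()
        near_prev = d <= cluster_bp
        near_next = near_prev.shift(-1, fill_value=False)
        clustered = pos.index[(near_prev.fillna(False) | near_next)]
        reason[clustered] = "cluster"
    removed = calls[~reason.isna()].copy()
    removed["reason"] = reason[~reason.isna()]
    return calls[reason.isna()].copy(), removed


# ---------------------------------------------------------------------------
# QC metrics


def compute_mapd(copy_numbers) -> float:
    """Median absolute pairwise difference of successive log2 copy numbers."""
    cn = np.asarray(copy_numbers, dtype=float)
    if len(cn) < 2:
        raise ValueError("need at least two copy-number bins")
    if (cn <= 0).any():
        raise ValueError("copy numbers must be positive")
    return float(np.median(np.abs(np.diff(np.log2(cn)))))


FP_RATE_SNV_PER_MB = 0.0131
FP_RATE_INDEL_PER_MB = 0.00073


def estimate_fdr(
    profile: pd.Series,
    rate_snv_per_mb: float = FP_RATE_SNV_PER_MB,
    rate_indel_per_mb: float = FP_RATE_INDEL_PER_MB,
) -> QCMetrics:
    """Expected false-positive counts and per-cell FDR from fixed per-Mb
    error rates applied to the cell's accessible genome."""
    efp_snv = rate_snv_per_mb * profile["accessible_mb_snv"]
    efp_indel = rate_indel_per_mb * profile["accessible_mb_indel"]
    n_snv = profile.get("V_snv", 0) + profile.get("M_snv", 0)
    n_indel = profile.get("V_indel", 0) + profile.get("M_indel", 0)
    fdr_snv = min(1.0, efp_snv / n_snv) if n_snv > 0 else None
    fdr_indel = min(1.0, efp_indel / n_indel) if n_indel > 0 else None
    mapd = profile.get("mapd", None)
    return QCMetrics(mapd, efp_snv, efp_indel, fdr_snv, fdr_indel)


def catalog_fdr(profiles: pd.DataFrame, variant_class: str = "SNV") -> float:
    """Group-level FDR: summed expected false positives over summed calls."""
    rate = FP_RATE_SNV_PER_MB if variant_class == "SNV" else FP_RATE_INDEL_PER_MB
    suffix = "snv" if variant_class == "SNV" else "indel"
    efp = (rate * profiles[f"accessible_mb_{suffix}"]).sum()
    n = (profiles[f"V_{suffix}"] + profiles[f"M_{suffix}"]).sum()
    if n == 0:
        raise ValueError("no calls in catalog")
    return float(min(1.0, efp / n))


def flag_outliers(
    profiles: pd.DataFrame,
    burdens: pd.Series,
    sbs19_exposures: pd.Series | None = None,
    k: float = 4.0,
    low_floor: int = 2,
) -> pd.DataFrame:
    """Flag cells with aberrant burdens.

    HIGH: burden residual from a robust per-cell-type age trend exceeds
    k * MAD of residuals AND the cell's SBS19-like exposure exceeds its
    cohort median + k * MAD.  LOW: near-absence of calls (V+M <= floor).
    Flagged cells are excluded from all aging regressions downstream.
    """
    from scipy.stats import theilslopes

    out = profiles.copy()
    out["outlier"] = "none"
    v = out.get("V_snv", pd.Series(0, index=out.index))
    m = out.get("M_snv", pd.Series(0, index=out.index))
    out.loc[(v + m) <= low_floor, "outlier"] = "LOW"
    for ctype, grp in out.groupby("cell_type", sort=False):
        b = burdens.reindex(grp["cell"]).to_numpy()
        ages = grp["age"].to_numpy()
        if len(grp) < 3 or np.isnan(b).all():
            continue
        slope, intercept, *_ = theilslopes(b, ages)
        resid = b - (intercept + slope * ages)
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = max(mad, 1e-9)
        high = resid > k * scale
        if sbs19_exposures is not None:
            e = sbs19_exposures.reindex(grp["cell"]).fillna(0).to_numpy()
            emad = np.median(np.abs(e - np.median(e)))
            high &= e > np.median(e) + k * max(emad, 1e-9)
        idx = grp.index[high & (out.loc[grp.index, "outlier"] == "none")]
        out.loc[idx, "outlier"] = "HIGH"
    return out


def write_vcf(calls: pd.DataFrame, path, reference: Reference | None = None) -> None:
    """Minimal VCF 4.2 export of a (filtered) call table."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if reference is not None:
            for c, ln in reference.lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("##INFO=<ID=CELL,Number=1,Type=String,Description=\"Cell id\">\n")
        fh.write("##INFO=<ID=MODE,Number=1,Type=String,Description=\"Call mode\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, r in calls.sort_values(["chrom", "pos"]).iterrows():
            fh.write(
                f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t.\tPASS\t"
                f"CELL={r['cell']};MODE={r['mode']}\n"
            )
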