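"""Location-specific somatic detection sensitivity from leave-one-out
germline controls.

A germline heterozygous site re-genotyped as if it were somatic is a
positive control: the fraction of depth-eligible controls in a region that
the caller recovers estimates the VAF-based somatic detection sensitivity
S_vaf in that region for that cell.  Rescue-inclusive sensitivity scales
S_vaf by the cell's (V+M)/V call ratio, capped at 1.  Group sensitivity is
the call-count-weighted average over cells.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MIN_DEPTH = {"SNV": 6, "indel": 10}
DEFAULT_MIN_CONTROLS = 50


def region_sensitivity(
    germline: pd.DataFrame,
    min_controls: int = DEFAULT_MIN_CONTROLS,
) -> pd.DataFrame:
    """Per (region, cell) VAF-based sensitivity from leave-one-out controls.

    `germline` must carry columns ``region, cell, passes_min_depth, called``
    (assign regions with :func:`scmosaic.regions.assign_regions`).  Controls
    failing the minimum-depth requirement are excluded from both numerator
    and denominator.  Regions with fewer than `min_controls` eligible
    controls get a null estimate.
    """
    df = germline[germline["passes_min_depth"]]
    grp = df.groupby(["region", "cell"], sort=False, observed=True)
    out = grp.agg(n_controls=("called", "size"), n_called=("called", "sum")).reset_index()
    out["s_vaf"] = out["n_called"] / out["n_controls"]
    low = out["n_controls"] < min_controls
    if low.any():
        log.warning("%d (region, cell) sensitivity estimates below %d controls set to null",
                    int(low.sum()), min_controls)
        out.loc[low, "s_vaf"] = np.nan
    return out


def rescue_adjust(s_vaf, V, M):
    """Rescue-inclusive sensitivity: min(1, S_vaf * (V+M)/V).

    Vectorized; V=0 with M>0 yields null (the ratio is undefined), V=M=0
    leaves S_vaf unchanged.
    """
    s = np.asarray(s_vaf, dtype=float)
    V = np.asarray(V, dtype=float)
    M = np.asarray(M, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        adj = np.minimum(1.0, s * (V + M) / V)
    adj = np.where((V == 0) & (M == 0), s, adj)
    adj = np.where((V == 0) & (M > 0), np.nan, adj)
    if np.isscalar(s_vaf) or np.ndim(s_vaf) == 0:
        return float(adj)
    return adj


def group_sensitivity(
    estimates: pd.DataFrame,
    profiles: pd.DataFrame,
    mode: str = "vaf_plus_rescue",
    variant_class: str = "SNV",
) -> pd.DataFrame:
    """Mutation-count-weighted sensitivity per region for a group of cells.

    W_R = sum_i (N_i / sum_j N_j) * S_R,i with N_i = V_i + M_i in
    ``vaf_plus_rescue`` mode (S is the rescue-adjusted sensitivity) and
    N_i = V_i with the raw VAF sensitivity in ``vaf_only`` mode.  Cells
    lacking an estimate in a region are dropped with a warning and the
    weights renormalized over the remaining cells.
    """
    if mode not in ("vaf_only", "vaf_plus_rescue"):
        raise ValueError(f"unknown mode {mode!r}")
    if profiles.empty:
        raise ValueError("empty cell group")
    suffix = "snv" if variant_class == "SNV" else "indel"
    prof = profiles.set_index("cell")
    est = estimates[estimates["cell"].isin(prof.index)].copy()
    V = prof[f"V_{suffix}"].reindex(est["cell"]).to_numpy(dtype=float)
    M = prof[f"M_{suffix}"].reindex(est["cell"]).to_numpy(dtype=float)
    if mode == "vaf_plus_rescue":
        est["s"] = rescue_adjust(est["s_vaf"].to_numpy(), V, M)
        est["n"] = V + M
    else:
        est["s"] = est["s_vaf"]
        est["n"] = V
    null = est["s"].isna()
    if null.any():
        log.warning("dropping %d null sensitivity estimates; weights renormalized",
                    int(null.sum()))
        est = est[~null]
    if est.empty:
        raise ValueError("no usable sensitivity estimates")

    def w(g: pd.DataFrame) -> float:
        tot = g["n"].sum()
        if tot == 0:
            return float(g["s"].mean())
        return float((g["n"] / tot * g["s"]).sum())

    out = est.groupby("region", sort=False, observed=True).apply(w, include_groups=False)
    return out.rename("W").reset_index()
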