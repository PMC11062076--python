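"""Tumor mutation-density tracks and comparison with single-cell densities.

Hypermutated tumor samples are removed by Tukey's upper fence before
density aggregation.  Each remaining sample's mutations are counted per
1 Mb window and normalized by the sample's total, then summed across
samples of a tumor type.  The resulting tracks are correlated with
sensitivity-corrected single-cell densities and regressed on covariate
tracks (transformed by x -> -1/x); frequently mutated genes feed a
cell-type odds ratio with Fisher's exact test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, pearsonr, spearmanr

from .contexts import Reference

log = logging.getLogger(__name__)

TUKEY_K = 1.5


def remove_hypermutators(sample_counts: pd.Series) -> tuple[pd.Series, list]:
    """Drop samples above Tukey's upper fence Q3 + 1.5*IQR.

    With fewer than 4 samples no removal is attempted (warning).  Returns
    (retained counts, removed sample ids).
    """
    if len(sample_counts) < 4:
        log.warning("fewer than 4 samples; hypermutator removal skipped")
        return sample_counts, []
    q1, q3 = np.percentile(sample_counts.to_numpy(), [25, 75])
    fence = q3 + TUKEY_K * (q3 - q1)
    removed = sample_counts.index[sample_counts > fence].tolist()
    return sample_counts.drop(removed), removed


def density_track(
    catalog: pd.DataFrame,
    windows_1mb: pd.DataFrame,
    reference: Reference,
    drop_hypermutators: bool = True,
) -> pd.DataFrame:
    """Per-tumor-type normalized mutation density over retained 1 Mb windows.

    Each sample contributes its fraction of mutations per window; the track
    is the sum over samples.  Returns a DataFrame indexed by window gidx
    with one column per tumor type.
    """
    if catalog.empty:
        raise ValueError("empty tumor catalog")
    ret = windows_1mb[windows_1mb["retained"]]
    out = {}
    size = 1_000_000
    for ttype, tcat in catalog.groupby("tumor_type", sort=False):
        counts = tcat.groupby("sample").size()
        if drop_hypermutators:
            counts, removed = remove_hypermutators(counts)
            if removed:
                log.info("%s: removed %d hypermutators", ttype, len(removed))
            tcat = tcat[tcat["sample"].isin(counts.index)]
        gpos = reference.to_global(tcat["chrom"].to_numpy(), tcat["pos"].to_numpy())
        widx = gpos // size
        dens = np.zeros(len(windows_1mb))
        for _, scat in pd.DataFrame({"sample": tcat["sample"], "w": widx}).groupby(
            "sample", sort=False
        ):
            c = np.bincount(scat["w"].to_numpy(), minlength=len(windows_1mb)).astype(float)
            dens += c / c.sum()
        out[ttype] = dens[ret["gidx"].to_numpy()]
    return pd.DataFrame(out, index=ret["gidx"].to_numpy())


def cell_density_1mb(
    calls: pd.DataFrame,
    windows_1mb: pd.DataFrame,
    reference: Reference,
    W: pd.Series | None = None,
) -> pd.Series:
    """Single-cell-group mutation counts per retained 1 Mb window,
    optionally divided by a per-window group sensitivity W."""
    ret = windows_1mb[windows_1mb["retained"]]
    gpos = reference.to_global(calls["chrom"].to_numpy(), calls["pos"].to_numpy())
    widx = gpos // 1_000_000
    c = np.bincount(widx, minlength=len(windows_1mb)).astype(float)
    dens = pd.Series(c[ret["gidx"].to_numpy()], index=ret["gidx"].to_numpy())
    if W is not None:
        w = W.reindex(dens.index)
        if (w.fillna(0) <= 0).any():
            raise ValueError("non-positive sensitivity in retained windows")
        dens = dens / w
    return dens


def correlate_densities(
    cell_density: pd.Series,
    tumor_tracks: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlation of a single-cell density with each tumor-type track."""
    common = cell_density.index.intersection(tumor_tracks.index)
    if len(common) < 10:
        raise ValueError("fewer than 10 common windows")
    fn = pearsonr if method == "pearson" else spearmanr
    rows = []
    for ttype in tumor_tracks.columns:
        r, p = fn(cell_density.loc[common], tumor_tracks.loc[common, ttype])
        rows.append({"tumor_type": ttype, "r": float(r), "p": float(p), "n_windows": len(common)})
    return pd.DataFrame(rows)


def regress_on_covariates(
    tumor_track: pd.Series, covariates: pd.DataFrame
) -> pd.DataFrame:
    """R-squared of tumor density regressed on each covariate scaled by -1/x.

    Windows where the covariate is <= 0 are dropped (logged); a constant
    covariate raises.
    """
    rows = []
    for cov in covariates.columns:
        x = covariates[cov]
        common = tumor_track.index.intersection(x.index)
        x = x.loc[common]
        y = tumor_track.loc[common]
        keep = x > 0
        if (~keep).any():
            log.info("%s: dropped %d windows with non-positive covariate", cov, int((~keep).sum()))
        x, y = x[keep], y[keep]
        if x.nunique() <= 1:
            raise ValueError(f"degenerate (constant) covariate {cov}")
        t = -1.0 / x.to_numpy()
        X = np.column_stack([np.ones(len(t)), t])
        beta, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
        yhat = X @ beta
        ss_res = float(((y - yhat) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        rows.append({"covariate": cov, "r2": r2, "slope": float(beta[1]), "n_windows": len(t)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# frequently-mutated-gene odds ratios


def _genic_counts(calls: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Mutation count per gene by interval overlap (0-based half-open)."""
    counts = {}
    for chrom, gsub in genes.groupby("chrom", sort=False):
        sub = calls[calls["chrom"] == chrom]
        if sub.empty:
            continue
        starts = gsub["start"].to_numpy()
        ends = gsub["end"].to_numpy()
        names = gsub["name"].to_numpy()
        p0 = sub["pos"].to_numpy() - 1
        j = np.searchsorted(starts, p0, side="right") - 1
        inside = (j >= 0) & (p0 < ends[np.maximum(j, 0)])
        for g in names[j[inside]]:
            counts[g] = counts.get(g, 0) + 1
    return pd.Series(counts, dtype=int)


def top_mutated_genes(
    tumor_catalog: pd.DataFrame, genes: pd.DataFrame, n: int = 100
) -> pd.Index:
    """The n most tumor-mutated genes; ties broken by genomic order."""
    counts = _genic_counts(tumor_catalog, genes).reindex(genes["name"], fill_value=0)
    order = pd.DataFrame({"name": genes["name"], "count": counts.to_numpy()})
    order = order.sort_values(["count"], ascending=False, kind="stable")
    if n >= (order["count"] > -1).sum():
        raise ValueError("top-n must leave an out-group of genes")
    return pd.Index(order.head(n)["name"])


def gene_or(
    tumor_catalog: pd.DataFrame,
    ol_calls: pd.DataFrame,
    neuron_calls: pd.DataFrame,
    genes: pd.DataFrame,
    n: int = 100,
) -> dict:
    """Odds ratio of OL vs neuron genic mutations hitting the tumor's top-n
    most-mutated genes, with a two-sided Fisher exact p.

    OR = (OL in / OL out) / (neuron in / neuron out), counting only genic
    mutations.  A zero cell triggers a 0.5 continuity correction (flagged).
    """
    top = set(top_mutated_genes(tumor_catalog, genes, n=n))
    table = {}
    for label, calls in (("OL", ol_calls), ("neuron", neuron_calls)):
        per_gene = _genic_counts(calls, genes)
        in_top = int(per_gene.reindex(top, fill_value=0).sum())
        total = int(per_gene.sum())
        table[label] = (in_top, total - in_top)
    a, b = table["OL"]
    c, d = table["neuron"]
    flagged = 0 in (a, b, c, d)
    if flagged:
        a2, b2, c2, d2 = (x + 0.5 for x in (a, b, c, d))
        odds = (a2 / b2) / (c2 / d2)
    else:
        odds = (a / b) / (c / d)
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {
        "n_top_genes": n,
        "table": {"OL": (a, b), "neuron": (c, d)},
        "odds_ratio": float(odds),
        "fisher_p": float(p),
        "continuity_corrected": flagged,
    }


def gene_or_sweep(
    tumor_catalog: pd.DataFrame,
    ol_calls: pd.DataFrame,
    neuron_calls: pd.DataFrame,
    genes: pd.DataFrame,
    n_values=range(1, 501),
) -> pd.DataFrame:
    rows = []
    max_n = len(genes) - 1
    for n in n_values:
        if n > max_n:
            break
        res = gene_or(tumor_catalog, ol_calls, neuron_calls, genes, n=n)
        rows.append({"n": n, "odds_ratio": res["odds_ratio"], "fisher_p": res["fisher_p"]})
    return pd.DataFrame(rows)
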