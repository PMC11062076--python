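"""Genome-wide burden extrapolation and aging models.

A cell's genome-wide burden is its VAF-based call count times a
calls-to-burden scaling factor S (rescued calls are never extrapolated).
Burdens from MDA-amplified cells are additionally corrected by removing
the exposure attributable to the MDA artifact signature.  Aging models are
mixed-effects linear regressions of burden on age with a fixed
age x cell-type interaction and a per-individual random intercept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signatures import Spectrum, SignatureCatalog, fit_exposures

log = logging.getLogger(__name__)


def extrapolate_burden(scaling: float, n_vaf_calls: int) -> float:
    """Genome-wide burden = S x (number of VAF-based calls)."""
    if scaling <= 0:
        raise ValueError("burden scaling factor must be positive")
    if n_vaf_calls < 0:
        raise ValueError("negative call count")
    return scaling * n_vaf_calls


def burden_table(calls: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-cell SNV and indel burdens from VAF-based call counts.

    Uses the profile's V counts (authoritative) rather than re-counting the
    call table, so recurrence-filtered call tables can be passed without
    deflating burdens.
    """
    rows = []
    for _, p in profiles.iterrows():
        rows.append(
            {
                "cell": p["cell"],
                "burden_snv": extrapolate_burden(p["scaling_snv"], p["V_snv"]),
                "burden_indel": extrapolate_burden(p["scaling_indel"], p["V_indel"])
                if p.get("V_indel", 0) > 0 or p.get("scaling_indel", 0) > 0
                else 0.0,
            }
        )
    return pd.DataFrame(rows)


def correct_mda_burden(
    spectrum: Spectrum | np.ndarray,
    catalog: SignatureCatalog,
    artifact: np.ndarray,
    scaling: float,
    artifact_name: str = "MDA_artifact",
) -> float:
    """Artifact-corrected burden for an MDA-amplified cell.

    The (unscaled) spectrum is fit by NNLS to the active catalog augmented
    with the artifact signature; exposures are scaled to burden units and
    summed over everything except the artifact.
    """
    values = spectrum.values if isinstance(spectrum, Spectrum) else np.asarray(spectrum, float)
    if values.sum() == 0:
        raise ValueError("empty spectrum")
    if scaling <= 0:
        raise ValueError("scaling must be positive")
    art = np.asarray(artifact, dtype=float)
    art = art / art.sum()
    aug = SignatureCatalog(
        catalog.names + [artifact_name],
        np.column_stack([catalog.matrix, art]),
        kind=catalog.kind,
        provenance=catalog.provenance,
    )
    exposures, _ = fit_exposures(values, aug)
    return float(exposures.drop(artifact_name).sum() * scaling)


# ---------------------------------------------------------------------------
# aging models


@dataclass
class AgingModel:
    """Per-cell-type linear aging fit with per-individual random intercepts."""

    cell_types: list[str]
    slope: dict[str, float]
    intercept: dict[str, float]
    slope_ci: dict[str, tuple[float, float]]
    intercept_ci: dict[str, tuple[float, float]]
    slope_p: dict[str, float]
    intercept_p: dict[str, float]
    slope_diff_p: dict[tuple[str, str], float] = field(default_factory=dict)
    random_intercept_var: float = 0.0
    residual_var: float = 0.0
    method: str = "mixedlm"
    n_cells: int = 0
    n_individuals: int = 0

    def report(self) -> dict:
        return {
            "method": self.method,
            "n_cells": self.n_cells,
            "n_individuals": self.n_individuals,
            "random_intercept_var": self.random_intercept_var,
            "residual_var": self.residual_var,
            "cell_types": {
                ct: {
                    "slope": self.slope[ct],
                    "slope_ci": list(self.slope_ci[ct]),
                    "slope_p": self.slope_p[ct],
                    "intercept": self.intercept[ct],
                    "intercept_ci": list(self.intercept_ci[ct]),
                    "intercept_p": self.intercept_p[ct],
                }
                for ct in self.cell_types
            },
            "slope_diff_p": {f"{a}|{b}": p for (a, b), p in self.slope_diff_p.items()},
        }


def fit_aging(data: pd.DataFrame, response: str = "burden") -> AgingModel:
    """Fit ``response ~ age * cell_type`` with a per-individual random
    intercept; Wald (normal-approximation) tests and CIs per coefficient.

    Cells flagged as outliers are excluded.  If the random-effect variance
    collapses to zero or the mixed fit fails, falls back to OLS with
    heteroskedasticity-robust (HC3) errors; the fallback is recorded in
    ``method``.
    """
    import statsmodels.formula.api as smf

    df = data.copy()
    if "outlier" in df:
        df = df[df["outlier"] == "none"]
    df = df.dropna(subset=[response, "age"])
    if df["individual"].nunique() < 2:
        raise ValueError("need at least two individuals")
    if df["age"].nunique() < 3:
        raise ValueError("need at least three distinct ages")
    df = df.rename(columns={response: "_y"})
    cell_types = sorted(df["cell_type"].unique())
    # cell-type-specific intercepts and slopes in one parameterization
    formula = "_y ~ 0 + C(cell_type) + age:C(cell_type)"

    result = method = None
    if df["individual"].nunique() < len(df):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                md = smf.mixedlm(formula, df, groups=df["individual"])
                result = md.fit(reml=True)
                if not result.converged or np.isnan(result.bse).any():
                    result = None
                elif float(result.cov_re.iloc[0, 0]) < 1e-10:
                    result = None  # degenerate random effect: OLS is exact
                else:
                    method = "mixedlm"
            except Exception:  # singular fits on degenerate inputs
                result = None
    if result is None:
        ols = smf.ols(formula, df).fit(cov_type="HC3")
        result = ols
        method = "ols_hc3"
        re_var = 0.0
        resid_var = float(np.var(ols.resid, ddof=1)) if len(df) > 1 else 0.0
    else:
        re_var = float(result.cov_re.iloc[0, 0])
        resid_var = float(result.scale)

    params = result.params
    cov = result.cov_params()
    from scipy.stats import norm

    z = norm.ppf(0.975)

    def coef(name):
        est = float(params[name])
        se = float(np.sqrt(cov.loc[name, name]))
        p = 2 * norm.sf(abs(est) / se) if se > 0 else 0.0
        return est, (est - z * se, est + z * se), p

    slope, intercept, slope_ci, intercept_ci, slope_p, intercept_p = {}, {}, {}, {}, {}, {}
    for ct in cell_types:
        iname = f"C(cell_type)[{ct}]"
        sname = f"age:C(cell_type)[{ct}]"
        intercept[ct], intercept_ci[ct], intercept_p[ct] = coef(iname)
        slope[ct], slope_ci[ct], slope_p[ct] = coef(sname)

    slope_diff_p = {}
    for i, a in enumerate(cell_types):
        for b in cell_types[i + 1 :]:
            sa, sb = f"age:C(cell_type)[{a}]", f"age:C(cell_type)[{b}]"
            d = float(params[sa] - params[sb])
            var = float(cov.loc[sa, sa] + cov.loc[sb, sb] - 2 * cov.loc[sa, sb])
            if var > 0:
                slope_diff_p[(a, b)] = 2 * norm.sf(abs(d) / np.sqrt(var))
            else:
                slope_diff_p[(a, b)] = 0.0 if d != 0 else 1.0

    return AgingModel(
        cell_types=cell_types,
        slope=slope,
        intercept=intercept,
        slope_ci=slope_ci,
        intercept_ci=intercept_ci,
        slope_p=slope_p,
        intercept_p=intercept_p,
        slope_diff_p=slope_diff_p,
        random_intercept_var=re_var,
        residual_var=resid_var,
        method=method,
        n_cells=len(df),
        n_individuals=df["individual"].nunique(),
    )


def aging_input(profiles: pd.DataFrame, burdens: pd.DataFrame, which: str = "snv") -> pd.DataFrame:
    """Join profiles and a burden table into fit_aging's input format."""
    df = profiles.merge(burdens, on="cell")
    df["burden"] = df[f"burden_{which}"]
    return df[["cell", "individual", "age", "cell_type", "outlier", "burden"]]
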