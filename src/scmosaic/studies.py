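"""Reproducible recovery studies on the package's default synthetic cohorts.

Each driver simulates a cohort under the configured study conditions, runs
the ordinary analysis path (call tables -> burden extrapolation or NNLS
exposures -> outlier flagging -> mixed-effects aging fit) and returns the
recovered quantities.  They are deliberately thin: all scientific logic
lives in the analysis modules.
"""

from __future__ import annotations

import numpy as np

from . import burden as burden_mod
from . import callsets, signatures
from . import synthetic_data as sim


def _flagged_profiles(cohort, burdens, exposures=None):
    sbs19 = exposures["SBS19"] if exposures is not None and "SBS19" in exposures else None
    return callsets.flag_outliers(
        cohort.profiles, burdens.set_index("cell")["burden_snv"], sbs19
    )


def run_burden_study(seed: int) -> dict:
    """Total sSNV burden aging recovery under the default cohort conditions.

    Returns the fitted per-cell-type slopes, intercepts and the OL-over-
    neuron percent slope excess.
    """
    cfg = sim.SimConfig(seed=seed, simulate_indels=False)
    bundle = sim.generate_reference(cfg)
    cohort = sim.generate_cohort_calls(cfg, bundle)
    burdens = burden_mod.burden_table(cohort.calls, cohort.profiles)
    calls = callsets.annotate_channels(cohort.calls, bundle.reference)
    expo = signatures.cell_exposures(calls, cohort.profiles, signatures.synthetic_sbs_catalog())
    profiles = _flagged_profiles(cohort, burdens, expo)
    model = burden_mod.fit_aging(burden_mod.aging_input(profiles, burdens, "snv"))
    slope_ol, slope_n = model.slope["OL"], model.slope["neuron"]
    return {
        "slope_OL": slope_ol,
        "slope_neuron": slope_n,
        "intercept_OL": model.intercept["OL"],
        "intercept_neuron": model.intercept["neuron"],
        "pct_excess": 100.0 * (slope_ol / slope_n - 1.0),
        "slope_diff_p": model.slope_diff_p[("OL", "neuron")],
        "model": model,
    }


def run_exposure_study(seed: int) -> dict:
    """SBS signature-exposure aging recovery with per-signature yearly rates."""
    cfg = sim.exposure_study_config(seed=seed)
    bundle = sim.generate_reference(cfg)
    cohort = sim.generate_cohort_calls(cfg, bundle)
    burdens = burden_mod.burden_table(cohort.calls, cohort.profiles)
    calls = callsets.annotate_channels(cohort.calls, bundle.reference)
    expo = signatures.cell_exposures(calls, cohort.profiles, signatures.synthetic_sbs_catalog())
    profiles = _flagged_profiles(cohort, burdens, expo)
    models = signatures.exposure_aging(expo, profiles)
    return {
        "SBS5_OL": models["SBS5"].slope["OL"],
        "SBS1_OL": models["SBS1"].slope["OL"],
        "SBS16_neuron": models["SBS16"].slope["neuron"],
        "models": models,
    }


def run_indel_study(seed: int) -> dict:
    """Indel burden and ID-signature aging recovery (totals 2.1 / 2.9 per
    year; per-signature rates as configured)."""
    cfg = sim.indel_study_config(seed=seed)
    bundle = sim.generate_reference(cfg)
    cohort = sim.generate_cohort_calls(cfg, bundle)
    burdens = burden_mod.burden_table(cohort.calls, cohort.profiles)
    profiles = _flagged_profiles(cohort, burdens)
    model = burden_mod.fit_aging(burden_mod.aging_input(profiles, burdens, "indel"))
    calls = callsets.annotate_channels(cohort.calls, bundle.reference)
    expo = signatures.cell_exposures(calls, cohort.profiles, signatures.synthetic_id_catalog())
    models = signatures.exposure_aging(expo, profiles)
    return {
        "indel_slope_OL": model.slope["OL"],
        "indel_slope_neuron": model.slope["neuron"],
        "ID9_OL": models["ID9"].slope["OL"],
        "model": model,
        "models": models,
    }


def seeds_from(master_seed: int, n: int) -> list[int]:
    """Derive n distinct sub-seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
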