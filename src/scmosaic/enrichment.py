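"""Regional mutation enrichment with a spectrum-preserving permutation null.

The null distribution shuffles each cell's calls over the cell's eligible
genome (sites meeting the minimum depth requirement), preserving both the
number of calls and their mutation channels: an SNV is re-placed only at
sites whose reference trinucleotide context admits its SBS96 channel; a
1 bp indel only at homopolymer sites matching its ID83 channel, with a
logged uniform fallback for channels without indexed sites.

Observed counts are divided by the group sensitivity W per region, then
renormalized so the adjusted counts sum to the observed total (the null is
uniform over the eligible genome and needs no adjustment).  Enrichment is
the corrected count over the permutation-mean count; two-sided p-values
count permutations whose |log enrichment| exceeds the observed value,
floored at 1/n_iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contexts import Reference, N_CONTEXTS, channel_context
from .regions import RegionSet, GenomeMask
from .sensitivity import region_sensitivity, group_sensitivity

log = logging.getLogger(__name__)

DEFAULT_N_PERMUTATIONS = 10_000
_ITER_BLOCK = 1000  # permutation iterations processed per vectorized block


@dataclass
class EligibleSites:
    """Context-partitioned eligible genome for permutation placement.

    `by_key` maps a context key (SBS96: pyrimidine trinucleotide context id
    0..31; ID83: channel id) to the global positions of eligible sites
    admitting it; `fallback` is the full eligible site list used when a key
    has no indexed sites.
    """

    by_key: dict[int, np.ndarray]
    fallback: np.ndarray

    @classmethod
    def snv_sites(cls, reference: Reference, mask: GenomeMask | None = None) -> "EligibleSites":
        sites = reference.context_site_index()
        if mask is not None:
            keep = mask.alignable
            sites = [s[keep[s // 100]] for s in sites]
        allsites = np.sort(np.concatenate(sites)) if sites else np.array([], dtype=np.int64)
        return cls({k: s for k, s in enumerate(sites)}, allsites)

    @classmethod
    def indel_sites(cls, reference: Reference, mask: GenomeMask | None = None) -> "EligibleSites":
        """Index 1 bp del/ins channels at homopolymer runs; longer events
        fall back to uniform placement over the eligible genome."""
        from .contexts import ID83_CHANNELS

        by_key: dict[int, list] = {}
        for chrom in reference.contigs:
            seq = reference.seqs[chrom]
            off = reference.offset(chrom)
            change = np.flatnonzero(np.diff(seq) != 0)
            run_starts = np.concatenate([[0], change + 1])
            run_ends = np.concatenate([change + 1, [len(seq)]])
            keep = run_starts > 0
            for s, e in zip(run_starts[keep], run_ends[keep]):
                L = e - s
                b = chr(seq[s])
                base = "C" if b in "CG" else "T"
                g = off + s
                del_ch = ID83_CHANNELS.index(f"1:Del:{base}:{min(L, 6) - 1}")
                ins_ch = ID83_CHANNELS.index(f"1:Ins:{base}:{min(L, 5)}")
                by_key.setdefault(del_ch, []).append(g)
                by_key.setdefault(ins_ch, []).append(g)
        arrs = {k: np.array(v, dtype=np.int64) for k, v in by_key.items()}
        n = reference.total_length
        fallback = np.arange(1, n - 1, dtype=np.int64)
        if mask is not None:
            keep_mask = mask.alignable
            arrs = {k: v[keep_mask[v // 100]] for k, v in arrs.items()}
            fallback = fallback[keep_mask[fallback // 100]]
        return cls(arrs, fallback)

    def sites_for(self, key: int) -> np.ndarray:
        s = self.by_key.get(int(key))
        if s is None or len(s) == 0:
            log.warning("no eligible sites for context key %d; uniform fallback", key)
            return self.fallback
        return s


def _call_keys(calls: pd.DataFrame, variant_class: str) -> np.ndarray:
    if variant_class == "SNV":
        ch = calls["sbs96_channel"].to_numpy()
        if (ch < 0).any():
            raise ValueError("calls must carry SBS96 channels (annotate first)")
        return np.array([channel_context(int(c)) for c in ch])
    ch = calls["id83_channel"].to_numpy()
    if (ch < 0).any():
        raise ValueError("calls must carry ID83 channels (annotate first)")
    return ch.astype(np.int64)


@dataclass
class PermutationNull:
    region_ids: list
    counts: np.ndarray  # (n_iterations, n_regions)
    channel_counts: np.ndarray | None = None  # (n_iterations, n_regions, n_channels)

    @property
    def n_iterations(self) -> int:
        return self.counts.shape[0]

    def mean(self) -> np.ndarray:
        return self.counts.mean(axis=0)


def permute_calls(
    calls: pd.DataFrame,
    regionset: RegionSet,
    eligible: EligibleSites | dict[str, EligibleSites],
    n_iterations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator = 0,
    variant_class: str = "SNV",
    collect_channels: bool = False,
) -> PermutationNull:
    """Spectrum-preserving permutation null counts per region.

    `eligible` is a single EligibleSites (shared across cells) or a
    per-cell dict.  Each iteration re-places every call uniformly over the
    eligible sites matching its channel context and tallies counts per
    region of `regionset`.
    """
    if len(calls) == 0:
        raise ValueError("no calls to permute")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keys = _call_keys(calls, variant_class)
    cells = calls["cell"].to_numpy()
    n_reg = len(regionset.ids)
    counts = np.zeros((n_iterations, n_reg), dtype=np.int64)
    n_chan = 96 if variant_class == "SNV" else 83
    chan = (
        calls["sbs96_channel" if variant_class == "SNV" else "id83_channel"].to_numpy()
        if collect_channels
        else None
    )
    chan_counts = (
        np.zeros((n_iterations, n_reg, n_chan), dtype=np.int32) if collect_channels else None
    )
    shared = isinstance(eligible, EligibleSites)
    group_cols = keys if shared else pd.MultiIndex.from_arrays([cells, keys])
    df = pd.DataFrame({"key": keys, "cell": cells, "i": np.arange(len(keys))})
    group_by = ["key"] if shared else ["cell", "key"]
    for gname, grp in df.groupby(group_by, sort=False):
        key = gname[-1] if isinstance(gname, tuple) else gname
        elig = eligible if shared else eligible[grp["cell"].iloc[0]]
        sites = elig.sites_for(int(key))
        m = len(grp)
        idx = grp["i"].to_numpy()
        for b0 in range(0, n_iterations, _ITER_BLOCK):
            b = min(_ITER_BLOCK, n_iterations - b0)
            draws = sites[rng.integers(0, len(sites), (b, m))]
            codes = regionset.region_of_global(draws.ravel()).reshape(b, m)
            valid = codes >= 0
            it = np.repeat(np.arange(b0, b0 + b), m).reshape(b, m)
            np.add.at(counts, (it[valid], codes[valid]), 1)
            if collect_channels:
                ch = np.broadcast_to(chan[idx], (b, m))
                np.add.at(chan_counts, (it[valid], codes[valid], ch[valid]), 1)
    return PermutationNull(list(regionset.ids), counts, chan_counts)


def expected_null_counts(
    calls: pd.DataFrame,
    regionset: RegionSet,
    eligible: EligibleSites | dict[str, EligibleSites],
    variant_class: str = "SNV",
) -> pd.Series:
    """Exact permutation-mean counts per region (no sampling): each call
    contributes its region placement probabilities directly."""
    keys = _call_keys(calls, variant_class)
    cells = calls["cell"].to_numpy()
    shared = isinstance(eligible, EligibleSites)
    n_reg = len(regionset.ids)
    expected = np.zeros(n_reg)
    df = pd.DataFrame({"key": keys, "cell": cells})
    for gname, grp in df.groupby(["key"] if shared else ["cell", "key"], sort=False):
        key = gname[-1] if isinstance(gname, tuple) else gname
        elig = eligible if shared else eligible[grp["cell"].iloc[0]]
        sites = elig.sites_for(int(key))
        codes = regionset.region_of_global(sites)
        share = np.bincount(codes[codes >= 0], minlength=n_reg) / len(sites)
        expected += len(grp) * share
    return pd.Series(expected, index=list(regionset.ids))


# ---------------------------------------------------------------------------
# sensitivity adjustment and significance


def adjust_and_normalize(observed: pd.Series, W: pd.Series) -> pd.DataFrame:
    """Sensitivity-adjust observed counts and renormalize to the original
    total: A = N / W, corrected = (A / sum A) * sum N (so the corrected
    counts remain comparable to the unadjusted permutation null)."""
    obs = observed.astype(float)
    w = W.reindex(obs.index)
    bad = (w.fillna(0) <= 0) & (obs > 0)
    if bad.any():
        raise ValueError(f"zero/missing sensitivity in regions with mutations: {list(obs.index[bad])}")
    A = obs / w
    A = A.fillna(0.0)
    F = A / A.sum() if A.sum() > 0 else A
    corrected = F * obs.sum()
    return pd.DataFrame({"N": obs, "W": w, "A": A, "F": F, "corrected": corrected})


def enrichment_and_p(corrected: pd.Series, null: PermutationNull) -> pd.DataFrame:
    """Enrichment ratio and two-sided permutation p per region.

    E = corrected / mean(null counts); the null enrichment distribution is
    the *uncorrected* per-iteration count over the null mean; p is the
    fraction of iterations with |log E_i| > |log E|, floored at 1/n_iter.
    """
    if null.n_iterations < 1:
        raise ValueError("need at least one permutation iteration")
    mu = null.mean()
    if (mu <= 0).any():
        raise ValueError("permutation null mean is zero in some region")
    corr = corrected.reindex(null.region_ids).to_numpy(dtype=float)
    E = corr / mu
    with np.errstate(divide="ignore"):
        logE = np.abs(np.log(E))
        log_null = np.abs(np.log(null.counts / mu))
    exceed = (log_null > logE[None, :]).mean(axis=0)
    p = np.maximum(1.0 / null.n_iterations, exceed)
    return pd.DataFrame(
        {
            "region": null.region_ids,
            "corrected": corr,
            "null_mean": mu,
            "enrichment": E,
            "p": p,
            "n_iterations": null.n_iterations,
        }
    ).set_index("region")


def enrichment_analysis(
    calls: pd.DataFrame,
    germline: pd.DataFrame,
    profiles: pd.DataFrame,
    regionset: RegionSet,
    eligible: EligibleSites | dict[str, EligibleSites],
    reference: Reference,
    n_iterations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator = 0,
    variant_class: str = "SNV",
    use_rescue: bool = True,
    sensitivity_correction: bool = True,
    min_controls: int = 50,
) -> pd.DataFrame:
    """End-to-end regional enrichment for one group of cells.

    Observed counts use VAF-based plus rescued calls (`use_rescue=True`);
    sensitivity is estimated from the leave-one-out germline controls of
    the same cells, combined with call-count weights, and applied to the
    observed counts before comparison against the permutation null.
    """
    from .regions import assign_regions

    df = calls[calls["variant_class"] == variant_class].copy()
    if not use_rescue:
        df = df[df["mode"] == "vaf"]
    df = df[df["cell"].isin(set(profiles["cell"]))]
    df["region"] = assign_regions(df, regionset, reference)
    observed = (
        df.dropna(subset=["region"]).groupby("region", sort=False).size()
        .reindex(regionset.ids, fill_value=0)
    )
    if sensitivity_correction:
        germ = germline[
            (germline["variant_class"] == variant_class)
            & germline["cell"].isin(set(profiles["cell"]))
        ].copy()
        germ["region"] = assign_regions(germ, regionset, reference)
        germ = germ.dropna(subset=["region"])
        est = region_sensitivity(germ, min_controls=min_controls)
        W = group_sensitivity(
            est,
            profiles,
            mode="vaf_plus_rescue" if use_rescue else "vaf_only",
            variant_class=variant_class,
        ).set_index("region")["W"]
    else:
        W = pd.Series(1.0, index=observed.index)
    adj = adjust_and_normalize(observed, W)
    null = permute_calls(
        df, regionset, eligible, n_iterations=n_iterations, seed=seed,
        variant_class=variant_class,
    )
    res = enrichment_and_p(adj["corrected"], null)
    res["N"] = observed
    res["W"] = W
    res["uncorrected_enrichment"] = observed.to_numpy(dtype=float) / res["null_mean"]
    return res


def signature_exposure_enrichment(
    calls: pd.DataFrame,
    catalog,
    regionset: RegionSet,
    eligible: EligibleSites | dict[str, EligibleSites],
    reference: Reference,
    n_iterations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator = 0,
    low_count_threshold: int = 30,
) -> pd.DataFrame:
    """Per-signature exposure enrichment over (coarse) regions.

    Only VAF-based calls are used; region spectra are fit by NNLS to the
    active catalog and the exposure replaces the mutation count, both for
    the observed calls and for every permutation iteration.  No sensitivity
    adjustment is applied (regions are meant to be large, e.g. 3 quantiles).
    """
    from .regions import assign_regions
    from .signatures import fit_exposures

    kind = catalog.kind
    variant_class = "SNV" if kind == "SBS96" else "indel"
    chan_col = "sbs96_channel" if kind == "SBS96" else "id83_channel"
    n_chan = 96 if kind == "SBS96" else 83
    df = calls[(calls["variant_class"] == variant_class) & (calls["mode"] == "vaf")].copy()
    df["region"] = assign_regions(df, regionset, reference)
    df = df.dropna(subset=["region"])
    null = permute_calls(
        df, regionset, eligible, n_iterations=n_iterations, seed=seed,
        variant_class=variant_class, collect_channels=True,
    )
    rows = []
    n_reg = len(regionset.ids)
    null_exp = np.zeros((null.n_iterations, n_reg, len(catalog.names)))
    for r in range(n_reg):
        for it in range(null.n_iterations):
            exp, _ = fit_exposures(null.channel_counts[it, r].astype(float), catalog)
            null_exp[it, r] = exp.to_numpy()
    for r, rid in enumerate(regionset.ids):
        sub = df[df["region"] == rid]
        spec = np.bincount(
            sub[chan_col].to_numpy()[sub[chan_col].to_numpy() >= 0], minlength=n_chan
        ).astype(float)
        obs_exp, _ = fit_exposures(spec, catalog)
        mu = null_exp[:, r, :].mean(axis=0)
        for si, sig in enumerate(catalog.names):
            if mu[si] <= 0:
                E, p = np.nan, np.nan
            else:
                E = obs_exp.iloc[si] / mu[si]
                with np.errstate(divide="ignore"):
                    le = abs(np.log(E)) if E > 0 else np.inf
                    ln = np.abs(np.log(null_exp[:, r, si] / mu[si]))
                p = max(1.0 / null.n_iterations, float((ln > le).mean()))
            rows.append(
                {
                    "region": rid,
                    "signature": sig,
                    "exposure": float(obs_exp.iloc[si]),
                    "null_mean_exposure": float(mu[si]),
                    "enrichment": E,
                    "p": p,
                    "n_calls": len(sub),
                    "low_count": len(sub) < low_count_threshold,
                }
            )
    return pd.DataFrame(rows)
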