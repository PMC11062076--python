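"""Mutational spectra and signature exposures.

Spectra are per-cell (or per-region) SBS96 / ID83 channel histograms,
optionally scaled so the spectrum sums to the extrapolated genome-wide
burden, and — for indels — divided elementwise by a per-channel detection
sensitivity correction vector.  Exposures are obtained by non-negative
least squares against a catalog of unit signatures.

The shipped catalogs are SYNTHETIC: deterministic stand-ins with the
qualitative character of the correspondingly named COSMIC signatures
(e.g. the SBS1-like column concentrates on C>T at NpCpG, the SBS16-like
column on T>C).  They exist so that simulation, fitting and tests run with
no external downloads; real analyses should load a published catalog with
:func:`load_catalog`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import ranksums

from .contexts import SBS96_CHANNELS, ID83_CHANNELS, Reference

KIND_SIZES = {"SBS96": 96, "ID83": 83}


@dataclass
class Spectrum:
    kind: str  # SBS96 | ID83
    values: np.ndarray
    scale: float = 1.0
    correction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in KIND_SIZES:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if len(self.values) != KIND_SIZES[self.kind]:
            raise ValueError(f"{self.kind} spectrum must have {KIND_SIZES[self.kind]} channels")
        if (self.values < 0).any():
            raise ValueError("spectrum values must be non-negative")

    @property
    def channels(self) -> tuple[str, ...]:
        return SBS96_CHANNELS if self.kind == "SBS96" else ID83_CHANNELS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel": self.channels, "value": self.values})


@dataclass
class SignatureCatalog:
    names: list[str]
    matrix: np.ndarray  # channels x signatures, columns sum to 1
    kind: str = "SBS96"
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (KIND_SIZES[self.kind], len(self.names)):
            raise ValueError("catalog matrix shape does not match names/kind")
        if (self.matrix < 0).any():
            raise ValueError("signature entries must be non-negative")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1) > 1e-9):
            raise ValueError("signature columns must sum to 1")

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        channels = SBS96_CHANNELS if self.kind == "SBS96" else ID83_CHANNELS
        return pd.DataFrame(self.matrix, index=list(channels), columns=self.names)


def load_catalog(path, kind: str = "SBS96", provenance: str = "file") -> SignatureCatalog:
    """Load a catalog TSV: first column channel names, one column per signature."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    expected = list(SBS96_CHANNELS if kind == "SBS96" else ID83_CHANNELS)
    df = df.reindex(expected)
    if df.isna().any().any():
        raise ValueError("catalog missing channels")
    m = df.to_numpy(dtype=float)
    m = m / m.sum(axis=0, keepdims=True)
    return SignatureCatalog(list(df.columns), m, kind=kind, provenance=provenance)


# ---------------------------------------------------------------------------
# synthetic catalogs


def _norm(v: np.ndarray) -> np.ndarray:
    return v / v.sum()


def synthetic_sbs_catalog() -> SignatureCatalog:
    """Five SBS signatures with distinct, nearly orthogonal supports."""
    idx = {name: i for i, name in enumerate(SBS96_CHANNELS)}
    cols = {}
    # SBS1-like: C>T at NpCpG, small flat background
    v = np.full(96, 0.03 / 92)
    for f in "ACGT":
        v[idx[f"{f}[C>T]G"]] = 0.97 / 4
    cols["SBS1"] = _norm(v)
    # SBS5-like: broad, featureless clock-like background over all channels
    t = np.arange(96)
    cols["SBS5"] = _norm(1.0 + 0.4 * np.sin(t / 5.0) + 0.2 * np.cos(t / 2.0))
    # SBS16-like: T>C dominated
    v = np.full(96, 0.08 / 80)
    for f in "ACGT":
        for th in "ACGT":
            v[idx[f"{f}[T>C]{th}"]] = 0.92 / 16
    cols["SBS16"] = _norm(v)
    # SBS19-like: C>G dominated
    v = np.full(96, 0.10 / 80)
    for f in "ACGT":
        for th in "ACGT":
            v[idx[f"{f}[C>G]{th}"]] = 0.90 / 16
    cols["SBS19"] = _norm(v)
    # SBS32-like: C>T away from CpG
    v = np.full(96, 0.06 / 84)
    for f in "ACGT":
        for th in "ACT":
            v[idx[f"{f}[C>T]{th}"]] = 0.94 / 12
    cols["SBS32"] = _norm(v)
    names = sorted(cols)
    return SignatureCatalog(names, np.column_stack([cols[n] for n in names]), "SBS96")


def synthetic_id_catalog() -> SignatureCatalog:
    """Six ID signatures supported on channels the simulator can place."""
    idx = {name: i for i, name in enumerate(ID83_CHANNELS)}
    cols: dict[str, np.ndarray] = {}

    def make(weights: dict[str, float]) -> np.ndarray:
        v = np.zeros(83)
        for name, w in weights.items():
            v[idx[name]] = w
        return _norm(v)

    # ID9-like: 1 bp T deletions at short homopolymers
    cols["ID9"] = make({"1:Del:T:0": 0.40, "1:Del:T:1": 0.35, "1:Del:T:2": 0.25})
    # ID5-like: 1 bp T deletions at long homopolymers
    cols["ID5"] = make({"1:Del:T:3": 0.40, "1:Del:T:4": 0.30, "1:Del:T:5": 0.30})
    # ID2-like: 1 bp T insertions at long homopolymers
    cols["ID2"] = make({"1:Ins:T:3": 0.40, "1:Ins:T:4": 0.30, "1:Ins:T:5": 0.30})
    # ID4-like: >=2 bp deletions without flanking repeats
    cols["ID4"] = make(
        {"2:Del:R:0": 0.40, "3:Del:R:0": 0.30, "4:Del:R:0": 0.20, "5:Del:R:0": 0.10}
    )
    # ID8-like: longer deletions with a microhomology component
    cols["ID8"] = make(
        {"5:Del:R:0": 0.30, "4:Del:R:0": 0.30, "2:Del:M:1": 0.20, "3:Del:M:1": 0.20}
    )
    # ID11-like: 1 bp C events
    cols["ID11"] = make(
        {"1:Del:C:0": 0.30, "1:Del:C:1": 0.30, "1:Ins:C:1": 0.20, "1:Ins:C:2": 0.20}
    )
    names = sorted(cols, key=lambda n: int(n[2:]))
    return SignatureCatalog(names, np.column_stack([cols[n] for n in names]), "ID83")


# ---------------------------------------------------------------------------
# spectra and fitting


def build_spectrum(
    calls: pd.DataFrame,
    reference: Reference | None = None,
    kind: str = "SBS96",
    scale: float = 1.0,
    id83_correction: np.ndarray | None = None,
    vaf_only: bool = True,
) -> Spectrum:
    """Channel histogram of a call table, scaled to burden units.

    Signature-rescued calls are excluded by default (`vaf_only`): they were
    selected partly on their signature and would bias the spectrum.  The
    `scale` factor is the cell's calls-to-burden scaling, so the scaled
    spectrum sums to the extrapolated burden.  ID83 spectra are divided
    elementwise by `id83_correction` (per-channel detection sensitivity,
    default identity).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    df = calls
    if vaf_only and "mode" in df:
        df = df[df["mode"] == "vaf"]
    want = "SNV" if kind == "SBS96" else "indel"
    col = "sbs96_channel" if kind == "SBS96" else "id83_channel"
    if "variant_class" in df:
        df = df[df["variant_class"] == want]
    if col not in df:
        if reference is None:
            raise ValueError(f"calls lack {col}; pass a reference to annotate")
        from .callsets import annotate_channels

        df = annotate_channels(df, reference)
    ch = df[col].to_numpy()
    ch = ch[ch >= 0]
    counts = np.bincount(ch, minlength=KIND_SIZES[kind]).astype(float)
    if kind == "ID83" and id83_correction is not None:
        corr = np.asarray(id83_correction, dtype=float)
        if len(corr) != 83 or (corr <= 0).any():
            raise ValueError("id83 correction vector must be 83 positive values")
        counts = counts / corr
    return Spectrum(kind, counts * scale, scale=scale, correction=id83_correction)


def fit_exposures(spectrum: Spectrum | np.ndarray, catalog: SignatureCatalog) -> tuple[pd.Series, float]:
    """Non-negative least-squares exposures: argmin ||s - C x||, x >= 0."""
    values = spectrum.values if isinstance(spectrum, Spectrum) else np.asarray(spectrum, float)
    if len(catalog.names) == 0:
        raise ValueError("empty catalog")
    x, resid = nnls(catalog.matrix, values)
    return pd.Series(x, index=catalog.names), float(resid)


def cosine_similarity(a: Spectrum | np.ndarray, b: Spectrum | np.ndarray) -> float:
    if isinstance(a, Spectrum) and isinstance(b, Spectrum) and a.kind != b.kind:
        raise ValueError("spectra of different kinds are not comparable")
    va = a.values if isinstance(a, Spectrum) else np.asarray(a, float)
    vb = b.values if isinstance(b, Spectrum) else np.asarray(b, float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(va, vb) / (na * nb))


def cell_exposures(
    calls: pd.DataFrame,
    profiles: pd.DataFrame,
    catalog: SignatureCatalog,
    reference: Reference | None = None,
    id83_correction: np.ndarray | None = None,
) -> pd.DataFrame:
    """Burden-scaled per-cell exposures: one row per cell, one column per
    signature, from NNLS fits of each cell's VAF-based spectrum."""
    kind = catalog.kind
    scale_col = "scaling_snv" if kind == "SBS96" else "scaling_indel"
    rows = {}
    for _, prof in profiles.iterrows():
        sub = calls[calls["cell"] == prof["cell"]]
        spec = build_spectrum(
            sub, reference, kind=kind, scale=float(prof[scale_col]),
            id83_correction=id83_correction,
        )
        exp, _ = fit_exposures(spec, catalog)
        rows[prof["cell"]] = exp
    out = pd.DataFrame(rows).T
    out.index.name = "cell"
    return out


def exposure_aging(exposures: pd.DataFrame, profiles: pd.DataFrame):
    """Per-signature aging models (mixed model with per-individual random
    intercepts), with the burden-scaled exposure as the response.

    Returns {signature name: AgingModel}.
    """
    from .burden import fit_aging

    out = {}
    meta = profiles.set_index("cell")
    for sig in exposures.columns:
        df = meta.loc[exposures.index, ["individual", "age", "cell_type", "outlier"]].copy()
        df["burden"] = exposures[sig].to_numpy()
        df = df.reset_index()
        out[sig] = fit_aging(df)
    return out


def transcribed_strand_bias(
    calls: pd.DataFrame, genes: pd.DataFrame, sub_from: str = "T", sub_to: str = "C"
) -> tuple[float, pd.DataFrame]:
    """Two-sided rank-sum test for transcribed-strand bias of one base change.

    For each cell, counts mutations of the given pyrimidine-strand change
    (default T>C) falling in genes, split by whether the mutated pyrimidine
    lies on the transcribed (template) strand.  A gene on '+' is transcribed
    from the '-' template, so a T>C recorded on the reference '+' strand
    (ref base T) is on the template of '-' genes.
    """
    g = genes.sort_values(["chrom", "start"])
    is_fwd_change = calls["ref"].isin([sub_from]) & calls["alt"].isin([sub_to])
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    is_rev_change = calls["ref"].isin([comp[sub_from]]) & calls["alt"].isin([comp[sub_to]])
    rows = []
    for chrom, gs in g.groupby("chrom", sort=False):
        sub = calls[(calls["chrom"] == chrom) & (is_fwd_change | is_rev_change)]
        if sub.empty:
            continue
        starts = gs["start"].to_numpy()
        ends = gs["end"].to_numpy()
        strands = gs["strand"].to_numpy()
        j = np.searchsorted(starts, sub["pos"].to_numpy() - 1, side="right") - 1
        inside = (j >= 0) & ((sub["pos"].to_numpy() - 1) < ends[np.maximum(j, 0)])
        sub = sub[inside]
        j = j[inside]
        on_ref_strand = sub["ref"].isin([sub_from]).to_numpy()
        gene_plus = strands[j] == "+"
        # pyrimidine on reference strand & gene on '+': pyrimidine is on the
        # non-template strand -> untranscribed; all other combinations flip.
        transcribed = on_ref_strand != gene_plus
        rows.append(pd.DataFrame({"cell": sub["cell"], "transcribed": transcribed}))
    if not rows:
        raise ValueError("no qualifying mutations in genes")
    df = pd.concat(rows)
    per_cell = df.groupby(["cell", "transcribed"]).size().unstack(fill_value=0)
    t = per_cell.get(True, pd.Series(0, index=per_cell.index))
    u = per_cell.get(False, pd.Series(0, index=per_cell.index))
    stat = ranksums(t, u)
    return float(stat.pvalue), per_cell
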