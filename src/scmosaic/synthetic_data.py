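"""Synthetic single-cell somatic mutation cohorts.

Generates every input the analysis pipeline consumes — reference genome,
gene model, covariate tracks, per-cell somatic call tables, leave-one-out
germline control tables, depth summaries, lineage-pair read support and
tumor catalogs — with the statistical structure the downstream analyses
assume:

* per-cell true mutation counts follow a linear aging model
  ``E[burden] = intercept + slope * age + b_individual`` with a Gaussian
  per-individual random intercept and Poisson cell-level noise;
* mutation channels are drawn from a per-cell-type signature mixture,
  either as fixed fractions or as per-signature yearly rates;
* positions are placed at reference sites whose trinucleotide (SBS96) or
  homopolymer/repeat (ID83) context admits the drawn channel, optionally
  weighted by a region-dependent mutagenesis multiplier;
* observed calls are a thinned subset of the truth with region-dependent
  detection sensitivity, split into VAF-based and signature-rescued calls;
* leave-one-out germline control sites are detected with the same
  region-dependent VAF sensitivity, so the sensitivity module can recover
  the configured detection model;
* lineage pairs share an injected set of pre-split mutations, with
  cross-cell read support subject to configurable allelic dropout.

Every latent quantity is kept in a truth record for testing; analysis
modules never read it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .contexts import (
    BASES,
    Reference,
    N_CONTEXTS,
    SBS96_CHANNELS,
    ID83_CHANNELS,
    channel_alt_index,
    channel_context,
    id83_channel,
)

# ---------------------------------------------------------------------------
# configuration


@dataclass
class AgingParams:
    """Linear aging model for one cell type and variant class."""

    slope: float  # mutations / year
    intercept: float  # mutations at birth
    random_sd: float = 0.0  # s.d. of the per-individual random intercept

    def validate(self) -> None:
        if self.slope < 0 or self.intercept < 0 or self.random_sd < 0:
            raise ValueError("aging parameters must be non-negative")


@dataclass
class SignatureMix:
    """Signature composition for one cell type and variant class.

    In ``fraction`` mode, `weights` are age-independent mixture fractions
    (must sum to 1).  In ``rate`` mode, `weights` are per-signature yearly
    rates; the implied total slope is their sum and the per-signature
    intercept is the cell type's aging intercept split by `intercept_frac`
    (defaults to the rate shares).
    """

    weights: dict[str, float]
    mode: str = "fraction"  # fraction | rate
    intercept_frac: dict[str, float] | None = None

    def validate(self) -> None:
        if self.mode not in ("fraction", "rate"):
            raise ValueError(f"unknown signature mode {self.mode!r}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("signature weights must be non-negative")
        if self.mode == "fraction":
            if abs(sum(self.weights.values()) - 1.0) > 1e-9:
                raise ValueError("signature fractions must sum to 1")


@dataclass
class DetectionModel:
    """Region-dependent detection.  Total detection probability at a site is
    ``baseline * multiplier(region quantile)``; among detected calls a
    fraction `rescue_fraction` are signature-rescued rather than VAF-based.
    Leave-one-out germline controls are detected with the VAF-based
    probability ``baseline * multiplier * (1 - rescue_fraction)``.
    """

    baseline: float = 0.48
    baseline_indel: float = 0.41
    rescue_fraction: float = 0.2
    region_multipliers: dict[int, float] = field(default_factory=dict)  # quantile -> mult
    n_quantiles: int = 10

    def validate(self) -> None:
        for v in (self.baseline, self.baseline_indel, self.rescue_fraction):
            if not 0.0 <= v <= 1.0:
                raise ValueError("detection fractions must be in [0, 1]")
        for q, m in self.region_multipliers.items():
            if not (0.0 <= self.baseline * m <= 1.0):
                raise ValueError(f"detection probability outside [0,1] in quantile {q}")


@dataclass
class LineagePair:
    individual: str
    shared_burden: int
    cell_type: str = "OL"
    split_age: float | None = None

    def validate(self) -> None:
        if self.shared_burden < 0:
            raise ValueError("shared burden must be non-negative")


@dataclass
class TumorTypeModel:
    n_samples: int = 20
    mean_burden: float = 5000.0
    hypermutator_fraction: float = 0.0
    hypermutator_fold: float = 20.0
    coupling: float = 0.0  # log-linear coupling of density to the bias covariate


@dataclass
class CohortEntry:
    individual: str
    age: float
    cells: dict[str, int]  # cell type -> number of cells


@dataclass
class SimConfig:
    """Full specification of one synthetic study."""

    genome_length: int = 1_000_000  # bp per chromosome
    n_chromosomes: int = 2
    gene_fraction: float = 0.4
    homopolymer_spacing: int = 300  # one seeded homopolymer per this many bp
    cohort: list[CohortEntry] = field(default_factory=lambda: default_cohort())
    aging_snv: dict[str, AgingParams] = field(
        default_factory=lambda: {
            "OL": AgingParams(29.0, 165.0, 25.0),
            "neuron": AgingParams(16.0, 107.0, 20.0),
        }
    )
    aging_indel: dict[str, AgingParams] = field(
        default_factory=lambda: {
            "OL": AgingParams(2.1, 10.0, 2.0),
            "neuron": AgingParams(2.9, 10.0, 2.0),
        }
    )
    sbs_mix: dict[str, SignatureMix] = field(
        default_factory=lambda: {
            "OL": SignatureMix(
                {"SBS1": 2.77 / 29, "SBS5": 22.7 / 29, "SBS16": 0.18 / 29, "SBS32": 3.35 / 29}
            ),
            "neuron": SignatureMix(
                {"SBS1": 0.29 / 16.79, "SBS5": 14.5 / 16.79, "SBS16": 2.0 / 16.79}
            ),
        }
    )
    id_mix: dict[str, SignatureMix] = field(
        default_factory=lambda: {
            "OL": SignatureMix(
                {"ID2": 0.1 / 2.1, "ID4": 0.09 / 2.1, "ID5": 0.72 / 2.1,
                 "ID8": 0.40 / 2.1, "ID9": 0.69 / 2.1, "ID11": 0.10 / 2.1}
            ),
            "neuron": SignatureMix(
                {"ID2": 0.02 / 2.9, "ID4": 1.20 / 2.9, "ID5": 0.60 / 2.9,
                 "ID8": 0.73 / 2.9, "ID9": 0.25 / 2.9, "ID11": 0.10 / 2.9}
            ),
        }
    )
    simulate_indels: bool = True
    region_bias: dict[int, float] = field(default_factory=dict)  # quantile -> multiplier
    bias_n_quantiles: int = 10
    detection: DetectionModel = field(default_factory=DetectionModel)
    germline_spacing: int = 1500  # one het control site per this many bp
    germline_depth_mean: float = 30.0
    min_depth_snv: int = 6
    min_depth_indel: int = 10
    accessible_fraction: float = 0.9
    lineage_pairs: list[LineagePair] = field(default_factory=list)
    pair_dropout_private: float = 0.05  # shared site seen with 0 alt reads, good depth
    pair_dropout_indet: float = 0.10  # shared site with low depth / 1 alt read
    pair_depth_mean: float = 30.0
    tumor_model: dict[str, TumorTypeModel] = field(default_factory=dict)
    emit_pair_support: bool = False
    emit_depth: bool = False
    chemistry: dict[str, str] = field(default_factory=dict)  # cell type -> PTA/MDA
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length < 1e5:
            raise ValueError("genome_length must be at least 1e5 bp")
        if self.genome_length % 1000:
            raise ValueError("genome_length must be a multiple of the 1 kb window")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        known = {e.individual for e in self.cohort}
        for p in self.lineage_pairs:
            p.validate()
            if p.individual not in known:
                raise ValueError(f"lineage pair references unknown individual {p.individual}")
        for d in (self.aging_snv, self.aging_indel):
            for a in d.values():
                a.validate()
        for d in (self.sbs_mix, self.id_mix):
            for m in d.values():
                m.validate()
        self.detection.validate()
        for q, m in self.region_bias.items():
            if m < 0:
                raise ValueError("region bias multipliers must be non-negative")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def default_cohort() -> list[CohortEntry]:
    """Two-cell-type brain cohort: 13 donors (ages 0.4-83) contributing 5
    oligodendrocytes each; 19 donors contributing 3 neurons each, 12 of them
    shared with the OL set.
    """
    ol_ages = [0.4, 1.2, 5, 12, 18, 25, 33, 42, 49, 58, 66, 75, 83]
    extra_neuron_ages = [0.6, 8, 29, 45, 62, 77, 104]
    cohort = []
    for i, age in enumerate(ol_ages):
        cells = {"OL": 5}
        if i < 12:
            cells["neuron"] = 3
        cohort.append(CohortEntry(f"I{i + 1:02d}", float(age), cells))
    for j, age in enumerate(extra_neuron_ages):
        cohort.append(CohortEntry(f"I{len(ol_ages) + j + 1:02d}", float(age), {"neuron": 3}))
    return cohort


# ---------------------------------------------------------------------------
# reference, gene model, covariate tracks


@dataclass
class ReferenceBundle:
    reference: Reference
    genes: pd.DataFrame  # chrom, start, end, name, strand (BED, 0-based half-open)
    tracks: dict[str, pd.DataFrame]  # name -> chrom, start, end, value (bedGraph)
    categorical: pd.DataFrame  # chrom, start, end, state (BED)

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.reference.to_fasta(f"{outdir}/reference.fa")
        self.genes.to_csv(f"{outdir}/genes.bed", sep="\t", header=False, index=False)
        for name, tr in self.tracks.items():
            tr.to_csv(f"{outdir}/{name}.bedgraph", sep="\t", header=False, index=False)
        self.categorical.to_csv(
            f"{outdir}/chromatin_states.bed", sep="\t", header=False, index=False
        )


def _track_values(rng: np.random.Generator, n_windows: int, smooth: bool) -> np.ndarray:
    """Positive per-1kb-window covariate values, deterministic given rng state."""
    x = np.arange(n_windows)
    if smooth:
        base = 2.0 + np.sin(2 * np.pi * x / 199.0) + 0.5 * np.sin(2 * np.pi * x / 53.0)
    else:
        base = np.full(n_windows, 2.0)
    noise = rng.normal(0, 0.3, n_windows)
    return np.round(np.exp(base + noise), 4)


def generate_reference(config: SimConfig) -> ReferenceBundle:
    """Seeded reference genome with gene model and covariate tracks.

    Homopolymer runs (length 4-8) are planted at a configurable spacing so
    every 1 bp indel channel has placement sites; the rest of the sequence
    is i.i.d. uniform over ACGT.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = int(config.genome_length)
    seqs: dict[str, np.ndarray] = {}
    ascii_bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for ci in range(config.n_chromosomes):
        seq = ascii_bases[rng.integers(0, 4, L)]
        n_hp = L // config.homopolymer_spacing
        starts = rng.integers(10, L - 20, n_hp)
        lens = rng.integers(4, 9, n_hp)
        bases = ascii_bases[rng.integers(0, 4, n_hp)]
        for s, ln, b in zip(starts, lens, bases):
            seq[s : s + ln] = b
        seqs[f"chr{ci + 1}"] = seq
    ref = Reference(seqs)

    # gene model: alternating gene/intergene blocks hitting the target fraction
    gene_rows = []
    gid = 0
    for chrom in ref.contigs:
        pos = 0
        while pos < L - 1000:
            glen = int(rng.integers(5_000, 30_000))
            ilen = max(1000, int(glen * (1 - config.gene_fraction) / max(config.gene_fraction, 1e-9)))
            start = min(pos, L)
            end = min(pos + glen, L)
            if end - start > 500:
                gid += 1
                strand = "+" if rng.random() < 0.5 else "-"
                gene_rows.append((chrom, start, end, f"gene{gid}", strand))
            pos = end + ilen
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "name", "strand"])

    # quantitative covariate tracks on a 1 kb grid
    tracks = {}
    for name, smooth in (("covA", True), ("covB", True)):
        rows = []
        for chrom in ref.contigs:
            n_win = L // 1000
            vals = _track_values(rng, n_win, smooth)
            starts = np.arange(n_win) * 1000
            rows.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": starts + 1000, "value": vals}
                )
            )
        tracks[name] = pd.concat(rows, ignore_index=True)

    # categorical chromatin-state-like annotation: 3 states in blocks
    cat_rows = []
    for chrom in ref.contigs:
        pos = 0
        while pos < L:
            span = int(rng.integers(10_000, 50_000))
            state = f"state{rng.integers(1, 4)}"
            cat_rows.append((chrom, pos, min(pos + span, L), state))
            pos += span
    categorical = pd.DataFrame(cat_rows, columns=["chrom", "start", "end", "state"])
    return ReferenceBundle(ref, genes, tracks, categorical)


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortData:
    calls: pd.DataFrame  # chrom, pos, ref, alt, cell, individual, variant_class, mode
    germline: pd.DataFrame  # chrom, pos, cell, variant_class, depth, passes_min_depth, called
    profiles: pd.DataFrame
    pair_support: pd.DataFrame | None
    depth: pd.DataFrame | None
    truth: dict

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.calls.to_csv(f"{outdir}/calls.tsv", sep="\t", index=False)
        self.germline.to_csv(f"{outdir}/germline_controls.tsv", sep="\t", index=False)
        self.profiles.to_csv(f"{outdir}/profiles.tsv", sep="\t", index=False)
        if self.pair_support is not None:
            self.pair_support.to_csv(f"{outdir}/pair_support.tsv", sep="\t", index=False)
        if self.depth is not None:
            self.depth.to_csv(f"{outdir}/depth_100bp.tsv", sep="\t", index=False)
        # truth sidecar: consumed by tests only, never by analysis modules
        self.truth["true_burden"].to_csv(f"{outdir}/truth_burden.tsv", sep="\t", index=False)


def _window_quantile_multipliers(
    values: np.ndarray, multipliers: dict[int, float], n_quantiles: int
) -> np.ndarray:
    """Per-window multiplier from quantile-keyed config (1-based quantiles)."""
    if not multipliers:
        return np.ones(len(values))
    order = np.argsort(values, kind="stable")
    q = np.empty(len(values), dtype=np.int64)
    q[order] = np.arange(len(values)) * n_quantiles // len(values) + 1
    mult = np.ones(len(values))
    for quant, m in multipliers.items():
        mult[q == quant] = m
    return mult


class _SitePlacer:
    """Samples genomic positions whose context admits a requested channel."""

    def __init__(self, bundle: ReferenceBundle, config: SimConfig):
        self.ref = bundle.reference
        self.config = config
        self.sites = self.ref.context_site_index()
        covA = bundle.tracks["covA"]["value"].to_numpy()
        self.window_bias = _window_quantile_multipliers(
            covA, config.region_bias, config.bias_n_quantiles
        )
        self.window_det = _window_quantile_multipliers(
            covA, config.detection.region_multipliers, config.detection.n_quantiles
        )
        self.uniform_bias = not config.region_bias
        self._cum: dict[int, np.ndarray] = {}
        self.seq_all = np.concatenate([self.ref.seqs[c] for c in self.ref.contigs])

    def _biased_choice(self, rng, ctx: int, n: int) -> np.ndarray:
        sites = self.sites[ctx]
        if self.uniform_bias:
            return sites[rng.integers(0, len(sites), n)]
        if ctx not in self._cum:
            w = self.window_bias[np.minimum(sites // 1000, len(self.window_bias) - 1)]
            self._cum[ctx] = np.cumsum(w / w.sum())
        c = self._cum[ctx]
        return sites[np.searchsorted(c, rng.random(n), side="right").clip(0, len(sites) - 1)]

    def place_snvs(self, rng, channels: np.ndarray) -> tuple[np.ndarray, list, list]:
        """Global positions + ref/alt alleles for drawn SBS96 channels."""
        gpos = np.empty(len(channels), dtype=np.int64)
        refs = np.empty(len(channels), dtype=object)
        alts = np.empty(len(channels), dtype=object)
        seq_all = self.seq_all
        for ch in np.unique(channels):
            m = channels == ch
            ctx = channel_context(int(ch))
            pos = self._biased_choice(rng, ctx, int(m.sum()))
            gpos[m] = pos
            center = seq_all[pos]
            pyr = (center == ord("C")) | (center == ord("T"))
            alt_py = BASES[channel_alt_index(int(ch))]
            alt_pu = {"A": "T", "C": "G", "G": "C", "T": "A"}[alt_py]
            refs[m] = [chr(b) for b in center]
            alts[m] = np.where(pyr, alt_py, alt_pu)
        return gpos, list(refs), list(alts)

    def detection_prob(self, gpos: np.ndarray, variant_class: str) -> np.ndarray:
        det = self.config.detection
        base = det.baseline if variant_class == "SNV" else det.baseline_indel
        w = np.minimum(gpos // 1000, len(self.window_det) - 1)
        return np.clip(base * self.window_det[w], 0.0, 1.0)


class _IndelPlacer:
    """Places indels realizing ID83 channels: homopolymer runs for 1 bp
    events, rejection sampling (capped) for multi-bp deletion channels."""

    MAX_TRIES = 400

    def __init__(self, bundle: ReferenceBundle, placer: _SitePlacer):
        self.ref = bundle.reference
        self.placer = placer
        # homopolymer run index: global start, length, base char, per run
        starts, lengths, bases = [], [], []
        for chrom in self.ref.contigs:
            seq = self.ref.seqs[chrom]
            off = self.ref.offset(chrom)
            change = np.flatnonzero(np.diff(seq) != 0)
            run_starts = np.concatenate([[0], change + 1])
            run_ends = np.concatenate([change + 1, [len(seq)]])
            keep = run_starts > 0  # need an anchor base to the left
            starts.append(run_starts[keep] + off)
            lengths.append((run_ends - run_starts)[keep])
            bases.append(seq[run_starts[keep]])
        self.run_start = np.concatenate(starts)
        self.run_len = np.concatenate(lengths)
        self.run_base = np.concatenate(bases)
        self.seq_all = np.concatenate([self.ref.seqs[c] for c in self.ref.contigs])
        self._groups: dict[tuple, np.ndarray] = {}

    def _runs_for(self, base_cls: str, min_len: int, max_len: int | None) -> np.ndarray:
        key = (base_cls, min_len, max_len)
        if key not in self._groups:
            if base_cls == "C":
                bm = (self.run_base == ord("C")) | (self.run_base == ord("G"))
            else:
                bm = (self.run_base == ord("A")) | (self.run_base == ord("T"))
            lm = self.run_len >= min_len
            if max_len is not None:
                lm &= self.run_len <= max_len
            self._groups[key] = np.flatnonzero(bm & lm)
        return self._groups[key]

    def place(self, rng, channel: int) -> tuple[int, str, str]:
        """One placement for one ID83 channel: (global anchor pos, ref, alt)."""
        name = ID83_CHANNELS[channel]
        parts = name.split(":")
        length, kind, sub, k = int(parts[0]), parts[1], parts[2], int(parts[3])
        if length == 1:
            if kind == "Del":
                # k < 5: homopolymer of length exactly k+1; k = 5: length >= 6
                lo, hi = (k + 1, k + 1) if k < 5 else (6, None)
            else:
                if k == 0:  # no adjacent copy of the inserted base
                    return self._place_by_rejection(rng, channel)
                lo, hi = (k, k) if k < 5 else (5, None)
            cand = self._runs_for(sub, lo, hi)
            if len(cand) == 0:
                raise RuntimeError(f"no placement site for channel {name}")
            r = cand[rng.integers(0, len(cand))]
            start = int(self.run_start[r])
            b = chr(self.run_base[r])
            anchor = chr(self.seq_all[start - 1])
            if kind == "Del":
                return start - 1, anchor + b, anchor
            return start - 1, anchor, anchor + b
        return self._place_by_rejection(rng, channel)

    def _place_by_rejection(self, rng, channel: int) -> tuple[int, str, str]:
        name = ID83_CHANNELS[channel]
        parts = name.split(":")
        length, kind = int(parts[0]), parts[1]
        total = len(self.seq_all)
        for _ in range(self.MAX_TRIES):
            g = int(rng.integers(1, total - length - 2))
            chrom, pos = self.ref.from_global(np.array([g]))
            chrom, pos = chrom[0], int(pos[0])
            if pos + length >= len(self.ref.seqs[chrom]):
                continue
            anchor = self.ref.base(chrom, pos)
            if kind == "Del":
                deleted = self.ref.slice(chrom, pos + 1, pos + length)
                ref_al, alt_al = anchor + deleted, anchor
            else:
                ins = "".join(BASES[i] for i in rng.integers(0, 4, length))
                ref_al, alt_al = anchor, anchor + ins
            try:
                got = id83_channel(self.ref, chrom, pos, ref_al, alt_al)
            except ValueError:
                continue
            if got == channel:
                return g, ref_al, alt_al
        raise RuntimeError(f"channel {name} unplaceable after {self.MAX_TRIES} tries")


def _per_cell_signature_means(
    mix: SignatureMix, aging: AgingParams, age: float, b_ind: float
) -> dict[str, float]:
    """Expected per-signature true mutation counts for one cell."""
    if mix.mode == "fraction":
        total = max(aging.intercept + aging.slope * age + b_ind, 0.0)
        return {s: total * w for s, w in mix.weights.items()}
    rates = mix.weights
    total_rate = sum(rates.values())
    ifrac = mix.intercept_frac or {
        s: (r / total_rate if total_rate > 0 else 1 / len(rates)) for s, r in rates.items()
    }
    out = {}
    for s, r in rates.items():
        share = ifrac.get(s, 0.0)
        out[s] = max(aging.intercept * share + r * age + b_ind * share, 0.0)
    return out


def generate_cohort_calls(
    config: SimConfig,
    bundle: ReferenceBundle,
    sbs_catalog=None,
    id_catalog=None,
) -> CohortData:
    """Simulate the cohort's somatic call tables and companion inputs.

    `sbs_catalog` / `id_catalog` are SignatureCatalog objects giving the
    channel distribution of each signature named in the config mixes; when
    omitted, the package's synthetic catalogs are used.
    """
    from . import signatures as sig_mod

    config.validate()
    if sbs_catalog is None:
        sbs_catalog = sig_mod.synthetic_sbs_catalog()
    if id_catalog is None:
        id_catalog = sig_mod.synthetic_id_catalog()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ref = bundle.reference
    placer = _SitePlacer(bundle, config)
    indel_placer = _IndelPlacer(bundle, placer) if config.simulate_indels else None
    det = config.detection

    # per-individual random intercepts, one per variant class
    b_snv = {e.individual: rng.normal(0, 1) for e in config.cohort}
    b_indel = {e.individual: rng.normal(0, 1) for e in config.cohort}

    call_rows = []
    truth_rows = []
    truth_sig_rows = []
    profile_rows = []
    truth_positions: dict[str, dict[str, np.ndarray]] = {}

    def simulate_class(
        cell: str,
        individual: str,
        age: float,
        ctype: str,
        variant_class: str,
    ) -> tuple[int, int, int]:
        """Draw truth + observed calls; returns (true_n, V, M)."""
        if variant_class == "SNV":
            aging = config.aging_snv[ctype]
            mix = config.sbs_mix[ctype]
            catalog = sbs_catalog
            b = b_snv[individual] * aging.random_sd
        else:
            aging = config.aging_indel[ctype]
            mix = config.id_mix[ctype]
            catalog = id_catalog
            b = b_indel[individual] * aging.random_sd
        means = _per_cell_signature_means(mix, aging, age, b)
        gpos_all, refs_all, alts_all, true_n = [], [], [], 0
        for signame, mean in means.items():
            n = int(rng.poisson(mean))
            truth_sig_rows.append((cell, variant_class, signame, n))
            if n == 0:
                continue
            true_n += n
            p = catalog.matrix[:, catalog.names.index(signame)]
            channels = rng.choice(len(p), size=n, p=p)
            if variant_class == "SNV":
                gpos, refs, alts = placer.place_snvs(rng, channels)
                gpos_all.append(gpos)
                refs_all += refs
                alts_all += alts
            else:
                for ch in channels:
                    g, r_al, a_al = indel_placer.place(rng, int(ch))
                    gpos_all.append(np.array([g]))
                    refs_all.append(r_al)
                    alts_all.append(a_al)
        if true_n == 0:
            truth_positions.setdefault(cell, {})[variant_class] = np.array([], dtype=np.int64)
            return 0, 0, 0
        gpos = np.concatenate(gpos_all)
        truth_positions.setdefault(cell, {})[variant_class] = gpos
        p_det = placer.detection_prob(gpos, variant_class)
        detected = rng.random(len(gpos)) < p_det
        rescued = rng.random(len(gpos)) < det.rescue_fraction
        chroms, poss = ref.from_global(gpos)
        V = M = 0
        for i in np.flatnonzero(detected):
            mode = "rescue" if rescued[i] else "vaf"
            if mode == "vaf":
                V += 1
            else:
                M += 1
            call_rows.append(
                (chroms[i], int(poss[i]), refs_all[i], alts_all[i], cell,
                 individual, variant_class, mode)
            )
        return true_n, V, M

    # expected global VAF sensitivity by construction (placement-weighted)
    def global_vaf_sens(variant_class: str) -> float:
        base = det.baseline if variant_class == "SNV" else det.baseline_indel
        w = placer.window_bias / placer.window_bias.sum()
        return float(np.sum(w * np.clip(base * placer.window_det, 0, 1))) * (
            1 - det.rescue_fraction
        )

    s_vaf_snv = global_vaf_sens("SNV")
    s_vaf_indel = global_vaf_sens("indel")
    genome_mb = ref.total_length / 1e6

    for entry in config.cohort:
        for ctype, n_cells in entry.cells.items():
            for k in range(n_cells):
                cell = f"{entry.individual}_{ctype}_{k + 1}"
                tn_snv, v_snv, m_snv = simulate_class(
                    cell, entry.individual, entry.age, ctype, "SNV"
                )
                if config.simulate_indels:
                    tn_ind, v_ind, m_ind = simulate_class(
                        cell, entry.individual, entry.age, ctype, "indel"
                    )
                else:
                    tn_ind = v_ind = m_ind = 0
                truth_rows.append((cell, entry.individual, tn_snv, tn_ind))
                profile_rows.append(
                    {
                        "cell": cell,
                        "individual": entry.individual,
                        "age": entry.age,
                        "cell_type": ctype,
                        "chemistry": config.chemistry.get(ctype, "PTA"),
                        "V_snv": v_snv,
                        "M_snv": m_snv,
                        "V_indel": v_ind,
                        "M_indel": m_ind,
                        "scaling_snv": 1.0 / s_vaf_snv if s_vaf_snv > 0 else np.nan,
                        "scaling_indel": 1.0 / s_vaf_indel if s_vaf_indel > 0 else np.nan,
                        "global_vaf_sensitivity": s_vaf_snv,
                        "global_total_sensitivity": min(
                            1.0, s_vaf_snv * (v_snv + m_snv) / v_snv
                        )
                        if v_snv > 0
                        else np.nan,
                        "accessible_mb_snv": config.accessible_fraction * genome_mb,
                        "accessible_mb_indel": config.accessible_fraction * genome_mb,
                        "outlier": "none",
                    }
                )

    calls = pd.DataFrame(
        call_rows,
        columns=["chrom", "pos", "ref", "alt", "cell", "individual", "variant_class", "mode"],
    )
    profiles = pd.DataFrame(profile_rows)
    truth_burden = pd.DataFrame(
        truth_rows, columns=["cell", "individual", "true_snv", "true_indel"]
    )

    # --- leave-one-out germline control sites ------------------------------
    germ_rows = []
    n_germ = ref.total_length // config.germline_spacing
    germ_gpos = np.sort(rng.integers(2, ref.total_length - 2, n_germ))
    g_chrom, g_pos = ref.from_global(germ_gpos)
    p_vaf = {
        "SNV": np.clip(
            det.baseline
            * placer.window_det[np.minimum(germ_gpos // 1000, len(placer.window_det) - 1)],
            0,
            1,
        )
        * (1 - det.rescue_fraction),
        "indel": np.clip(
            det.baseline_indel
            * placer.window_det[np.minimum(germ_gpos // 1000, len(placer.window_det) - 1)],
            0,
            1,
        )
        * (1 - det.rescue_fraction),
    }
    min_depth = {"SNV": config.min_depth_snv, "indel": config.min_depth_indel}
    for cell in profiles["cell"]:
        for vc in ("SNV", "indel") if config.simulate_indels else ("SNV",):
            depth = rng.poisson(config.germline_depth_mean, n_germ)
            passes = depth >= min_depth[vc]
            called = (rng.random(n_germ) < p_vaf[vc]) & passes
            germ_rows.append(
                pd.DataFrame(
                    {
                        "chrom": g_chrom,
                        "pos": g_pos,
                        "cell": cell,
                        "variant_class": vc,
                        "depth": depth,
                        "passes_min_depth": passes,
                        "called": called,
                    }
                )
            )
    germline = pd.concat(germ_rows, ignore_index=True)

    # --- lineage pairs ------------------------------------------------------
    pair_support = None
    shared_truth: dict[tuple[str, str], np.ndarray] = {}
    if config.lineage_pairs:
        support_rows = []
        for pair in config.lineage_pairs:
            cells = profiles[
                (profiles["individual"] == pair.individual)
                & (profiles["cell_type"] == pair.cell_type)
            ]["cell"].tolist()
            if len(cells) < 2:
                raise ValueError(
                    f"lineage pair needs >=2 {pair.cell_type} cells in {pair.individual}"
                )
            a, b = cells[0], cells[1]
            # inject shared pre-split mutations into both cells (uniform SBS mix)
            n = pair.shared_burden
            channels = rng.integers(0, 96, n)
            gpos, refs, alts = placer.place_snvs(rng, channels)
            shared_truth[(a, b)] = gpos
            chroms, poss = ref.from_global(gpos)
            new_rows = []
            for cell in (a, b):
                p_det = placer.detection_prob(gpos, "SNV")
                detmask = rng.random(n) < p_det
                for i in np.flatnonzero(detmask):
                    new_rows.append(
                        (chroms[i], int(poss[i]), refs[i], alts[i], cell,
                         pair.individual, "SNV", "vaf")
                    )
            calls = pd.concat(
                [calls, pd.DataFrame(new_rows, columns=calls.columns)], ignore_index=True
            )
            for cell in (a, b):
                extra = len([r for r in new_rows if r[4] == cell])
                profiles.loc[profiles["cell"] == cell, "V_snv"] += extra
        if config.emit_pair_support:
            pair_support = _emit_pair_support(
                config, ref, rng, calls, profiles, shared_truth, germ_gpos
            )

    depth_df = _emit_depth(config, ref, rng, profiles) if config.emit_depth else None

    truth = {
        "true_burden": truth_burden,
        "true_signature_counts": pd.DataFrame(
            truth_sig_rows, columns=["cell", "variant_class", "signature", "count"]
        ),
        "true_positions": truth_positions,
        "shared_sets": shared_truth,
        "global_vaf_sensitivity": {"SNV": s_vaf_snv, "indel": s_vaf_indel},
        "window_detection_multiplier": placer.window_det,
        "window_bias": placer.window_bias,
    }
    return CohortData(calls, germline, profiles, pair_support, depth_df, truth)


def _emit_pair_support(config, ref, rng, calls, profiles, shared_truth, germ_gpos):
    """Cross-cell read support for every within-individual same-type pair."""
    rows = []
    d_priv, d_ind = config.pair_dropout_private, config.pair_dropout_indet
    for ind, grp in profiles.groupby("individual", sort=False):
        for ctype, sub in grp.groupby("cell_type", sort=False):
            cells = sub["cell"].tolist()
            for a in cells:
                for b in cells:
                    if a >= b:
                        continue
                    shared = set()
                    for (x, y), gpos in shared_truth.items():
                        if {x, y} == {a, b}:
                            chs, ps = ref.from_global(gpos)
                            shared = {(c, int(p)) for c, p in zip(chs, ps)}
                    sites = calls[
                        (calls["cell"].isin([a, b])) & (calls["variant_class"] == "SNV")
                    ][["chrom", "pos"]].drop_duplicates()
                    for _, site in sites.iterrows():
                        key = (site["chrom"], int(site["pos"]))
                        for cell in (a, b):
                            alt, dp = _support_draw(
                                rng, key in shared, d_priv, d_ind, config.pair_depth_mean
                            )
                            rows.append((site["chrom"], int(site["pos"]), cell, a, b, "somatic", alt, dp))
                    # hSNP support: germline sites are truly shared
                    n_h = min(len(germ_gpos), 2000)
                    hs = germ_gpos[rng.choice(len(germ_gpos), n_h, replace=False)]
                    chs, ps = ref.from_global(np.sort(hs))
                    for c, p in zip(chs, ps):
                        for cell in (a, b):
                            alt, dp = _support_draw(
                                rng, True, d_priv, d_ind, config.pair_depth_mean
                            )
                            rows.append((c, int(p), cell, a, b, "hsnp", alt, dp))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "cell", "cell_a", "cell_b", "kind", "alt_reads", "depth"]
    )


def _support_draw(rng, truly_shared, d_priv, d_ind, depth_mean):
    """(alt_reads, depth) for one site in one cell of a pair."""
    u = rng.random()
    if truly_shared:
        if u < d_priv:  # allelic dropout: no variant reads at good depth
            return 0, max(6, int(rng.poisson(depth_mean)))
        if u < d_priv + d_ind:  # low depth or a stray read
            return int(rng.integers(0, 2)), int(rng.integers(0, 6))
        dp = max(4, int(rng.poisson(depth_mean)))
        alt = max(2, int(rng.binomial(dp, 0.45)))
        return alt, dp
    return 0, max(6, int(rng.poisson(depth_mean)))


def _emit_depth(config, ref, rng, profiles):
    """100 bp depth summaries: two bulk samples and the single-cell mean."""
    rows = []
    for chrom in ref.contigs:
        n_win = len(ref.seqs[chrom]) // 100
        starts = np.arange(n_win) * 100
        accessible = rng.random(n_win) < config.accessible_fraction
        bulk1 = np.where(accessible, rng.poisson(30, n_win), rng.poisson(2, n_win))
        bulk2 = np.where(accessible, rng.poisson(30, n_win), rng.poisson(2, n_win))
        sc = np.where(accessible, rng.normal(30, 2, n_win), rng.normal(2, 1, n_win))
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "bulk_1": bulk1, "bulk_2": bulk2,
                 "sc_mean": np.round(sc, 3)}
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# tumor catalogs


def generate_tumor_catalog(config: SimConfig, bundle: ReferenceBundle) -> pd.DataFrame:
    """MAF-like somatic SNV tables for each configured tumor type.

    Per-sample burdens are Poisson around the type mean; a configured
    fraction of samples are hypermutators with fold-increased burden.
    Positions follow a density log-linearly coupled to the covA covariate.
    """
    config.validate()
    if not config.tumor_model:
        raise ValueError("tumor_model not configured")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    ref = bundle.reference
    covA = bundle.tracks["covA"]["value"].to_numpy()
    z = (covA - covA.mean()) / max(covA.std(), 1e-12)
    rows = []
    ascii_bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq_all = np.concatenate([ref.seqs[c] for c in ref.contigs])
    for ttype, model in config.tumor_model.items():
        w = np.exp(model.coupling * z)
        w = w / w.sum()
        cum = np.cumsum(w)
        n_hyper = int(round(model.hypermutator_fraction * model.n_samples))
        for si in range(model.n_samples):
            mean = model.mean_burden * (model.hypermutator_fold if si < n_hyper else 1.0)
            n = rng.poisson(mean)
            win = np.searchsorted(cum, rng.random(n), side="right").clip(0, len(w) - 1)
            gpos = win * 1000 + rng.integers(0, 1000, n)
            gpos = np.clip(gpos, 1, ref.total_length - 2)
            chroms, poss = ref.from_global(gpos)
            refs = seq_all[gpos]
            shift = rng.integers(1, 4, n)
            alts = ascii_bases[(np.searchsorted(ascii_bases, refs) + shift) % 4]
            rows.append(
                pd.DataFrame(
                    {
                        "tumor_type": ttype,
                        "sample": f"{ttype}_s{si + 1}",
                        "chrom": chroms,
                        "pos": poss,
                        "ref": [chr(b) for b in refs],
                        "alt": [chr(b) for b in alts],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# named study configurations


def burden_study_config(seed: int = 0, **overrides) -> SimConfig:
    """Total-burden aging study: the default conditions."""
    cfg = SimConfig(seed=seed)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def exposure_study_config(seed: int = 0) -> SimConfig:
    """Per-signature yearly-rate conditions for SBS exposure recovery."""
    cfg = SimConfig(seed=seed, simulate_indels=False)
    cfg.sbs_mix = {
        "OL": SignatureMix(
            {"SBS1": 2.77, "SBS5": 22.7, "SBS16": 0.18, "SBS32": 3.35}, mode="rate"
        ),
        "neuron": SignatureMix(
            {"SBS1": 0.29, "SBS5": 14.5, "SBS16": 2.0}, mode="rate"
        ),
    }
    # in rate mode the total slope is the sum of the per-signature rates
    cfg.aging_snv = {
        "OL": AgingParams(sum(cfg.sbs_mix["OL"].weights.values()), 165.0, 25.0),
        "neuron": AgingParams(sum(cfg.sbs_mix["neuron"].weights.values()), 107.0, 20.0),
    }
    return cfg


def indel_study_config(seed: int = 0) -> SimConfig:
    """Indel-signature yearly-rate conditions (totals 2.1 / 2.9 per year)."""
    cfg = SimConfig(seed=seed)
    cfg.sbs_mix = {  # keep SNVs tiny; this study is about indels
        ct: SignatureMix({"SBS5": 1.0}) for ct in ("OL", "neuron")
    }
    cfg.aging_snv = {
        "OL": AgingParams(1.0, 5.0, 1.0),
        "neuron": AgingParams(1.0, 5.0, 1.0),
    }
    cfg.id_mix = {
        "OL": SignatureMix(
            {"ID2": 0.10, "ID4": 0.09, "ID5": 0.72, "ID8": 0.40, "ID9": 0.69, "ID11": 0.10},
            mode="rate",
        ),
        "neuron": SignatureMix(
            {"ID2": 0.02, "ID4": 1.20, "ID5": 0.60, "ID8": 0.73, "ID9": 0.25, "ID11": 0.10},
            mode="rate",
        ),
    }
    cfg.aging_indel = {
        "OL": AgingParams(2.1, 10.0, 2.0),
        "neuron": AgingParams(2.9, 10.0, 2.0),
    }
    return cfg


def lineage_study_config(seed: int = 0, shared_burden: int = 263) -> SimConfig:
    """Small cohort with one injected related OL pair and full detection,
    so cross-cell dropout is the only loss the f-correction must undo."""
    cfg = SimConfig(seed=seed, simulate_indels=False)
    cfg.cohort = [
        CohortEntry("P01", 82.0, {"OL": 2}),
        CohortEntry("P02", 50.0, {"OL": 3}),
        CohortEntry("P03", 20.0, {"OL": 3}),
    ]
    cfg.detection = DetectionModel(baseline=1.0, rescue_fraction=0.0)
    cfg.lineage_pairs = [LineagePair("P01", shared_burden)]
    cfg.emit_pair_support = True
    return cfg
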