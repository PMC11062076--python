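"""Reference-genome handling and mutation channel classification.

Substitutions are classified into the standard 96-channel scheme (six
pyrimidine-strand base changes x 16 flanking dinucleotide contexts) and
indels into the standard 83-channel scheme (homopolymer-length-stratified
1 bp events, repeat-stratified longer events, and microhomology deletions).
Channel order follows the SigProfiler/COSMIC convention so spectra written
by this package line up with published catalog layouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pyfaidx import Fasta

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUB_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

# uint8 ASCII -> 0..3 base index, 255 for anything else (N, gaps)
_BASE_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_IDX[ord(_b)] = _i
    _BASE_IDX[ord(_b.lower())] = _i

# base index -> complement index (A<->T, C<->G)
_COMP_IDX = np.array([3, 2, 1, 0], dtype=np.uint8)

# (ref_idx, alt_idx) -> substitution-type index on the pyrimidine strand.
# ref must already be pyrimidine (C=1 or T=3).
_SUB_IDX = np.full((4, 4), 255, dtype=np.uint8)
_SUB_IDX[1, 0] = 0  # C>A
_SUB_IDX[1, 2] = 1  # C>G
_SUB_IDX[1, 3] = 2  # C>T
_SUB_IDX[3, 0] = 3  # T>A
_SUB_IDX[3, 1] = 4  # T>C
_SUB_IDX[3, 2] = 5  # T>G

SBS96_CHANNELS = tuple(
    f"{f}[{sub}]{t}" for sub in SUB_TYPES for f in BASES for t in BASES
)

# 32 pyrimidine-centred trinucleotide contexts: (center C or T) * 16 flanks
N_CONTEXTS = 32
CONTEXT_NAMES = tuple(
    f"{f}{c}{t}" for c in "CT" for f in BASES for t in BASES
)


def _build_id83_names() -> tuple[str, ...]:
    names: list[str] = []
    for base in "CT":
        names += [f"1:Del:{base}:{k}" for k in range(6)]
    for base in "CT":
        names += [f"1:Ins:{base}:{k}" for k in range(6)]
    for length in range(2, 6):
        names += [f"{length}:Del:R:{k}" for k in range(6)]
    for length in range(2, 6):
        names += [f"{length}:Ins:R:{k}" for k in range(6)]
    names += ["2:Del:M:1"]
    names += [f"3:Del:M:{k}" for k in (1, 2)]
    names += [f"4:Del:M:{k}" for k in (1, 2, 3)]
    names += [f"5:Del:M:{k}" for k in (1, 2, 3, 4, 5)]
    return tuple(names)


ID83_CHANNELS = _build_id83_names()
_ID83_INDEX = {name: i for i, name in enumerate(ID83_CHANNELS)}

assert len(SBS96_CHANNELS) == 96 and len(ID83_CHANNELS) == 83


@dataclass
class Reference:
    """In-memory reference genome: contig name -> uint8 ASCII array.

    Contig order is significant; global coordinates concatenate contigs in
    this order, which lets downstream modules index the whole genome with a
    single integer axis.
    """

    seqs: dict[str, np.ndarray]
    _offsets: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        off = 0
        self._offsets = {}
        for name, seq in self.seqs.items():
            self._offsets[name] = off
            off += len(seq)

    @property
    def contigs(self) -> list[str]:
        return list(self.seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.seqs.values())

    def offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def to_global(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """1-based per-contig positions -> 0-based global coordinates."""
        off = np.array([self._offsets[c] for c in np.asarray(chrom, dtype=object)])
        return off + np.asarray(pos, dtype=np.int64) - 1

    def from_global(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """0-based global coordinates -> (contig names, 1-based positions)."""
        gpos = np.asarray(gpos, dtype=np.int64)
        names = np.array(self.contigs, dtype=object)
        bounds = np.cumsum([len(self.seqs[c]) for c in self.contigs])
        idx = np.searchsorted(bounds, gpos, side="right")
        starts = bounds - np.array([len(self.seqs[c]) for c in self.contigs])
        return names[idx], gpos - starts[idx] + 1

    @classmethod
    def from_fasta(cls, path: str) -> "Reference":
        fa = Fasta(str(path), rebuild=False, build_index=True)
        seqs = {
            name: np.frombuffer(str(fa[name][:]).upper().encode(), dtype=np.uint8).copy()
            for name in fa.keys()
        }
        return cls(seqs)

    def to_fasta(self, path: str, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self.seqs.items():
                fh.write(f">{name}\n")
                s = seq.tobytes().decode()
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")

    def base_idx(self, chrom: str) -> np.ndarray:
        """Contig sequence as 0..3 base indices (255 for non-ACGT), cached."""
        cache = getattr(self, "_bidx_cache", None)
        if cache is None:
            cache = self._bidx_cache = {}
        if chrom not in cache:
            cache[chrom] = _BASE_IDX[self.seqs[chrom]]
        return cache[chrom]

    def base(self, chrom: str, pos: int) -> str:
        """1-based single-base lookup."""
        return chr(self.seqs[chrom][pos - 1])

    def slice(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice."""
        return self.seqs[chrom][start - 1 : end].tobytes().decode()

    # -- context machinery -------------------------------------------------

    def context_ids(self, chrom: str) -> np.ndarray:
        """Pyrimidine-collapsed trinucleotide context id (0..31) per position.

        -1 at contig edges and wherever the trinucleotide contains a non-ACGT
        base.  Cached per contig.
        """
        cache = getattr(self, "_ctx_cache", None)
        if cache is None:
            cache = self._ctx_cache = {}
        if chrom in cache:
            return cache[chrom]
        b = _BASE_IDX[self.seqs[chrom]]
        n = len(b)
        ctx = np.full(n, -1, dtype=np.int8)
        if n >= 3:
            center = b[1:-1]
            five = b[:-2]
            three = b[2:]
            ok = (center != 255) & (five != 255) & (three != 255)
            pyr = (center == 1) | (center == 3)
            c_idx = np.where(center == 3, 1, 0)  # 0 for C, 1 for T after collapse
            f = np.where(pyr, five, _COMP_IDX[np.minimum(three, 3)])
            t = np.where(pyr, three, _COMP_IDX[np.minimum(five, 3)])
            # purine centers: collapse C<->G, A<->T; T-center stays 1, A-center -> T
            c_idx = np.where(pyr, c_idx, np.where(center == 0, 1, 0))
            val = c_idx * 16 + f.astype(np.int16) * 4 + t.astype(np.int16)
            ctx[1:-1] = np.where(ok, val, -1).astype(np.int8)
        cache[chrom] = ctx
        return ctx

    def context_site_index(self) -> list[np.ndarray]:
        """Global positions of every site in each of the 32 contexts."""
        cached = getattr(self, "_site_index", None)
        if cached is not None:
            return cached
        all_ctx = np.concatenate([self.context_ids(c) for c in self.contigs])
        order = np.argsort(all_ctx, kind="stable")
        sorted_ctx = all_ctx[order]
        sites = []
        for ctx in range(N_CONTEXTS):
            lo = np.searchsorted(sorted_ctx, ctx, side="left")
            hi = np.searchsorted(sorted_ctx, ctx, side="right")
            sites.append(np.sort(order[lo:hi]))
        self._site_index = sites
        return sites


# -- SBS96 -----------------------------------------------------------------


def sbs96_channel_of(channel_name: str) -> int:
    return SBS96_CHANNELS.index(channel_name)


def channel_context(channel: int) -> int:
    """SBS96 channel -> pyrimidine-collapsed context id (0..31)."""
    sub = channel // 16
    return (0 if sub < 3 else 1) * 16 + channel % 16


def channel_alt_index(channel: int) -> int:
    """Pyrimidine-strand alt base index of an SBS96 channel."""
    sub = channel // 16
    alts = {0: 0, 1: 2, 2: 3, 3: 0, 4: 1, 5: 2}
    return alts[sub]


def sbs96_channels(
    ref: Reference, chrom: np.ndarray, pos: np.ndarray, ref_al: np.ndarray, alt_al: np.ndarray
) -> np.ndarray:
    """Vectorized SBS96 classification of SNVs (1-based positions).

    Returns -1 where the flanking context is undefined (contig edge / N).
    Raises ValueError if a stated reference allele disagrees with the genome.
    """
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    out = np.full(len(pos), -1, dtype=np.int16)
    ref_idx = _BASE_IDX[np.frombuffer("".join(ref_al).encode(), dtype=np.uint8)]
    alt_idx = _BASE_IDX[np.frombuffer("".join(alt_al).encode(), dtype=np.uint8)]
    for c in np.unique(chrom):
        m = chrom == c
        p = pos[m]
        seq = _BASE_IDX[ref.seqs[c]]
        if np.any((p < 1) | (p > len(seq))):
            raise ValueError(f"position outside contig {c}")
        center = seq[p - 1]
        if np.any(center != ref_idx[m]):
            bad = np.where(center != ref_idx[m])[0][0]
            raise ValueError(
                f"reference allele mismatch at {c}:{p[bad]} "
                f"(genome {BASES[center[bad]] if center[bad] < 4 else 'N'})"
            )
        edge = (p == 1) | (p == len(seq))
        five = np.where(edge, 255, seq[np.maximum(p - 2, 0)])
        three = np.where(edge, 255, seq[np.minimum(p, len(seq) - 1)])
        pyr = (center == 1) | (center == 3)
        r = np.where(pyr, center, _COMP_IDX[np.minimum(center, 3)])
        a = np.where(pyr, alt_idx[m], _COMP_IDX[np.minimum(alt_idx[m], 3)])
        f = np.where(pyr, five, _COMP_IDX[np.minimum(three, 3)])
        t = np.where(pyr, three, _COMP_IDX[np.minimum(five, 3)])
        sub = _SUB_IDX[r, a]
        ok = (five != 255) & (three != 255) & (sub != 255)
        ch = sub.astype(np.int16) * 16 + f.astype(np.int16) * 4 + t.astype(np.int16)
        out[m] = np.where(ok, ch, -1)
    return out


# -- ID83 ------------------------------------------------------------------


def _run_length(seq: np.ndarray, start: int, base: int, step: int) -> int:
    """Length of the run of `base` walking from `start` (inclusive) by `step`."""
    n = 0
    i = start
    while 0 <= i < len(seq) and seq[i] == base:
        n += 1
        i += step
    return n


def _count_copies(seq: np.ndarray, start: int, motif: np.ndarray, step: int) -> int:
    """Copies of `motif` tiling from `start` in direction `step` (+1/-1 motifs)."""
    L = len(motif)
    n = 0
    i = start
    while True:
        if step > 0:
            if i + L > len(seq) or not np.array_equal(seq[i : i + L], motif):
                break
            n += 1
            i += L
        else:
            if i - L < 0 or not np.array_equal(seq[i - L : i], motif):
                break
            n += 1
            i -= L
    return n


def id83_channel(ref: Reference, chrom: str, pos: int, ref_al: str, alt_al: str) -> int:
    """Classify one anchored indel (VCF convention: ref/alt share base 1).

    `pos` is the 1-based position of the shared anchor base.  Returns the
    channel index 0..82, or -1 for events longer than the scheme covers.
    """
    seq = ref.base_idx(chrom)
    if len(ref_al) == len(alt_al):
        raise ValueError("not an indel")
    if ref_al[0] != alt_al[0]:
        raise ValueError("indel alleles must share an anchor base")
    if len(ref_al) > len(alt_al):  # deletion
        d = ref_al[1:]
        L = len(d)
        motif = _BASE_IDX[np.frombuffer(d.encode(), dtype=np.uint8)]
        start = pos  # 0-based index of first deleted base
        if not np.array_equal(seq[start : start + L], motif):
            raise ValueError(f"deleted sequence mismatch at {chrom}:{pos}")
        if L == 1:
            b = motif[0]
            run = (
                _run_length(seq, start, b, -1) + _run_length(seq, start + 1, b, 1)
            )
            base = "C" if b in (1, 2) else "T"  # G collapses to C, A to T
            return _ID83_INDEX[f"1:Del:{base}:{min(run, 6) - 1}"]
        if L > 5:
            length = 5
        else:
            length = L
        extra = (
            _count_copies(seq, start + L, motif, +1)
            + _count_copies(seq, start, motif, -1)
        )
        if extra >= 1:
            return _ID83_INDEX[f"{length}:Del:R:{min(extra, 5)}"]
        # microhomology: partial overlap of the deleted sequence with flanks
        mh_r = 0
        while mh_r < L - 1 and start + L + mh_r < len(seq) and seq[start + L + mh_r] == motif[mh_r]:
            mh_r += 1
        mh_l = 0
        while mh_l < L - 1 and start - 1 - mh_l >= 0 and seq[start - 1 - mh_l] == motif[L - 1 - mh_l]:
            mh_l += 1
        mh = max(mh_r, mh_l)
        if mh >= 1:
            cap = {2: 1, 3: 2, 4: 3, 5: 5}[length]
            return _ID83_INDEX[f"{length}:Del:M:{min(mh, cap)}"]
        return _ID83_INDEX[f"{length}:Del:R:0"]
    # insertion
    ins = alt_al[1:]
    L = len(ins)
    motif = _BASE_IDX[np.frombuffer(ins.encode(), dtype=np.uint8)]
    start = pos  # insertion lands between 0-based pos-1 and pos
    if L == 1:
        b = motif[0]
        run = _run_length(seq, start, b, 1) + _run_length(seq, start - 1, b, -1)
        base = "C" if b in (1, 2) else "T"
        return _ID83_INDEX[f"1:Ins:{base}:{min(run, 5)}"]
    length = min(L, 5)
    copies = _count_copies(seq, start, motif, +1) + _count_copies(seq, start, motif, -1)
    return _ID83_INDEX[f"{length}:Ins:R:{min(copies, 5)}"]


def id83_channels(
    ref: Reference, chrom: np.ndarray, pos: np.ndarray, ref_al: np.ndarray, alt_al: np.ndarray
) -> np.ndarray:
    out = np.empty(len(pos), dtype=np.int16)
    for i in range(len(pos)):
        out[i] = id83_channel(ref, chrom[i], int(pos[i]), ref_al[i], alt_al[i])
    return out


def revcomp(s: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(s))
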