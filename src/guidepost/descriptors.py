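"""Physical descriptors of the 147-bp sequence context around a target site.

Each of the 23 site positions gets a 147-bp window (73-bp flank on each
side), and four context descriptors are computed per window:

* nucleotide complexity via block decomposition (BDM-style aggregation over
  non-overlapping k-mer blocks, with a pluggable k-mer -> complexity table
  and a Shannon-entropy fallback),
* GC content of the window,
* nucleosome occupancy and nucleosome affinity, supplied either by a
  per-base precomputed track file or by a deterministic sequence-derived
  surrogate (10-bp periodicity of AA/TT/TA dinucleotides).

Stacking the four rows gives the 4 x 23 descriptor matrix; each row is
min-max normalized with dataset-level statistics fitted once on training
data and persisted with the model, so identical sequences at different loci
can still be told apart by their context.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .encoding import SITE_LENGTH, SgRNATargetPair

FLANK = 73
WINDOW_LENGTH = 2 * FLANK + 1  # 147
CONTEXT_LENGTH = WINDOW_LENGTH + SITE_LENGTH - 1  # 169

DESCRIPTOR_ROWS = ("nucleotide_bdm", "gc_content", "nupop_occupancy", "nupop_affinity")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Symbol codes: A=0, C=1, G=2, T=3, N=4 (alphabetical; local to this module).
_SYM = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _SYM[ord(_b)] = _i


class ContigLookupError(KeyError):
    """Requested chromosome is absent from the genome."""


class BoundsError(ValueError):
    """Site does not fit inside its contig."""


class MissingTrackError(KeyError):
    """A per-base track has no value at a requested position."""


class ConfigurationError(ValueError):
    """Descriptor configuration is unusable (e.g. empty table, no fallback)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ContextWindow:
    """A 147-bp window centered on one site base (center +/- 73)."""

    chrom: str
    center: int  # 0-based genomic coordinate of the center base
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW_LENGTH:
            raise ValueError(
                f"context window must be {WINDOW_LENGTH} bp, got {len(self.sequence)}"
            )
        self.sequence = self.sequence.upper()


@dataclass
class PhysicalDescriptors:
    """The 4 x 23 normalized descriptor matrix (rows as in DESCRIPTOR_ROWS)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (4, SITE_LENGTH):
            raise ValueError(f"descriptor matrix must be 4x{SITE_LENGTH}")


def _contig_seq(genome, chrom: str) -> str:
    """Fetch a contig as an uppercase string from a pyfaidx.Fasta or mapping."""
    try:
        rec = genome[chrom]
    except KeyError as exc:
        raise ContigLookupError(f"contig {chrom!r} not found in genome") from exc
    return str(rec[:]) if hasattr(rec, "__getitem__") and not isinstance(rec, str) else str(rec)


def extract_context(genome, pair: SgRNATargetPair) -> str:
    """The 169-bp oriented context covering all 23 windows, N-padded at edges.

    Window j of the site is ``context[j : j + 147]`` with its center at
    index 73 + j, for both strands (minus-strand contexts are
    reverse-complemented so the center base equals ``target_seq[j]``).
    """
    seq = _contig_seq(genome, pair.chrom).upper()
    if pair.start < 0 or pair.end > len(seq):
        raise BoundsError(
            f"site {pair.chrom}:{pair.start}-{pair.end} outside contig of length {len(seq)}"
        )
    lo = pair.start - FLANK
    hi = pair.end + FLANK  # start + 23 + 73
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(seq))
    ctx = "N" * left_pad + seq[max(0, lo):min(hi, len(seq))] + "N" * right_pad
    if pair.strand == "-":
        ctx = reverse_complement(ctx)
    return ctx


def extract_windows(genome, pair: SgRNATargetPair) -> List[ContextWindow]:
    """One 147-bp window per site position, centered on that base."""
    ctx = extract_context(genome, pair)
    windows = []
    for j in range(SITE_LENGTH):
        if pair.strand == "+":
            center = pair.start + j
        else:
            center = pair.start + SITE_LENGTH - 1 - j
        windows.append(ContextWindow(pair.chrom, center, ctx[j:j + WINDOW_LENGTH]))
    return windows


def gc_content(window: ContextWindow) -> float:
    """(#G + #C) / window length; N counts in the denominator only."""
    s = window.sequence
    return (s.count("G") + s.count("C")) / len(s)


def _shannon_block_complexity(block_codes: np.ndarray) -> float:
    """Fallback per-block complexity: Shannon entropy (bits/symbol, N as a
    fifth symbol) times the block length."""
    counts = np.bincount(block_codes, minlength=5).astype(np.float64)
    p = counts[counts > 0] / block_codes.size
    return float(-(p * np.log2(p)).sum() * block_codes.size)


def bdm_score(
    window: ContextWindow,
    block_size: int = 12,
    block_table: Optional[Mapping[str, float]] = None,
    fallback: bool = True,
) -> float:
    """Block-decomposition complexity of the window.

    The window is cut into non-overlapping blocks of ``block_size`` (the
    remainder is dropped) and the score is
    ``sum over distinct blocks of complexity(block) + log2(multiplicity)``.
    Block complexities come from ``block_table``; blocks absent from the
    table (or all blocks, when no table is given) use the Shannon-entropy
    fallback unless ``fallback`` is disabled.
    """
    if block_size < 1:
        raise ConfigurationError("block_size must be >= 1")
    if not block_table and not fallback:
        raise ConfigurationError("no block table and fallback disabled")
    s = window.sequence
    n_blocks = len(s) // block_size
    tally: Dict[str, int] = {}
    for b in range(n_blocks):
        blk = s[b * block_size:(b + 1) * block_size]
        tally[blk] = tally.get(blk, 0) + 1
    score = 0.0
    for blk, mult in tally.items():
        if block_table is not None and blk in block_table:
            c = float(block_table[blk])
        elif fallback:
            c = _shannon_block_complexity(_SYM[np.frombuffer(blk.encode(), dtype=np.uint8)])
        else:
            raise ConfigurationError(f"block {blk!r} absent from table and fallback disabled")
        score += c + math.log2(mult)
    return score


# ---------------------------------------------------------------------------
# Nucleosome occupancy / affinity providers
# ---------------------------------------------------------------------------

_PERIODIC_DINUCS = ("AA", "TT", "TA")
_PERIOD = 10.0


class SurrogateNucleosomeProvider:
    """Deterministic sequence-derived stand-in for a nucleosome-score track.

    Affinity is the 10-bp phase coherence of AA/TT/TA dinucleotides across
    the window (amplitude of the period-10 Fourier component of the
    dinucleotide indicator, normalized by the dinucleotide count);
    occupancy is a logistic transform of the affinity.  Purely a function
    of the window sequence, hence reproducible and dependency-free.
    """

    name = "surrogate"

    def scores(self, window: ContextWindow) -> Tuple[float, float]:
        d = self._indicator(window.sequence)
        return self._from_indicator(d)

    @staticmethod
    def _indicator(seq: str) -> np.ndarray:
        codes = _SYM[np.frombuffer(seq.encode(), dtype=np.uint8)]
        a, b = codes[:-1], codes[1:]
        # AA, TT, TA under codes A=0, T=3
        return (
            ((a == 0) & (b == 0)) | ((a == 3) & (b == 3)) | ((a == 3) & (b == 0))
        ).astype(np.float64)

    @staticmethod
    def _from_indicator(d: np.ndarray) -> Tuple[float, float]:
        idx = np.arange(d.size)
        c = float(np.sum(d * np.cos(2 * np.pi * idx / _PERIOD)))
        s = float(np.sum(d * np.sin(2 * np.pi * idx / _PERIOD)))
        total = float(d.sum())
        affinity = math.sqrt(c * c + s * s) / max(total, 1.0)
        occupancy = 1.0 / (1.0 + math.exp(-6.0 * (affinity - 0.25)))
        return occupancy, affinity


class TrackNucleosomeProvider:
    """Per-base nucleosome scores from a precomputed track.

    The track is a tab-separated file with columns
    (chrom, 0-based pos, occupancy, affinity); values are looked up at the
    window's center position.
    """

    name = "track"

    def __init__(self, values: Mapping[Tuple[str, int], Tuple[float, float]]):
        self._values = dict(values)

    @classmethod
    def from_file(cls, path) -> "TrackNucleosomeProvider":
        values = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise ValueError(f"malformed track line {lineno}: {line!r}")
                chrom, pos, occ, aff = parts
                values[(chrom, int(pos))] = (float(occ), float(aff))
        return cls(values)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for (chrom, pos), (occ, aff) in sorted(self._values.items()):
                fh.write(f"{chrom}\t{pos}\t{occ!r}\t{aff!r}\n")

    def scores(self, window: ContextWindow) -> Tuple[float, float]:
        key = (window.chrom, window.center)
        if key not in self._values:
            raise MissingTrackError(f"no track value at {window.chrom}:{window.center}")
        return self._values[key]


def nucleosome_scores(provider, window: ContextWindow) -> Tuple[float, float]:
    """(occupancy, affinity) at the window center from the given provider."""
    return provider.scores(window)


# ---------------------------------------------------------------------------
# Normalization and assembly of the 4 x 23 matrix
# ---------------------------------------------------------------------------


@dataclass
class NormalizationStats:
    """Per-row min/max fitted on training data, frozen at inference time."""

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=np.float64).reshape(4)
        self.maxs = np.asarray(self.maxs, dtype=np.float64).reshape(4)

    @classmethod
    def fit(cls, raw_matrices: Sequence[np.ndarray]) -> "NormalizationStats":
        stack = np.concatenate([np.asarray(m).reshape(4, -1) for m in raw_matrices], axis=1)
        return cls(stack.min(axis=1), stack.max(axis=1))

    def apply(self, raw: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw, dtype=np.float64)
        out = np.zeros_like(raw)
        for r in range(4):
            span = self.maxs[r] - self.mins[r]
            if span <= 0:
                if np.any(raw[r] != self.mins[r]):
                    warnings.warn(
                        f"degenerate normalization range for row {DESCRIPTOR_ROWS[r]}; "
                        "row set to 0"
                    )
                out[r] = 0.0
            else:
                out[r] = np.clip((raw[r] - self.mins[r]) / span, 0.0, 1.0)
        return out

    def to_dict(self) -> Dict[str, list]:
        return {"mins": self.mins.tolist(), "maxs": self.maxs.tolist()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "NormalizationStats":
        return cls(np.asarray(d["mins"]), np.asarray(d["maxs"]))


@dataclass
class DescriptorConfig:
    """Everything needed to turn a site into its 4 x 23 descriptor matrix."""

    block_size: int = 12
    block_table: Optional[Mapping[str, float]] = None
    fallback: bool = True
    provider: object = field(default_factory=SurrogateNucleosomeProvider)
    norm_stats: Optional[NormalizationStats] = None


def raw_descriptor_matrix(genome, pair: SgRNATargetPair, config: DescriptorConfig) -> np.ndarray:
    """Un-normalized 4 x 23 matrix (BDM, GC, occupancy, affinity rows)."""
    ctx = extract_context(genome, pair)
    codes = _SYM[np.frombuffer(ctx.encode(), dtype=np.uint8)]
    raw = np.empty((4, SITE_LENGTH), dtype=np.float64)

    # GC row: windowed G/C counts via cumulative sums.
    is_gc = ((codes == 1) | (codes == 2)).astype(np.float64)
    cs = np.concatenate([[0.0], np.cumsum(is_gc)])
    raw[1] = (cs[WINDOW_LENGTH:] - cs[:SITE_LENGTH]) / WINDOW_LENGTH

    # BDM row: per-window block decomposition.  Pre-encode every block-sized
    # k-mer of the context once (id + entropy fallback), then tally the
    # non-overlapping blocks of each window.
    bs = config.block_size
    n_blocks = WINDOW_LENGTH // bs
    n_kmers = CONTEXT_LENGTH - bs + 1
    powers = 5 ** np.arange(bs - 1, -1, -1, dtype=np.int64)
    ids = np.array(
        [int(np.dot(codes[s:s + bs].astype(np.int64), powers)) for s in range(n_kmers)],
        dtype=np.int64,
    )
    sym_cum = np.zeros((5, CONTEXT_LENGTH + 1))
    for sym in range(5):
        sym_cum[sym, 1:] = np.cumsum(codes == sym)
    ent = np.zeros(n_kmers)
    for s in range(n_kmers):
        counts = sym_cum[:, s + bs] - sym_cum[:, s]
        p = counts[counts > 0] / bs
        ent[s] = -(p * np.log2(p)).sum() * bs
    table = config.block_table
    if not table and not config.fallback:
        raise ConfigurationError("no block table and fallback disabled")
    for j in range(SITE_LENGTH):
        offs = j + bs * np.arange(n_blocks)
        uniq, first_idx, mult = np.unique(ids[offs], return_index=True, return_counts=True)
        score = float(np.log2(mult).sum())
        for u_id, fi in zip(uniq, first_idx):
            s0 = int(offs[fi])
            blk = ctx[s0:s0 + bs]
            if table is not None and blk in table:
                score += float(table[blk])
            elif config.fallback:
                score += float(ent[s0])
            else:
                raise ConfigurationError(
                    f"block {blk!r} absent from table and fallback disabled"
                )
        raw[0, j] = score

    # Nucleosome rows.
    provider = config.provider
    if isinstance(provider, SurrogateNucleosomeProvider):
        d = SurrogateNucleosomeProvider._indicator(ctx)
        idx = np.arange(WINDOW_LENGTH - 1)
        cosk = np.cos(2 * np.pi * idx / _PERIOD)
        sink = np.sin(2 * np.pi * idx / _PERIOD)
        c = np.correlate(d, cosk, mode="valid")
        s = np.correlate(d, sink, mode="valid")
        csum = np.concatenate([[0.0], np.cumsum(d)])
        tot = csum[WINDOW_LENGTH - 1:] - csum[:SITE_LENGTH]
        aff = np.sqrt(c * c + s * s) / np.maximum(tot, 1.0)
        raw[3] = aff
        raw[2] = 1.0 / (1.0 + np.exp(-6.0 * (aff - 0.25)))
    else:
        for j, window in enumerate(extract_windows(genome, pair)):
            occ, aff = provider.scores(window)
            raw[2, j] = occ
            raw[3, j] = aff
    return raw


def descriptor_matrix(genome, pair: SgRNATargetPair, config: DescriptorConfig) -> PhysicalDescriptors:
    """Normalized 4 x 23 descriptor matrix for one site.

    Requires ``config.norm_stats`` (dataset-level min/max fitted on the
    training set); rows are min-max scaled and clipped into [0, 1].
    """
    if config.norm_stats is None:
        raise ConfigurationError("descriptor_matrix requires fitted norm_stats in config")
    raw = raw_descriptor_matrix(genome, pair, config)
    return PhysicalDescriptors(config.norm_stats.apply(raw))
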