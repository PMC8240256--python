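"""Degenerate (IUPAC) motif scanning and motif-composition statistics.

Motifs are degenerate DNA words (e.g. the E-Box ``CACRTG`` bound by the
CLOCK:BMAL1 heterodimer, the RORE ``RGGTCA`` bound by ROR/REV-ERB nuclear
receptors, and the D-Box ``TTATGYAA``). Each IUPAC column is treated as a
probability column uniform over its allowed bases against a flat 0.25
background, so a matching window scores ``sum(log2(4 / |allowed|))`` bits and
the exact null distribution of scores is computable by dynamic programming.

Beyond plain scanning the module provides hit merging with score averaging,
center-anchored score-weighted density profiles, nearest-motif spacing
(start-to-start, the convention under which a motif pair separated by a
6-nt spacer yields a 12-bp mode), discriminative k-mer enrichment between two
sequence sets, and the bound-vs-unbound motif-gain fold change used for
between-lineage comparisons.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .intervals import GenomeInterval

__all__ = [
    "IUPAC_CODES",
    "MotifDefinition",
    "MotifHit",
    "MergedHit",
    "DensityProfile",
    "MotifGain",
    "BUILTIN_MOTIFS",
    "reverse_complement",
    "scan_iupac",
    "threshold_scan",
    "merge_hits",
    "density_profile",
    "nearest_motif_spacing",
    "discriminative_kmer_enrichment",
    "motif_gain_fold_change",
]

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "K": "GT", "M": "AC", "S": "CG", "W": "AT",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYKMSWBDHVN", "TGCAYRMKSWVHDBN")
_MAX_EXACT_LENGTH = 16


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifDefinition:
    """A named degenerate DNA motif."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ParameterError("motif string must be non-empty")
        bad = set(self.iupac) - set(IUPAC_CODES)
        if bad:
            raise ParameterError(f"invalid IUPAC letter(s) {sorted(bad)} in {self.iupac!r}")

    def __len__(self) -> int:
        return len(self.iupac)

    @property
    def allowed(self) -> tuple[str, ...]:
        return tuple(IUPAC_CODES[c] for c in self.iupac)

    @property
    def max_score(self) -> float:
        """Log-odds score (bits) of any matching window."""
        return sum(math.log2(4 / len(a)) for a in self.allowed)

    @property
    def match_probability(self) -> float:
        """Probability a random i.i.d.-uniform window matches one strand."""
        return math.prod(len(a) / 4 for a in self.allowed)

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.iupac) == self.iupac

    def reverse_complemented(self) -> "MotifDefinition":
        return MotifDefinition(self.name, reverse_complement(self.iupac))


BUILTIN_MOTIFS: dict[str, MotifDefinition] = {
    "E-Box": MotifDefinition("E-Box", "CACRTG"),
    "E-Box-canonical": MotifDefinition("E-Box-canonical", "CACGTG"),
    "RORE": MotifDefinition("RORE", "RGGTCA"),
    "RORE-optimal": MotifDefinition("RORE-optimal", "AGGTCA"),
    "D-Box": MotifDefinition("D-Box", "TTATGYAA"),
    "RORE-discriminative": MotifDefinition("RORE-discriminative", "AGGKCA"),
}


@dataclass(frozen=True)
class MotifHit:
    """One motif match, in plus-strand coordinates of the scanned sequence."""

    interval: GenomeInterval
    strand: str
    score: float
    motif: str
    is_top_score: bool


@dataclass(frozen=True)
class MergedHit:
    """A maximal chain of overlapping hits collapsed to its union span."""

    interval: GenomeInterval
    score: float  # arithmetic mean of member scores
    n_members: int


@dataclass
class DensityProfile:
    """Mean score-weighted motif occurrence around region centers."""

    offsets: np.ndarray  # -flank .. +flank
    values: np.ndarray
    n_regions: int
    coverage: np.ndarray  # number of regions contributing at each offset


@dataclass(frozen=True)
class MotifGain:
    """Per-sequence mean motif count in bound vs unbound sequence sets."""

    fold: float
    bound_mean: float
    unbound_mean: float
    undefined_denominator: bool


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(sequence: str) -> np.ndarray:
    codes = np.full(len(sequence), 4, dtype=np.int8)  # 4 = N / anything else
    for base, code in _BASE_CODE.items():
        codes[np.frombuffer(sequence.encode(), dtype=np.uint8) == ord(base)] = code
    return codes


def _score_matrix(motif: MotifDefinition) -> np.ndarray:
    """Per-column log2 score for each base; -inf where disallowed; N never matches."""
    m = np.full((len(motif), 5), -np.inf)
    for i, allowed in enumerate(motif.allowed):
        for b in allowed:
            m[i, _BASE_CODE[b]] = math.log2(4 / len(allowed))
    return m


def _window_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    L = matrix.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    total = np.zeros(n)
    for i in range(L):
        total += matrix[i, codes[i:i + n]]
    return total


def _strand_hits(
    sequence_codes: np.ndarray,
    motif: MotifDefinition,
    min_score: float,
    chrom: str,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Positions and scores per strand with window score >= min_score."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for strand, m in (("+", motif), ("-", motif.reverse_complemented())):
        scores = _window_scores(sequence_codes, _score_matrix(m))
        if min_score == -np.inf:
            pos = np.arange(len(scores))
        else:
            pos = np.nonzero(scores >= min_score - 1e-9)[0]
        out[strand] = (pos, scores[pos])
    return out


def _collapse_and_build(
    per_strand: dict[str, tuple[np.ndarray, np.ndarray]],
    motif: MotifDefinition,
    chrom: str,
    both_strands: bool,
) -> list[MotifHit]:
    hits: list[tuple[int, str, float]] = []
    plus_pos = set(per_strand["+"][0].tolist())
    for p, s in zip(*per_strand["+"]):
        hits.append((int(p), "+", float(s)))
    if both_strands:
        for p, s in zip(*per_strand["-"]):
            # palindromic motifs: a minus hit at the same window duplicates the
            # plus hit; keep the plus-strand copy only
            if motif.is_palindromic and int(p) in plus_pos:
                continue
            hits.append((int(p), "-", float(s)))
    hits.sort(key=lambda h: (h[0], h[1]))
    top = motif.max_score
    out = []
    for p, strand, s in hits:
        out.append(
            MotifHit(
                interval=GenomeInterval(chrom, p, p + len(motif), strand=strand,
                                        name=motif.name, score=s),
                strand=strand,
                score=s,
                motif=motif.name,
                is_top_score=bool(np.isfinite(s) and s >= top - 1e-9),
            )
        )
    return out


def scan_iupac(
    sequence: str,
    motif: MotifDefinition,
    both_strands: bool = True,
    chrom: str = "seq",
) -> list[MotifHit]:
    """Report every window matching the degenerate pattern.

    Minus-strand hits are reported in plus-strand coordinates with strand
    ``-``; for palindromic motifs the redundant minus-strand self-hit is
    collapsed onto the plus strand. Windows containing ``N`` never match.
    """
    codes = _encode(sequence.upper())
    per_strand = _strand_hits(codes, motif, motif.max_score, chrom)
    return _collapse_and_build(per_strand, motif, chrom, both_strands)


def _null_survival(motif: MotifDefinition) -> list[tuple[float, float]]:
    """Exact (score, P(S >= score)) pairs under the i.i.d. uniform null.

    Computed by dynamic programming over per-column score distributions;
    windows containing a disallowed base have score -inf and survival 1.
    """
    dist: dict[float, float] = {0.0: 1.0}
    dead = 0.0
    for allowed in motif.allowed:
        col_score = math.log2(4 / len(allowed))
        p_match = len(allowed) / 4
        new: dict[float, float] = {}
        for s, p in dist.items():
            key = round(s + col_score, 9)
            new[key] = new.get(key, 0.0) + p * p_match
        dead += sum(dist.values()) * (1 - p_match)
        dist = new
    pairs = sorted(dist.items(), reverse=True)
    out: list[tuple[float, float]] = []
    cum = 0.0
    for s, p in pairs:
        cum += p
        out.append((s, cum))
    out.append((-np.inf, 1.0))
    return out


def threshold_scan(
    sequence: str,
    motif: MotifDefinition,
    p_threshold: float = 0.01,
    both_strands: bool = True,
    chrom: str = "seq",
) -> list[MotifHit]:
    """Report windows whose score has exact null probability <= p_threshold.

    The score-to-p map is exact (dynamic programming over per-column score
    distributions), so at maximal stringency this reduces to
    :func:`scan_iupac`. At ``p_threshold=1.0`` every window is reported.
    """
    if len(motif) > _MAX_EXACT_LENGTH:
        raise ParameterError(
            f"motif length {len(motif)} exceeds exact-null bound {_MAX_EXACT_LENGTH}"
        )
    if not (0 < p_threshold <= 1):
        raise ParameterError(f"p_threshold must be in (0, 1], got {p_threshold}")
    survival = _null_survival(motif)
    # smallest score whose survival probability is still within the threshold
    passing = [s for s, p in survival if p <= p_threshold]
    min_score = min(passing) if passing else np.inf
    if p_threshold >= 1.0:
        min_score = -np.inf
    codes = _encode(sequence.upper())
    per_strand = _strand_hits(codes, motif, min_score, chrom)
    return _collapse_and_build(per_strand, motif, chrom, both_strands)


# ---------------------------------------------------------------------------
# Hit aggregation
# ---------------------------------------------------------------------------

def merge_hits(hits: Sequence[MotifHit]) -> list[MergedHit]:
    """Collapse maximal chains of transitively overlapping hits.

    Each merged record spans the union of its members and carries the
    arithmetic mean of member scores (strand-agnostic, like bedtools merge).
    """
    ordered = sorted(hits, key=lambda h: (h.interval.chrom, h.interval.start, h.interval.end))
    merged: list[MergedHit] = []
    chain: list[MotifHit] = []

    def _flush() -> None:
        if chain:
            merged.append(
                MergedHit(
                    interval=GenomeInterval(
                        chain[0].interval.chrom,
                        chain[0].interval.start,
                        max(h.interval.end for h in chain),
                        name=chain[0].motif,
                    ),
                    score=float(np.mean([h.score for h in chain])),
                    n_members=len(chain),
                )
            )

    for h in ordered:
        if (
            chain
            and h.interval.chrom == chain[0].interval.chrom
            and h.interval.start < max(c.interval.end for c in chain)
        ):
            chain.append(h)
        else:
            _flush()
            chain = [h]
    _flush()
    return merged


def density_profile(
    regions: Sequence[GenomeInterval],
    merged_hits: Sequence[MergedHit],
    flank: int = 100,
    seq_lengths: Optional[dict[str, int]] = None,
) -> DensityProfile:
    """Score-weighted motif occurrence around region centers, +/- flank bp.

    Minus-strand regions are flipped so profiles are orientation-normalized.
    Windows truncated by a sequence end are masked rather than zero-filled,
    so each offset averages only over the regions that actually cover it.
    """
    if not regions:
        raise ParameterError("regions must be non-empty")
    width = 2 * flank + 1
    values = np.zeros(width)
    coverage = np.zeros(width, dtype=np.int64)
    by_chrom: dict[str, list[MergedHit]] = {}
    for h in merged_hits:
        by_chrom.setdefault(h.interval.chrom, []).append(h)

    for region in regions:
        center = region.center
        win_lo, win_hi = center - flank, center + flank + 1
        lo_valid = max(win_lo, 0)
        hi_valid = win_hi
        if seq_lengths is not None and region.chrom in seq_lengths:
            hi_valid = min(win_hi, seq_lengths[region.chrom])
        if hi_valid <= lo_valid:
            continue
        local = np.zeros(width)
        for h in by_chrom.get(region.chrom, []):
            a = max(h.interval.start, lo_valid) - win_lo
            b = min(h.interval.end, hi_valid) - win_lo
            if b > a:
                local[a:b] += h.score
        mask = np.zeros(width, dtype=bool)
        mask[lo_valid - win_lo: hi_valid - win_lo] = True
        if region.strand == "-":
            local = local[::-1]
            mask = mask[::-1]
        values[mask] += local[mask]
        coverage += mask
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(coverage > 0, values / np.maximum(coverage, 1), 0.0)
    return DensityProfile(
        offsets=np.arange(-flank, flank + 1),
        values=mean,
        n_regions=len(regions),
        coverage=coverage,
    )


def nearest_motif_spacing(
    hits: Sequence[MotifHit],
    top_score_only: bool = True,
) -> list[int]:
    """Start-to-start distance from each retained hit to the nearest
    non-overlapping retained hit, pooled across sequences.

    Under this convention a pair of 6-mers separated by a 6-nt spacer yields
    a spacing of 12 bp. Sequences with fewer than two retained hits
    contribute nothing.
    """
    retained = [h for h in hits if h.is_top_score] if top_score_only else list(hits)
    by_chrom: dict[str, list[MotifHit]] = {}
    for h in retained:
        by_chrom.setdefault(h.interval.chrom, []).append(h)
    distances: list[int] = []
    for chrom_hits in by_chrom.values():
        chrom_hits.sort(key=lambda h: (h.interval.start, h.interval.end))
        n = len(chrom_hits)
        for i, h in enumerate(chrom_hits):
            best: Optional[int] = None
            # start-sorted: the first non-overlapping hit on each side is the
            # nearest one on that side
            for j in range(i + 1, n):
                other = chrom_hits[j]
                if h.interval.overlap_bp(other.interval) == 0:
                    best = abs(other.interval.start - h.interval.start)
                    break
            for j in range(i - 1, -1, -1):
                other = chrom_hits[j]
                if h.interval.overlap_bp(other.interval) == 0:
                    d = abs(other.interval.start - h.interval.start)
                    if best is None or d < best:
                        best = d
                    break
            if best is not None:
                distances.append(best)
    return distances


# ---------------------------------------------------------------------------
# Set-level statistics
# ---------------------------------------------------------------------------

def _canonical_kmers(seq: str, k: int) -> set[str]:
    seq = seq.upper()
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if set(w) - {"A", "C", "G", "T"}:
            continue
        out.add(min(w, reverse_complement(w)))
    return out


def discriminative_kmer_enrichment(
    foreground: Sequence[str],
    background: Sequence[str],
    k: int,
) -> pd.DataFrame:
    """Per-k-mer presence enrichment of foreground over background sequences.

    Each k-mer is collapsed with its reverse complement; the table reports
    the fraction of sequences in each set containing it, the fold ratio, and
    a one-sided exact (hypergeometric) p-value, sorted by ascending p.
    """
    if not foreground or not background:
        raise ParameterError("both sequence sets must be non-empty")
    if k > 8:
        raise ParameterError(f"k must be <= 8, got {k}")
    shortest = min(len(s) for s in itertools.chain(foreground, background))
    if k > shortest:
        raise ParameterError(f"k={k} larger than shortest sequence ({shortest} nt)")
    fg_counts: Counter[str] = Counter()
    bg_counts: Counter[str] = Counter()
    for s in foreground:
        fg_counts.update(_canonical_kmers(s, k))
    for s in background:
        bg_counts.update(_canonical_kmers(s, k))
    kmers = sorted(set(fg_counts) | set(bg_counts))
    nf, nb = len(foreground), len(background)
    fg = np.array([fg_counts.get(km, 0) for km in kmers])
    bg = np.array([bg_counts.get(km, 0) for km in kmers])
    fg_frac = fg / nf
    bg_frac = bg / nb
    with np.errstate(divide="ignore"):
        fold = np.where(bg_frac > 0, fg_frac / np.where(bg_frac > 0, bg_frac, 1), np.inf)
        fold = np.where((bg_frac == 0) & (fg_frac == 0), 1.0, fold)
    # one-sided Fisher exact == hypergeometric upper tail
    p = stats.hypergeom.sf(fg - 1, nf + nb, fg + bg, nf)
    table = pd.DataFrame(
        {"kmer": kmers, "fg_fraction": fg_frac, "bg_fraction": bg_frac, "fold": fold, "p": p}
    )
    return table.sort_values(["p", "kmer"], kind="mergesort").reset_index(drop=True)


def motif_gain_fold_change(
    bound_seqs: Sequence[str],
    unbound_seqs: Sequence[str],
    motif: MotifDefinition,
) -> MotifGain:
    """Fold change in per-sequence mean motif count, bound over unbound.

    A zero hit count in the unbound set yields an infinite fold flagged via
    ``undefined_denominator`` rather than an exception. Applied per species
    to ortholog sets, this is the motif-gain comparison statistic.
    """
    if not bound_seqs or not unbound_seqs:
        raise ParameterError("both sequence sets must be non-empty")
    bound_mean = float(np.mean([len(scan_iupac(s, motif)) for s in bound_seqs]))
    unbound_mean = float(np.mean([len(scan_iupac(s, motif)) for s in unbound_seqs]))
    if unbound_mean == 0.0:
        return MotifGain(float("inf"), bound_mean, unbound_mean, True)
    return MotifGain(bound_mean / unbound_mean, bound_mean, unbound_mean, False)
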