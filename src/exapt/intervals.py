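"""Genomic intervals, repeat annotations, and the repeat-overlap peak classifier.

All coordinates are 0-based, half-open ``[start, end)`` — the native BED
convention, which the UCSC RepeatMasker track dialect also uses for its
``genoStart``/``genoEnd`` columns.

The central operation is :func:`classify_rabs`, which labels each
ChIP-seq-style peak as a Repeat-Associated Binding Site (RABS) when a single
repeat covers at least ``min_fraction`` of the peak's length, mirroring the
``bedtools intersect -f 0.5`` semantics commonly used for this analysis.
Overlap is always attributed to the single best repeat (maximal overlap,
ties broken by leftmost repeat start), never to a union of repeats.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import BoundsError, ParameterError, ParseError, SamplingError, SchemaError

__all__ = [
    "ChromSizes",
    "GenomeInterval",
    "RepeatAnnotation",
    "OverlapCall",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "read_repeatmasker_table",
    "write_repeatmasker_table",
    "classify_rabs",
    "nearest_distance",
    "matched_random_repeats",
]

#: repeat classes removed on ingest, following standard RepeatMasker filtering
EXCLUDED_REPEAT_CLASSES = frozenset({"Low_complexity", "Simple_repeat"})


@dataclass(frozen=True)
class ChromSizes:
    """Chromosome name -> length (bp) mapping used to bound-check intervals."""

    entries: Mapping[str, int]

    def __post_init__(self) -> None:
        for name, length in self.entries.items():
            if length <= 0:
                raise ParameterError(f"chromosome {name!r} has non-positive length {length}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.entries

    def __getitem__(self, chrom: str) -> int:
        return self.entries[chrom]

    def validate(self, interval: "GenomeInterval") -> None:
        if interval.chrom not in self.entries:
            raise BoundsError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > self.entries[interval.chrom]:
            raise BoundsError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} exceeds "
                f"chromosome length {self.entries[interval.chrom]}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "ChromSizes":
        return read_chrom_sizes(path)


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A 0-based half-open genomic interval with optional strand/name/score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ParameterError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ParameterError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomeInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class RepeatAnnotation:
    """A single repeat copy with family/class labels and optional divergence."""

    interval: GenomeInterval
    family: str
    class_name: str
    divergence_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.family:
            raise ParameterError("repeat family must be non-empty")


@dataclass(frozen=True)
class OverlapCall:
    """The classification of one peak against the repeat annotation.

    ``repeat`` is present only for RABS calls; Non-RABS peaks still report the
    best overlap found (possibly 0) through ``overlap_bp``/``fraction_of_peak``.
    """

    peak: GenomeInterval
    repeat: Optional[RepeatAnnotation]
    overlap_bp: int
    fraction_of_peak: float
    label: str  # "RABS" or "Non-RABS"

    @property
    def is_rabs(self) -> bool:
        return self.label == "RABS"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Read a two-column (name, length) chromosome-sizes file."""
    entries: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns, got {line!r}")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer length {parts[1]!r}") from exc
            if name in entries:
                raise ParseError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            entries[name] = length
    return ChromSizes(entries)


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sizes.entries):
            fh.write(f"{name}\t{sizes.entries[name]}\n")


def read_bed(path: str | Path, chromsizes: Optional[ChromSizes] = None) -> list[GenomeInterval]:
    """Read a BED3+ file into intervals, in file order.

    Optional columns 4-6 (name, score, strand) populate the corresponding
    fields when present. Coordinates are validated against ``chromsizes``
    when it is given.
    """
    out: list[GenomeInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates in {line!r}") from exc
            if start >= end or start < 0:
                raise ParseError(f"{path}:{lineno}: invalid coordinates start={start} end={end}")
            name = parts[3] if len(parts) > 3 else ""
            try:
                score = float(parts[4]) if len(parts) > 4 and parts[4] not in (".", "") else 0.0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score {parts[4]!r}") from exc
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
            interval = GenomeInterval(parts[0], start, end, strand=strand, name=name, score=score)
            if chromsizes is not None:
                try:
                    chromsizes.validate(interval)
                except BoundsError as exc:
                    raise BoundsError(f"{path}:{lineno}: {exc}") from exc
            out.append(interval)
    return out


def write_bed(intervals: Iterable[GenomeInterval], path: str | Path) -> None:
    """Write intervals as sorted BED6."""
    rows = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in rows:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{iv.score:g}\t{iv.strand}\n"
            )


_RMSK_REQUIRED = (
    "genoName",
    "genoStart",
    "genoEnd",
    "strand",
    "repName",
    "repClass",
    "repFamily",
    "milliDiv",
)


def read_repeatmasker_table(path: str | Path) -> list[RepeatAnnotation]:
    """Read a UCSC RepeatMasker track table (tab-separated, with header).

    Records whose ``repClass`` is ``Low_complexity`` or ``Simple_repeat`` are
    dropped. ``milliDiv`` (substitutions per 1000 bp) is converted to percent
    divergence. Coordinates in this dialect are already 0-based half-open.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#").split("\t")
        col = {name: i for i, name in enumerate(header)}
        missing = [c for c in _RMSK_REQUIRED if c not in col]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
        out: list[RepeatAnnotation] = []
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            try:
                start = int(parts[col["genoStart"]])
                end = int(parts[col["genoEnd"]])
                millidiv = float(parts[col["milliDiv"]])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed row {line!r}") from exc
            repclass = parts[col["repClass"]]
            if repclass in EXCLUDED_REPEAT_CLASSES:
                continue
            strand = parts[col["strand"]]
            interval = GenomeInterval(
                parts[col["genoName"]],
                start,
                end,
                strand=strand if strand in ("+", "-") else ".",
                name=parts[col["repName"]],
            )
            out.append(
                RepeatAnnotation(
                    interval=interval,
                    family=parts[col["repName"]],
                    class_name=repclass,
                    divergence_pct=millidiv / 10.0,
                )
            )
    return out


def write_repeatmasker_table(repeats: Iterable[RepeatAnnotation], path: str | Path) -> None:
    """Write repeats in the UCSC RepeatMasker track dialect (sorted)."""
    rows = sorted(repeats, key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_RMSK_REQUIRED) + "\n")
        for r in rows:
            iv = r.interval
            millidiv = 0.0 if r.divergence_pct is None else r.divergence_pct * 10.0
            strand = iv.strand if iv.strand in ("+", "-") else "+"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{strand}\t{r.family}\t"
                f"{r.class_name}\t{r.class_name}\t{millidiv:g}\n"
            )


# ---------------------------------------------------------------------------
# Overlap machinery
# ---------------------------------------------------------------------------

@dataclass
class _ChromIndex:
    """Start-sorted interval arrays with a running-max of ends.

    Because the running maximum of ends is non-decreasing, all intervals that
    may overlap a query [qs, qe) live in the sorted slice
    [searchsorted(cummax_end, qs, 'right'), searchsorted(starts, qe, 'left'));
    candidates inside the slice are then filtered by actual overlap.
    """

    starts: np.ndarray
    ends: np.ndarray
    order: np.ndarray  # sorted position -> original index
    cummax_end: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.cummax_end = np.maximum.accumulate(self.ends)

    @classmethod
    def build(cls, starts: Sequence[int], ends: Sequence[int]) -> "_ChromIndex":
        s = np.asarray(starts, dtype=np.int64)
        e = np.asarray(ends, dtype=np.int64)
        order = np.lexsort((e, s))
        return cls(starts=s[order], ends=e[order], order=order)

    def candidate_slices(self, qstarts: np.ndarray, qends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self.cummax_end, qstarts, side="right")
        hi = np.searchsorted(self.starts, qends, side="left")
        return lo, np.maximum(hi, lo)


def _overlap_pairs(
    qstarts: np.ndarray, qends: np.ndarray, index: _ChromIndex
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (query_i, subject_sorted_j, overlap_bp>0) pairs on one chromosome."""
    lo, hi = index.candidate_slices(qstarts, qends)
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty
    qi = np.repeat(np.arange(len(qstarts)), counts)
    # concatenated ranges lo[i]..hi[i]
    offsets = np.concatenate(([0], np.cumsum(counts)))[:-1]
    sj = np.arange(total) - np.repeat(offsets, counts) + np.repeat(lo, counts)
    ov = np.minimum(qends[qi], index.ends[sj]) - np.maximum(qstarts[qi], index.starts[sj])
    keep = ov > 0
    return qi[keep], sj[keep], ov[keep]


def classify_rabs(
    peaks: Sequence[GenomeInterval],
    repeats: Sequence[RepeatAnnotation],
    min_fraction: float = 0.5,
) -> list[OverlapCall]:
    """Label peaks as RABS / Non-RABS by single-best-repeat overlap fraction.

    A peak is RABS iff some single repeat covers ``>= min_fraction`` of the
    peak's length. When several repeats qualify the one with maximal overlap
    is attributed (ties broken by leftmost repeat start, then leftmost end).
    Results are returned in peak input order.
    """
    if not (0 < min_fraction <= 1):
        raise ParameterError(f"min_fraction must be in (0, 1], got {min_fraction}")
    calls: list[Optional[OverlapCall]] = [None] * len(peaks)
    if not peaks:
        return []

    by_chrom_peaks: dict[str, list[int]] = {}
    for i, pk in enumerate(peaks):
        by_chrom_peaks.setdefault(pk.chrom, []).append(i)
    by_chrom_reps: dict[str, list[int]] = {}
    for j, rp in enumerate(repeats):
        by_chrom_reps.setdefault(rp.interval.chrom, []).append(j)

    for chrom, peak_ids in by_chrom_peaks.items():
        qstarts = np.array([peaks[i].start for i in peak_ids], dtype=np.int64)
        qends = np.array([peaks[i].end for i in peak_ids], dtype=np.int64)
        rep_ids = by_chrom_reps.get(chrom, [])
        best_ov = np.zeros(len(peak_ids), dtype=np.int64)
        best_rep = np.full(len(peak_ids), -1, dtype=np.int64)
        if rep_ids:
            index = _ChromIndex.build(
                [repeats[j].interval.start for j in rep_ids],
                [repeats[j].interval.end for j in rep_ids],
            )
            qi, sj, ov = _overlap_pairs(qstarts, qends, index)
            if len(qi):
                # best repeat per peak: max overlap, then leftmost start/end
                rank = np.lexsort((index.ends[sj], index.starts[sj], -ov, qi))
                qi, sj, ov = qi[rank], sj[rank], ov[rank]
                first = np.ones(len(qi), dtype=bool)
                first[1:] = qi[1:] != qi[:-1]
                best_ov[qi[first]] = ov[first]
                chrom_rep_ids = np.asarray(rep_ids, dtype=np.int64)
                best_rep[qi[first]] = chrom_rep_ids[index.order[sj[first]]]
        for k, i in enumerate(peak_ids):
            pk = peaks[i]
            ov = int(best_ov[k])
            is_rabs = ov > 0 and ov >= min_fraction * pk.length
            calls[i] = OverlapCall(
                peak=pk,
                repeat=repeats[int(best_rep[k])] if is_rabs else None,
                overlap_bp=ov,
                fraction_of_peak=ov / pk.length,
                label="RABS" if is_rabs else "Non-RABS",
            )
    return [c for c in calls if c is not None]


def nearest_distance(
    queries: Sequence[GenomeInterval],
    subjects: Sequence[GenomeInterval],
) -> list[tuple[GenomeInterval, Optional[GenomeInterval], Optional[int]]]:
    """Edge-gap distance from each query to its nearest subject.

    Overlapping or bookended intervals have distance 0. Queries on
    chromosomes with no subject report ``(query, None, None)``. On distance
    ties the upstream (leftmost-start) subject is reported.
    """
    if not subjects:
        raise ParameterError("subjects must be non-empty")
    by_chrom: dict[str, list[int]] = {}
    for j, s in enumerate(subjects):
        by_chrom.setdefault(s.chrom, []).append(j)

    results: list[tuple[GenomeInterval, Optional[GenomeInterval], Optional[int]]] = []
    indexes: dict[str, tuple[_ChromIndex, np.ndarray, np.ndarray]] = {}
    for chrom, ids in by_chrom.items():
        idx = _ChromIndex.build(
            [subjects[j].start for j in ids], [subjects[j].end for j in ids]
        )
        # sorted position of first interval attaining each running-max end
        n = len(ids)
        attained = np.zeros(n, dtype=np.int64)
        prev = np.concatenate(([np.iinfo(np.int64).min], idx.cummax_end[:-1]))
        new_max = idx.ends > prev
        attained[new_max] = np.nonzero(new_max)[0]
        attained = np.maximum.accumulate(attained)
        indexes[chrom] = (idx, np.asarray(ids, dtype=np.int64), attained)

    for q in queries:
        if q.chrom not in indexes:
            results.append((q, None, None))
            continue
        idx, ids, attained = indexes[q.chrom]
        # distance-0 candidates (overlapping or bookended): start <= q.end and
        # end >= q.start; report the leftmost-start one
        hi_zero = int(np.searchsorted(idx.starts, q.end, side="right"))
        lo_zero = int(np.searchsorted(idx.cummax_end, q.start, side="left"))
        zero_j = None
        for sj in range(lo_zero, hi_zero):
            if idx.ends[sj] >= q.start:
                zero_j = sj
                break
        if zero_j is not None:
            results.append((q, subjects[int(ids[idx.order[zero_j]])], 0))
            continue
        hi = int(np.searchsorted(idx.starts, q.end, side="left"))
        left_gap = right_gap = None
        left_j = right_j = None
        if hi > 0:
            left_j = int(attained[hi - 1])
            left_gap = int(q.start - idx.cummax_end[hi - 1])
        if hi < len(idx.starts):
            right_j = hi
            right_gap = int(idx.starts[hi] - q.end)
        if left_gap is not None and (right_gap is None or left_gap <= right_gap):
            results.append((q, subjects[int(ids[idx.order[left_j]])], max(left_gap, 0)))
        else:
            results.append((q, subjects[int(ids[idx.order[right_j]])], max(right_gap, 0)))
    return results


def matched_random_repeats(
    calls: Sequence[OverlapCall],
    all_repeats: Sequence[RepeatAnnotation],
    seed: int,
) -> list[RepeatAnnotation]:
    """Draw a random repeat set matching the RABS calls' family composition.

    Sampling is uniform without replacement within each family and
    deterministic for a fixed seed.
    """
    composition = Counter(c.repeat.family for c in calls if c.is_rabs and c.repeat is not None)
    pools: dict[str, list[RepeatAnnotation]] = {}
    for r in all_repeats:
        if r.family in composition:
            pools.setdefault(r.family, []).append(r)
    rng = np.random.default_rng(seed)
    out: list[RepeatAnnotation] = []
    for family in sorted(composition):
        need = composition[family]
        pool = pools.get(family, [])
        if len(pool) < need:
            raise SamplingError(
                f"family {family!r}: need {need} copies but only {len(pool)} available"
            )
        chosen = rng.choice(len(pool), size=need, replace=False)
        out.extend(pool[int(i)] for i in chosen)
    return out
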