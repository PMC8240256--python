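"""Proto-motif annotation, substitution paths, and motif maturation.

A *proto-motif* is a window in a transposable-element consensus that is a
near-match (small Hamming distance) to a canonical transcription-factor
binding motif. After transposition, individual element copies accumulate
point mutations; when a copy's proto-motif window comes to equal the
canonical motif, the motif has *matured*. The dominant mutational channel
for this in mammalian genomes is spontaneous deamination of methylated
cytosine at CpG dinucleotides, seen on the plus strand as C->T (when the C
is immediately followed by G) or as G->A (when the G is immediately preceded
by C, i.e. deamination on the minus strand).

The module also provides the Kimura 2-parameter divergence estimator
``d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))`` where ``P`` and ``Q`` are the
transition and transversion proportions over ungapped aligned sites.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio import Align

from .errors import ConfigurationError, ParameterError
from .motifs import IUPAC_CODES, MotifDefinition, reverse_complement

__all__ = [
    "ProtoMotif",
    "ConsensusModel",
    "SubstitutionEvent",
    "MaturationCall",
    "K2PResult",
    "find_proto_motifs",
    "substitution_path",
    "evolve_consensus",
    "classify_maturation",
    "k2p_divergence",
]

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass(frozen=True)
class ProtoMotif:
    """An (im)perfect motif occurrence in a consensus sequence.

    ``observed`` and ``canonical`` are motif-oriented: for a minus-strand
    proto-motif they are the reverse complement of the plus-strand window at
    ``offset``. A Hamming distance of zero is allowed (a perfect motif, e.g.
    a perfect antisense RORE).
    """

    label: str
    offset: int
    observed: str
    canonical: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.observed) != len(self.canonical):
            raise ParameterError(
                f"{self.label}: observed and canonical lengths differ "
                f"({len(self.observed)} vs {len(self.canonical)})"
            )
        if self.strand not in ("+", "-"):
            raise ParameterError(f"{self.label}: invalid strand {self.strand!r}")

    @property
    def mismatches(self) -> int:
        return sum(
            o not in IUPAC_CODES.get(c, c)
            for o, c in zip(self.observed, self.canonical)
        )


@dataclass
class ConsensusModel:
    """A consensus sequence annotated with its proto-motifs."""

    name: str
    sequence: str
    proto_motifs: list[ProtoMotif] = field(default_factory=list)

    def __post_init__(self) -> None:
        for pm in self.proto_motifs:
            if not (0 <= pm.offset and pm.offset + len(pm.observed) <= len(self.sequence)):
                raise ConfigurationError(
                    f"proto-motif {pm.label} at {pm.offset} outside consensus bounds"
                )
            window = self.sequence[pm.offset: pm.offset + len(pm.observed)]
            oriented = window if pm.strand == "+" else reverse_complement(window)
            if oriented != pm.observed:
                raise ConfigurationError(
                    f"proto-motif {pm.label}: annotated observed {pm.observed!r} does not "
                    f"match consensus window {oriented!r}"
                )

    def motif(self, label: str) -> ProtoMotif:
        for pm in self.proto_motifs:
            if pm.label == label:
                return pm
        raise KeyError(f"no proto-motif labelled {label!r}")

    def write(self, fasta_path: str | Path, annotation_path: str | Path) -> None:
        with open(fasta_path, "w") as fh:
            fh.write(f">{self.name}\n{self.sequence}\n")
        with open(annotation_path, "w") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["label", "offset", "observed", "canonical", "strand"])
            for pm in self.proto_motifs:
                writer.writerow([pm.label, pm.offset, pm.observed, pm.canonical, pm.strand])

    @classmethod
    def read(cls, fasta_path: str | Path, annotation_path: str | Path) -> "ConsensusModel":
        with open(fasta_path) as fh:
            header = fh.readline().strip().lstrip(">")
            sequence = "".join(line.strip() for line in fh)
        motifs: list[ProtoMotif] = []
        with open(annotation_path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                motifs.append(
                    ProtoMotif(
                        label=row["label"],
                        offset=int(row["offset"]),
                        observed=row["observed"],
                        canonical=row["canonical"],
                        strand=row["strand"],
                    )
                )
        return cls(name=header, sequence=sequence, proto_motifs=motifs)


@dataclass(frozen=True)
class SubstitutionEvent:
    """One point substitution within a motif window.

    ``deamination_consistent`` is true iff the change is C->T with the source
    C immediately followed by G, or G->A with the source G immediately
    preceded by C — both evaluated on the pre-mutation sequence with local
    flanking context. Positions whose required neighbour is unknown are
    conservatively classified non-consistent.
    """

    position: int
    from_base: str
    to_base: str
    deamination_consistent: bool

    def __post_init__(self) -> None:
        if self.from_base == self.to_base:
            raise ParameterError("substitution event requires from_base != to_base")


@dataclass(frozen=True)
class MaturationCall:
    """Maturation status of one proto-motif in one element copy."""

    copy_id: str
    proto_motif: str
    matured: bool
    events: tuple[SubstitutionEvent, ...]
    is_callable: bool = True

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class K2PResult:
    """Kimura 2-parameter divergence components."""

    P: float
    Q: float
    d: float
    n_sites: int
    defined: bool


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _matches_iupac(base: str, code: str) -> bool:
    return base in IUPAC_CODES.get(code, code)


def find_proto_motifs(
    consensus: str,
    canonical_motifs: Sequence[MotifDefinition],
    max_mismatch: int = 2,
) -> list[ProtoMotif]:
    """All windows within Hamming distance ``max_mismatch`` of any motif.

    Both strands are scanned; exact matches are included (distance 0).
    Overlapping reports for distinct canonical motifs are all retained.
    """
    if max_mismatch < 0:
        raise ParameterError("max_mismatch must be >= 0")
    consensus = consensus.upper()
    out: list[ProtoMotif] = []
    for motif in canonical_motifs:
        m = len(motif)
        for offset in range(len(consensus) - m + 1):
            window = consensus[offset: offset + m]
            for strand in ("+", "-"):
                oriented = window if strand == "+" else reverse_complement(window)
                dist = sum(
                    not _matches_iupac(b, c) for b, c in zip(oriented, motif.iupac)
                )
                if dist <= max_mismatch:
                    out.append(
                        ProtoMotif(
                            label=f"{motif.name}@{offset}({strand})",
                            offset=offset,
                            observed=oriented,
                            canonical=motif.iupac,
                            strand=strand,
                        )
                    )
    out.sort(key=lambda pm: (pm.offset, pm.label))
    return out


def _target_base(observed_base: str, canonical_code: str) -> str:
    """Concrete target for a mismatching column of a degenerate canonical."""
    allowed = IUPAC_CODES.get(canonical_code, canonical_code)
    if len(allowed) == 1:
        return allowed
    # degenerate column: prefer the deamination product where admissible
    if observed_base == "C" and "T" in allowed:
        return "T"
    if observed_base == "G" and "A" in allowed:
        return "A"
    return sorted(allowed)[0]


def substitution_path(
    observed: str,
    canonical: str,
    left_flank: str = "",
    right_flank: str = "",
) -> list[SubstitutionEvent]:
    """Minimum substitution path between equal-length motif strings.

    One event per mismatching position; deamination consistency is evaluated
    against the *observed* (pre-mutation) sequence extended by the supplied
    flanks. Gapped paths are out of scope.
    """
    if len(observed) != len(canonical):
        raise ParameterError(
            f"equal lengths required ({len(observed)} vs {len(canonical)}); "
            "gapped paths are not modelled"
        )
    observed = observed.upper()
    context = (left_flank + observed + right_flank).upper()
    shift = len(left_flank)
    events: list[SubstitutionEvent] = []
    for i, (src, code) in enumerate(zip(observed, canonical.upper())):
        if _matches_iupac(src, code):
            continue
        target = _target_base(src, code)
        ci = i + shift
        next_base = context[ci + 1] if ci + 1 < len(context) else None
        prev_base = context[ci - 1] if ci - 1 >= 0 else None
        consistent = (src == "C" and target == "T" and next_base == "G") or (
            src == "G" and target == "A" and prev_base == "C"
        )
        events.append(
            SubstitutionEvent(
                position=i, from_base=src, to_base=target,
                deamination_consistent=bool(consistent),
            )
        )
    return events


def evolve_consensus(
    model: ConsensusModel,
    substitutions: Sequence[tuple[str, str]],
) -> tuple[str, int]:
    """Replace named proto-motif windows by canonical targets, in place.

    Returns the evolved sequence and the number of positions that differ
    from the input consensus. Idempotent: a motif already canonical
    contributes zero substitutions.
    """
    seq = list(model.sequence)
    for label, target in substitutions:
        pm = model.motif(label)  # KeyError -> lookup error for unknown labels
        if len(target) != len(pm.observed):
            raise ParameterError(
                f"{label}: target length {len(target)} != motif length {len(pm.observed)}"
            )
        replacement = target if pm.strand == "+" else reverse_complement(target)
        seq[pm.offset: pm.offset + len(replacement)] = replacement
    evolved = "".join(seq)
    n_subs = sum(a != b for a, b in zip(model.sequence, evolved))
    return evolved, n_subs


def _alignment_columns(aligned_consensus: str) -> list[int]:
    """Map ungapped consensus position -> alignment column index."""
    cols = []
    for col, ch in enumerate(aligned_consensus):
        if ch != "-":
            cols.append(col)
    return cols


def classify_maturation(
    copies: Sequence[tuple[str, str]],
    model: ConsensusModel,
    aligned_consensus: Optional[str] = None,
) -> list[MaturationCall]:
    """Call maturation of each proto-motif in each (gappable) aligned copy.

    ``copies`` are (copy_id, aligned sequence) pairs on the coordinate system
    of ``aligned_consensus`` (defaults to the ungapped model sequence, i.e.
    substitution-only copies). Copies with a gap inside a motif window are
    flagged uncallable for that motif; otherwise the copy's window is
    compared with the canonical motif and the substitution path from the
    consensus proto-motif is reported.
    """
    reference = aligned_consensus if aligned_consensus is not None else model.sequence
    if reference.replace("-", "") != model.sequence:
        raise ParameterError("aligned consensus does not match the model sequence")
    col_of = _alignment_columns(reference)
    calls: list[MaturationCall] = []
    for copy_id, aligned in copies:
        if len(aligned) != len(reference):
            raise ParameterError(
                f"{copy_id}: alignment length {len(aligned)} != reference {len(reference)}"
            )
        for pm in model.proto_motifs:
            m = len(pm.observed)
            cols = [col_of[pm.offset + i] for i in range(m)]
            window = "".join(aligned[c] for c in cols)
            if "-" in window:
                calls.append(
                    MaturationCall(copy_id, pm.label, matured=False, events=(),
                                   is_callable=False)
                )
                continue
            # deamination context comes from the pre-mutation (consensus) source
            left = model.sequence[pm.offset - 1] if pm.offset > 0 else ""
            right = (
                model.sequence[pm.offset + m]
                if pm.offset + m < len(model.sequence)
                else ""
            )
            if pm.strand == "-":
                window_oriented = reverse_complement(window)
                left_o, right_o = reverse_complement(right), reverse_complement(left)
            else:
                window_oriented, left_o, right_o = window, left, right
            matured = all(
                _matches_iupac(b, c) for b, c in zip(window_oriented, pm.canonical)
            )
            events = tuple(
                substitution_path(pm.observed, window_oriented, left_o, right_o)
            )
            calls.append(
                MaturationCall(copy_id, pm.label, matured=matured, events=events)
            )
    return calls


def _pairwise_align(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global alignment with fixed scores (match +1, mismatch -1, gap -2)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    alignment = aligner.align(seq_a, seq_b)[0]  # first = deterministic traceback
    return str(alignment[0]), str(alignment[1])


def k2p_divergence(seq_a: str, seq_b: str, aligned: bool = True) -> K2PResult:
    """Kimura 2-parameter distance between two sequences.

    With ``aligned=True`` the inputs must be equal length; gap characters are
    skipped pairwise. Otherwise a built-in global aligner (match +1,
    mismatch -1, gap -2, deterministic traceback) is applied first. Inputs
    for which the logarithms are undefined return a flagged result.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if aligned:
        if len(seq_a) != len(seq_b):
            raise ParameterError("aligned sequences must have equal length")
        a, b = seq_a, seq_b
    else:
        a, b = _pairwise_align(seq_a.replace("-", ""), seq_b.replace("-", ""))
    transitions = transversions = n_sites = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n_sites += 1
        if x == y:
            continue
        same_class = ({x, y} <= _PURINES) or ({x, y} <= _PYRIMIDINES)
        if same_class:
            transitions += 1
        else:
            transversions += 1
    if n_sites == 0:
        return K2PResult(P=0.0, Q=0.0, d=float("nan"), n_sites=0, defined=False)
    P = transitions / n_sites
    Q = transversions / n_sites
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return K2PResult(P=P, Q=Q, d=float("nan"), n_sites=n_sites, defined=False)
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PResult(P=P, Q=Q, d=d, n_sites=n_sites, defined=True)
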