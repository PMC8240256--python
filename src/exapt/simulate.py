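"""Synthetic genomes with a SINE amplification burst and full ground truth.

The generator emulates the study system end to end so every analysis stage
can be exercised without any external data:

* an i.i.d.-uniform background genome with TSS anchors and pre-existing
  ("ancestral") regulator binding sites;
* a burst of element copies radiating independently from one consensus
  (star phylogeny) under a per-site substitution model with an elevated,
  deamination-specific rate at CpG sites (``kappa``-fold, default 10x);
* insertion placement with an optional bias toward the neighbourhood of
  ancestral sites;
* peak calls that depend on maturation of the consensus's designated E-Box
  proto-motif pair, with a binding probability boosted for proximally
  inserted copies;
* an optional post-split sister lineage (mouse-like / rat-like) with
  independent mutations and lineage-specific copy loss, linked by an
  ortholog map.

Every sampled decision is recorded in a ground-truth table, the acceptance
surface for recovery tests. All outputs are deterministic for a fixed seed.

The default consensus is a synthetic stand-in for a B4-superfamily SINE
consensus: a screened random background carrying one perfect antisense RORE,
two imperfect sense ROREs, one central imperfect E-Box, and — the feature
that matters for circadian-regulator binding — a pair of CpG-path E-Box
proto-motifs (CACGCG) separated by a 6-nt spacer near the 3' end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError
from .intervals import (
    ChromSizes,
    GenomeInterval,
    RepeatAnnotation,
    write_bed,
    write_chrom_sizes,
    write_repeatmasker_table,
)
from .enrichment import TSSSet
from .maturation import ConsensusModel, ProtoMotif, classify_maturation
from .motifs import reverse_complement

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedDataset",
    "LineageSplit",
    "default_consensus",
    "simulate_genome",
    "amplify_te",
    "place_insertions",
    "derive_peaks",
    "simulate_lineage_split",
    "simulate_dataset",
    "write_dataset",
    "mutate_sequences",
    "mutate_each",
    "EnrichmentScenario",
    "null_enrichment_scenario",
    "planted_enrichment_scenario",
]

# Synthetic consensus (147 nt): random background screened so that no window
# outside the annotated motifs is within Hamming distance 1 of CACGTG or an
# exact CACRTG/RGGTCA/TTATGYAA match, before or after maturation.
DEFAULT_CONSENSUS_SEQUENCE = (
    "TAATGAGCGGAGGATTGACCTGATTTGAGTTCGTATGGGCCCCCATCAAGGAGACCAGGG"
    "AGGTAGATCTCACATGGGCTGACAGGCCGCTCATATGGGTATACGGAAAGTCTGCCCCAG"
    "ATACACGCGCAAGACCACGCGGACGAT"
)

#: the proto-motif pair whose maturation licenses binding
DESIGNATED_EBOX_PAIR = ("E-Box 2", "E-Box 3")


def default_consensus() -> ConsensusModel:
    """Synthetic SINE consensus with the standard proto-motif annotation."""
    return ConsensusModel(
        name="synthetic-SINE-consensus",
        sequence=DEFAULT_CONSENSUS_SEQUENCE,
        proto_motifs=[
            ProtoMotif("RORE 1", 15, "AGGTCA", "AGGTCA", strand="-"),
            ProtoMotif("RORE 2", 27, "AGTTCG", "AGGTCA", strand="+"),
            ProtoMotif("RORE 3", 48, "AGGAGA", "AGGTCA", strand="+"),
            ProtoMotif("E-Box 1", 70, "CACATG", "CACGTG", strand="+"),
            ProtoMotif("E-Box 2", 123, "CACGCG", "CACGTG", strand="+"),
            ProtoMotif("E-Box 3", 135, "CACGCG", "CACGTG", strand="+"),
        ],
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study system.

    Defaults describe a desk-scale murine-like scenario: a 20-Mb genome
    carrying an 8000-copy focal burst plus an 8000-copy control family
    (~12% repeat density), a 10-fold CpG deamination multiplier, modest
    insertion bias toward ancestral sites, and binding coupled to maturation
    of the designated E-Box pair. ``mu`` sits near the maturation-yield
    optimum (``kappa * mu = 0.25``) so a usable minority of copies matures
    while most accumulate motif-breaking substitutions, echoing the
    bound-fraction regime of real SINE bursts. Binding of a matured copy is
    strongly context-dependent (base probability 0.1, boosted to ~1 near an
    ancestral site), reflecting the observation that bound copies lie far
    closer to pre-existing regulator sites than the family at large.
    """

    chrom_lengths: tuple[int, ...] = (5_000_000,) * 4
    n_tss: int = 2000
    n_ancestral_sites: int = 150
    n_te_copies: int = 8000
    family_name: str = "RSINE1"
    other_families: tuple[tuple[str, int], ...] = (("B4A", 8000),)
    mu: float = 0.025
    kappa: float = 10.0
    cpg_channel: str = "deamination"  # or "uniform"
    proximity_bias: float = 0.3
    proximity_window: int = 10_000
    maturation_coupling: float = 0.9
    binding_base_prob: float = 0.1
    binding_noise: float = 0.0
    peak_width: int = 200
    ancestral_site_width: int = 200
    post_split_mu: float = 0.025
    lineage_loss: float = 0.4
    consensus: Optional[ConsensusModel] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("mu", self.mu), ("proximity_bias", self.proximity_bias),
            ("maturation_coupling", self.maturation_coupling),
            ("binding_base_prob", self.binding_base_prob),
            ("binding_noise", self.binding_noise),
            ("post_split_mu", self.post_split_mu),
            ("lineage_loss", self.lineage_loss),
        ):
            if not (0 <= value <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.kappa < 1:
            raise ConfigurationError(f"kappa must be >= 1, got {self.kappa}")
        if self.n_te_copies < 0 or any(n < 0 for _, n in self.other_families):
            raise ConfigurationError("copy counts must be >= 0")
        if self.cpg_channel not in ("deamination", "uniform"):
            raise ConfigurationError(f"unknown cpg_channel {self.cpg_channel!r}")

    @property
    def consensus_model(self) -> ConsensusModel:
        return self.consensus if self.consensus is not None else default_consensus()

    @property
    def chromsizes(self) -> ChromSizes:
        return ChromSizes(
            {f"chr{i + 1}": length for i, length in enumerate(self.chrom_lengths)}
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        model = self.consensus_model
        d["consensus"] = {
            "name": model.name,
            "sequence": model.sequence,
            "proto_motifs": [dataclasses.asdict(pm) for pm in model.proto_motifs],
        }
        return d


@dataclass
class SimulationTruth:
    """Ground-truth labels for every emitted element copy."""

    table: pd.DataFrame  # indexed by copy_id

    @property
    def bound_ids(self) -> list[str]:
        return list(self.table.index[self.table["bound"]])

    @property
    def matured_pair_ids(self) -> list[str]:
        return list(self.table.index[self.table["matured_pair"]])


@dataclass
class LineageSplit:
    """Post-split sister sequences and the surviving ortholog pairs."""

    mouse: dict[str, str]
    rat: dict[str, str]
    ortholog_map: dict[str, str]


@dataclass
class SimulatedDataset:
    """All artifacts of one simulation, cross-referenced by copy_id."""

    config: SimulationConfig
    genome: dict[str, str]
    chromsizes: ChromSizes
    tss: TSSSet
    tss_intervals: list[GenomeInterval]
    ancestral_peaks: list[GenomeInterval]
    repeats: list[RepeatAnnotation]
    peaks: list[GenomeInterval]
    copy_sequences: dict[str, str]
    truth: SimulationTruth
    lineages: Optional[LineageSplit] = None


# ---------------------------------------------------------------------------
# Mutation engine
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.zeros(len(raw), dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        codes[raw == b] = i
    return codes


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _cpg_masks(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Positions of the C (resp. G) of every CpG dinucleotide."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c, is_g = arr == ord("C"), arr == ord("G")
    c_of_cpg = np.zeros(len(seq), dtype=bool)
    g_of_cpg = np.zeros(len(seq), dtype=bool)
    c_of_cpg[:-1] = is_c[:-1] & is_g[1:]
    g_of_cpg[1:] = is_g[1:] & is_c[:-1]
    return c_of_cpg, g_of_cpg


_MAX_SITE_PROB = 0.95  # cap so kappa * mu stays a probability


def mutate_sequences(
    source: str,
    n: int,
    mu: float,
    kappa: float,
    rng: np.random.Generator,
    cpg_channel: str = "deamination",
) -> tuple[list[str], list[list[tuple[int, str, str]]]]:
    """Independently mutate ``n`` descendants of ``source`` (star phylogeny).

    Each site mutates with probability ``mu``, multiplied by ``kappa``
    (capped at 0.95) at the C or G of a CpG dinucleotide in the source. With
    the ``deamination`` channel, CpG mutations are specifically C->T / G->A;
    elsewhere (and with the ``uniform`` channel everywhere) the target is
    uniform over the three alternatives.
    """
    L = len(source)
    codes = _encode(source)
    c_cpg, g_cpg = _cpg_masks(source)
    prob = np.full(L, mu)
    cpg = c_cpg | g_cpg
    prob[cpg] = min(_MAX_SITE_PROB, mu * kappa)
    mutated = rng.random((n, L)) < prob[None, :]
    shifts = rng.integers(1, 4, size=(n, L))  # uniform among 3 alternatives

    out_codes = np.broadcast_to(codes, (n, L)).copy()
    targets = (out_codes + shifts) % 4
    if cpg_channel == "deamination":
        targets[:, c_cpg] = 3  # C -> T
        targets[:, g_cpg] = 0  # G -> A
    out_codes[mutated] = targets[mutated]

    seqs = [_decode(out_codes[i]) for i in range(n)]
    records: list[list[tuple[int, str, str]]] = []
    for i in range(n):
        pos = np.nonzero(mutated[i])[0]
        records.append([(int(p), source[p], seqs[i][p]) for p in pos])
    return seqs, records


def mutate_each(
    sources: Sequence[str],
    mu: float,
    kappa: float,
    rng: np.random.Generator,
    cpg_channel: str = "deamination",
) -> list[str]:
    """Mutate each equal-length source sequence once (batched, vectorized).

    Same per-site model as :func:`mutate_sequences` but CpG context is taken
    from each row's own source.
    """
    if not sources:
        return []
    L = len(sources[0])
    if any(len(s) != L for s in sources):
        raise ParameterError("batched mutation requires equal-length sources")
    n = len(sources)
    codes = np.stack([_encode(s) for s in sources])
    arr = np.stack([np.frombuffer(s.encode(), dtype=np.uint8) for s in sources])
    is_c, is_g = arr == ord("C"), arr == ord("G")
    c_cpg = np.zeros((n, L), dtype=bool)
    g_cpg = np.zeros((n, L), dtype=bool)
    c_cpg[:, :-1] = is_c[:, :-1] & is_g[:, 1:]
    g_cpg[:, 1:] = is_g[:, 1:] & is_c[:, :-1]
    prob = np.full((n, L), mu)
    prob[c_cpg | g_cpg] = min(_MAX_SITE_PROB, mu * kappa)
    mutated = rng.random((n, L)) < prob
    targets = (codes + rng.integers(1, 4, size=(n, L))) % 4
    if cpg_channel == "deamination":
        targets[c_cpg] = 3
        targets[g_cpg] = 0
    out = codes.copy()
    out[mutated] = targets[mutated]
    return [_decode(out[i]) for i in range(n)]


# ---------------------------------------------------------------------------
# Simulation stages
# ---------------------------------------------------------------------------

def _validate_packing(config: SimulationConfig) -> None:
    model = config.consensus_model
    te_bp = config.n_te_copies * len(model.sequence)
    te_bp += sum(n * len(model.sequence) for _, n in config.other_families)
    feature_bp = te_bp + config.n_ancestral_sites * config.ancestral_site_width
    genome_bp = sum(config.chrom_lengths)
    if feature_bp > 0.5 * genome_bp:
        raise ConfigurationError(
            f"configured features ({feature_bp} bp) exceed half the genome "
            f"({genome_bp} bp): placement would force overlaps"
        )
    total_copies = config.n_te_copies + sum(n for _, n in config.other_families)
    if total_copies > 0 and config.n_tss < len(config.chrom_lengths):
        raise ConfigurationError(
            "need at least one TSS per chromosome when TE copies are simulated "
            f"(n_tss={config.n_tss}, chromosomes={len(config.chrom_lengths)})"
        )


def _per_chrom_counts(total: int, lengths: Sequence[int], rng: np.random.Generator,
                      at_least_one: bool) -> np.ndarray:
    lengths = np.asarray(lengths, dtype=float)
    n_chrom = len(lengths)
    base = np.ones(n_chrom, dtype=np.int64) if at_least_one else np.zeros(n_chrom, dtype=np.int64)
    remaining = total - int(base.sum())
    if remaining < 0:
        raise ConfigurationError(f"cannot place {total} features on {n_chrom} chromosomes")
    extra = rng.multinomial(remaining, lengths / lengths.sum())
    return base + extra


def simulate_genome(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, str], list[GenomeInterval], list[GenomeInterval]]:
    """Background genome, TSS intervals, and ancestral binding-site intervals."""
    _validate_packing(config)
    rng = np.random.default_rng(config.seed) if rng is None else rng
    chroms = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    genome = {
        c: _decode(rng.integers(0, 4, size=length).astype(np.int8))
        for c, length in zip(chroms, config.chrom_lengths)
    }

    tss_counts = _per_chrom_counts(config.n_tss, config.chrom_lengths, rng, at_least_one=True)
    tss_intervals: list[GenomeInterval] = []
    for c, length, k in zip(chroms, config.chrom_lengths, tss_counts):
        positions = np.sort(rng.integers(0, length - 1, size=int(k)))
        strands = rng.choice(["+", "-"], size=int(k))
        for j, (p, s) in enumerate(zip(positions, strands)):
            tss_intervals.append(
                GenomeInterval(c, int(p), int(p) + 1, strand=str(s), name=f"tss_{c}_{j}")
            )

    site_counts = _per_chrom_counts(
        config.n_ancestral_sites, config.chrom_lengths, rng, at_least_one=False
    )
    w = config.ancestral_site_width
    ancestral: list[GenomeInterval] = []
    for c, length, k in zip(chroms, config.chrom_lengths, site_counts):
        placed: list[tuple[int, int]] = []
        for j in range(int(k)):
            for _ in range(1000):
                start = int(rng.integers(0, length - w))
                if all(start + w <= s or start >= e for s, e in placed):
                    placed.append((start, start + w))
                    break
            else:
                raise ConfigurationError(
                    f"could not place ancestral site {j} on {c} without overlap"
                )
        placed.sort()
        for j, (s, e) in enumerate(placed):
            ancestral.append(GenomeInterval(c, s, e, name=f"ancestral_{c}_{j}"))
    return genome, tss_intervals, ancestral


def amplify_te(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[str], list[list[tuple[int, str, str]]]]:
    """Derive ``n_te_copies`` independent descendants of the consensus."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    return mutate_sequences(
        config.consensus_model.sequence,
        config.n_te_copies,
        config.mu,
        config.kappa,
        rng,
        cpg_channel=config.cpg_channel,
    )


def _random_other_consensus(length: int, family_rng: np.random.Generator) -> str:
    """A control-family consensus free of E-Box/RORE-like windows."""
    from .motifs import BUILTIN_MOTIFS, scan_iupac

    screens = [BUILTIN_MOTIFS["E-Box"], BUILTIN_MOTIFS["RORE"]]
    for _ in range(1000):
        seq = _decode(family_rng.integers(0, 4, size=length).astype(np.int8))
        if not any(scan_iupac(seq, m) for m in screens):
            return seq
    raise ConfigurationError("could not construct a motif-free control consensus")


def place_insertions(
    copy_lengths: Sequence[int],
    families: Sequence[str],
    config: SimulationConfig,
    ancestral_peaks: Sequence[GenomeInterval],
    rng: Optional[np.random.Generator] = None,
    biased: Optional[Sequence[bool]] = None,
) -> tuple[list[RepeatAnnotation], np.ndarray]:
    """Place element copies on the genome, avoiding ancestral sites.

    A ``proximity_bias`` fraction of eligible copies (all focal-family copies
    unless ``biased`` is given) is placed uniformly within
    ``proximity_window`` bp of a randomly chosen ancestral site; the rest are
    placed uniformly genome-wide. Placements overlapping an ancestral site or
    a previously placed copy are redrawn, so emitted annotations are pairwise
    disjoint. Returns annotations (family labels, random strand) and the
    per-copy proximal flag.
    """
    import bisect
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sizes = config.chromsizes
    chroms = sorted(sizes.entries)
    lengths = np.array([sizes.entries[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()

    anc_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in chroms:
        ivs = sorted(
            (iv for iv in ancestral_peaks if iv.chrom == c), key=lambda iv: iv.start
        )
        anc_by_chrom[c] = (
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
        )
    anc_list = list(ancestral_peaks)

    def overlaps_site(chrom: str, start: int, end: int) -> bool:
        starts, ends = anc_by_chrom[chrom]
        idx = int(np.searchsorted(starts, end, side="left"))
        return idx > 0 and int(ends[idx - 1]) > start

    placed_starts: dict[str, list[int]] = {c: [] for c in chroms}
    placed_ends: dict[str, list[int]] = {c: [] for c in chroms}

    def overlaps_placed(chrom: str, start: int, end: int) -> bool:
        # placed copies are pairwise disjoint, so neighbour checks suffice
        ps, pe = placed_starts[chrom], placed_ends[chrom]
        idx = bisect.bisect_right(ps, start)
        if idx > 0 and pe[idx - 1] > start:
            return True
        return idx < len(ps) and ps[idx] < end

    n = len(copy_lengths)
    if biased is None:
        biased = [fam == config.family_name for fam in families]
    proximal = np.zeros(n, dtype=bool)
    annotations: list[RepeatAnnotation] = []
    for i in range(n):
        L = int(copy_lengths[i])
        want_proximal = bool(biased[i]) and anc_list and (
            rng.random() < config.proximity_bias
        )
        placed = False
        for _ in range(1000):
            if want_proximal:
                site = anc_list[int(rng.integers(0, len(anc_list)))]
                lo = max(0, site.center - config.proximity_window)
                hi = min(sizes[site.chrom] - L, site.center + config.proximity_window)
                if hi <= lo:
                    continue
                chrom = site.chrom
                start = int(rng.integers(lo, hi))
            else:
                chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
                start = int(rng.integers(0, sizes[chrom] - L))
            if not overlaps_site(chrom, start, start + L) and not overlaps_placed(
                chrom, start, start + L
            ):
                placed = True
                break
        if not placed:
            raise ConfigurationError(
                f"could not place copy {i} after bounded retries; genome too crowded"
            )
        idx = bisect.bisect_right(placed_starts[chrom], start)
        placed_starts[chrom].insert(idx, start)
        placed_ends[chrom].insert(idx, start + L)
        proximal[i] = want_proximal
        strand = "+" if rng.random() < 0.5 else "-"
        annotations.append(
            RepeatAnnotation(
                interval=GenomeInterval(chrom, start, start + L, strand=strand,
                                        name=f"{families[i]}_{i}"),
                family=families[i],
                class_name="SINE",
            )
        )
    return annotations, proximal


def derive_peaks(
    annotations: Sequence[RepeatAnnotation],
    copy_sequences: dict[str, str],
    proximal: np.ndarray,
    config: SimulationConfig,
    ancestral_peaks: Sequence[GenomeInterval],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[GenomeInterval], SimulationTruth]:
    """Emit peaks from matured copies (plus all ancestral sites) and the truth.

    A focal copy is bound iff its designated E-Box pair is matured and a
    coupling draw succeeds, with probability ``binding_base_prob`` boosted by
    ``maturation_coupling`` for proximally inserted copies; unmatured copies
    may still bind at the ``binding_noise`` rate. Ancestral sites always emit
    peaks — they are the Non-RABS population.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    model = config.consensus_model
    label_a, label_b = DESIGNATED_EBOX_PAIR
    focal_ids = [
        ann.interval.name for ann in annotations if ann.family == config.family_name
    ]
    calls = classify_maturation(
        [(cid, copy_sequences[cid]) for cid in focal_ids], model
    )
    matured: dict[str, dict[str, bool]] = {cid: {} for cid in focal_ids}
    for call in calls:
        matured[call.copy_id][call.proto_motif] = call.matured

    rows = []
    peaks: list[GenomeInterval] = []
    half = config.peak_width // 2
    for i, ann in enumerate(annotations):
        cid = ann.interval.name
        is_focal = ann.family == config.family_name
        flags = matured.get(cid, {})
        pair = bool(flags.get(label_a)) and bool(flags.get(label_b))
        if pair:
            p_bind = config.binding_base_prob
            if proximal[i]:
                p_bind = min(1.0, p_bind + config.maturation_coupling)
        else:
            p_bind = config.binding_noise
        bound = bool(rng.random() < p_bind)
        if bound:
            c = ann.interval.center
            chrom_len = config.chromsizes[ann.interval.chrom]
            start = max(0, min(c - half, chrom_len - config.peak_width))
            peaks.append(
                GenomeInterval(ann.interval.chrom, start, start + config.peak_width,
                               name=f"peak_{cid}")
            )
        rows.append(
            {
                "copy_id": cid,
                "chrom": ann.interval.chrom,
                "start": ann.interval.start,
                "end": ann.interval.end,
                "strand": ann.interval.strand,
                "family": ann.family,
                "proximal": bool(proximal[i]),
                "matured_ebox2": bool(flags.get(label_a, False)),
                "matured_ebox3": bool(flags.get(label_b, False)),
                "matured_pair": pair,
                "bound": bound,
                "lineage": "mouse-like",
            }
        )
    peaks.extend(
        GenomeInterval(iv.chrom, iv.start, iv.end, name=f"peak_{iv.name}")
        for iv in ancestral_peaks
    )
    truth = SimulationTruth(pd.DataFrame(rows).set_index("copy_id"))
    return peaks, truth


def simulate_lineage_split(
    copy_sequences: dict[str, str],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    mu_mouse: Optional[float] = None,
    mu_rat: Optional[float] = None,
    loss_fraction: Optional[float] = None,
) -> LineageSplit:
    """Spawn mouse-like and rat-like descendants of each (ancestral) copy.

    Each copy receives independent post-split mutations in each lineage
    (same CpG scheme). A ``loss_fraction`` of copies is dropped from the
    rat-like lineage, emulating orthologs that cannot be traced; the
    ortholog map links the surviving pairs.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    mu_m = config.post_split_mu if mu_mouse is None else mu_mouse
    mu_r = config.post_split_mu if mu_rat is None else mu_rat
    loss = config.lineage_loss if loss_fraction is None else loss_fraction
    ids = sorted(copy_sequences)
    sources = [copy_sequences[cid] for cid in ids]
    mouse_seqs = mutate_each(sources, mu_m, config.kappa, rng, config.cpg_channel)
    rat_seqs = mutate_each(sources, mu_r, config.kappa, rng, config.cpg_channel)
    lost = rng.random(len(ids)) < loss
    mouse = dict(zip(ids, mouse_seqs))
    rat = {cid: seq for cid, seq, drop in zip(ids, rat_seqs, lost) if not drop}
    ortholog_map = {cid: cid for cid in rat}
    return LineageSplit(mouse=mouse, rat=rat, ortholog_map=ortholog_map)


def simulate_dataset(
    config: SimulationConfig,
    with_lineages: bool = True,
) -> SimulatedDataset:
    """Run every stage and assemble the cross-referenced dataset."""
    rng = np.random.default_rng(config.seed)
    genome, tss_intervals, ancestral = simulate_genome(config, rng)
    model = config.consensus_model

    focal_seqs, _ = mutate_sequences(
        model.sequence, config.n_te_copies, config.mu, config.kappa, rng,
        cpg_channel=config.cpg_channel,
    )
    families = [config.family_name] * config.n_te_copies
    all_seqs = list(focal_seqs)
    for fam, n_copies in config.other_families:
        fam_consensus = _random_other_consensus(len(model.sequence), rng)
        fam_seqs, _ = mutate_sequences(
            fam_consensus, n_copies, config.mu, config.kappa, rng,
            cpg_channel=config.cpg_channel,
        )
        all_seqs.extend(fam_seqs)
        families.extend([fam] * n_copies)

    annotations, proximal = place_insertions(
        [len(s) for s in all_seqs], families, config, ancestral, rng
    )
    copy_sequences = {
        ann.interval.name: seq for ann, seq in zip(annotations, all_seqs)
    }
    # divergence annotation of focal copies from the realized mutations
    annotations = [
        dataclasses.replace(
            ann,
            divergence_pct=(
                100.0 * sum(a != b for a, b in zip(seq, model.sequence)) / len(seq)
                if fam == config.family_name
                else None
            ),
        )
        for ann, seq, fam in zip(annotations, all_seqs, families)
    ]

    # embed copies into the background genome (minus-strand as reverse complement)
    mutable = {c: bytearray(s.encode()) for c, s in genome.items()}
    for ann in annotations:
        seq = copy_sequences[ann.interval.name]
        emb = seq if ann.interval.strand == "+" else reverse_complement(seq)
        mutable[ann.interval.chrom][ann.interval.start: ann.interval.end] = emb.encode()
    genome = {c: b.decode() for c, b in mutable.items()}

    peaks, truth = derive_peaks(
        annotations, copy_sequences, proximal, config, ancestral, rng
    )
    lineages = (
        simulate_lineage_split(copy_sequences, config, rng) if with_lineages else None
    )
    return SimulatedDataset(
        config=config,
        genome=genome,
        chromsizes=config.chromsizes,
        tss=TSSSet.from_intervals(tss_intervals),
        tss_intervals=tss_intervals,
        ancestral_peaks=ancestral,
        repeats=annotations,
        peaks=peaks,
        copy_sequences=copy_sequences,
        truth=truth,
        lineages=lineages,
    )


# ---------------------------------------------------------------------------
# Coordinate-level enrichment scenarios
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentScenario:
    """A coordinate-level dataset for exercising the enrichment stage."""

    peaks: list[GenomeInterval]
    repeats: list[RepeatAnnotation]
    tss: TSSSet
    chromsizes: ChromSizes
    focal_family: str
    target_ratio: Optional[float] = None
    n_planted: int = 0


def _uniform_repeats(
    n: int, family: str, copy_length: int, chrom: str, chrom_length: int,
    rng: np.random.Generator, margin: int = 0,
) -> list[RepeatAnnotation]:
    starts = rng.integers(margin, chrom_length - copy_length - margin, size=n)
    return [
        RepeatAnnotation(
            interval=GenomeInterval(chrom, int(s), int(s) + copy_length,
                                    strand="+", name=f"{family}_{i}"),
            family=family,
            class_name="SINE",
        )
        for i, s in enumerate(starts)
    ]


def _uniform_tss(n: int, chrom: str, chrom_length: int, rng: np.random.Generator) -> TSSSet:
    positions = np.sort(rng.integers(0, chrom_length - 1, size=n))
    return TSSSet(positions=tuple((chrom, int(p), "+") for p in positions))


def null_enrichment_scenario(
    n_families: int = 20,
    copies_per_family: int = 750,
    n_peaks: int = 1000,
    copy_length: int = 147,
    peak_width: int = 200,
    chrom_length: int = 7_400_000,
    n_tss: int = 2000,
    seed: int = 0,
) -> EnrichmentScenario:
    """Many families, uniform placement, no planted enrichment.

    Every family's observed count should match its shuffle expectation up to
    sampling noise; used to check the calibration of the binomial test. The
    default geometry keeps expected counts around 15 attributed peaks per
    family while holding the per-copy peak multiplicity
    (``n_peaks * w_eff / L``) near 0.04 — the binomial model treats peaks as
    independent trials, so a dense geometry in which one copy covers several
    peaks at once would overdisperse the counts it is meant to describe.
    """
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    repeats: list[RepeatAnnotation] = []
    for f in range(n_families):
        repeats.extend(
            _uniform_repeats(copies_per_family, f"FAM{f:02d}", copy_length,
                             chrom, chrom_length, rng)
        )
    peak_starts = rng.integers(0, chrom_length - peak_width, size=n_peaks)
    peaks = [
        GenomeInterval(chrom, int(s), int(s) + peak_width, name=f"peak_{i}")
        for i, s in enumerate(peak_starts)
    ]
    return EnrichmentScenario(
        peaks=peaks,
        repeats=repeats,
        tss=_uniform_tss(n_tss, chrom, chrom_length, rng),
        chromsizes=ChromSizes({chrom: chrom_length}),
        focal_family="FAM00",
    )


def planted_enrichment_scenario(
    target_ratio: float = 4.0,
    n_planted: int = 220,
    n_focal: int = 1000,
    n_control: int = 0,
    n_random_peaks: int = 180,
    copy_length: int = 147,
    peak_width: int = 200,
    min_fraction: float = 0.5,
    n_tss: int = 2000,
    seed: int = 0,
) -> EnrichmentScenario:
    """Plant one family at a target enrichment ratio.

    ``n_planted`` peaks are centered on focal copies (each fully containing
    its copy, hence attributed to the focal family); the remaining peaks and
    all copies are uniform. The chromosome length is solved from
    uniform-overlap geometry with Poisson saturation so that
    observed / expected equals ``target_ratio``: a random peak acquires an
    attribution with probability ``y = 1 - exp(-n_focal * w_eff / L)``, so
    observed ~ n_planted + n_random_peaks * y, expected ~ n_peaks * y, and
    ``y = n_planted / (n_peaks * r - n_random_peaks)``.

    The default is a single planted family: with exclusive best-repeat
    attribution, a second family would be out-competed at planted peaks in
    the observed data but not under the shuffle null, biasing both ratios.
    """
    need = int(np.ceil(min_fraction * peak_width))
    if copy_length < need:
        raise ConfigurationError(
            f"copies of {copy_length} bp can never cover {need} bp of a peak"
        )
    w_eff = copy_length + peak_width - 2 * need + 1
    n_peaks = n_planted + n_random_peaks
    denom = n_peaks * target_ratio - n_random_peaks
    if denom <= 0:
        raise ConfigurationError("target ratio too small for this peak composition")
    y = n_planted / denom
    if y >= 1:
        raise ConfigurationError("infeasible target: required overlap probability >= 1")
    x = -np.log1p(-y)
    chrom_length = int(round(n_focal * w_eff / x))
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    focal = _uniform_repeats(n_focal, "FOCAL", copy_length, chrom, chrom_length,
                             rng, margin=peak_width)
    control = _uniform_repeats(n_control, "CONTROL", copy_length, chrom,
                               chrom_length, rng, margin=peak_width)
    peaks: list[GenomeInterval] = []
    half = peak_width // 2
    for i in range(n_planted):
        c = focal[i].interval.center
        peaks.append(GenomeInterval(chrom, c - half, c - half + peak_width,
                                    name=f"planted_{i}"))
    for i, s in enumerate(rng.integers(0, chrom_length - peak_width, size=n_random_peaks)):
        peaks.append(GenomeInterval(chrom, int(s), int(s) + peak_width,
                                    name=f"random_{i}"))
    return EnrichmentScenario(
        peaks=peaks,
        repeats=focal + control,
        tss=_uniform_tss(n_tss, chrom, chrom_length, rng),
        chromsizes=ChromSizes({chrom: chrom_length}),
        focal_family="FOCAL",
        target_ratio=target_ratio,
        n_planted=n_planted,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, str]:
    """Write all artifacts as plain-text files plus a reproducibility manifest.

    Returns the file->sha256 digest map recorded in the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with open(outdir / "genome.fa", "w") as fh:
        for chrom in sorted(dataset.genome):
            fh.write(f">{chrom}\n")
            seq = dataset.genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i: i + 80] + "\n")
    write_chrom_sizes(dataset.chromsizes, outdir / "genome.chrom.sizes")
    write_bed(dataset.tss_intervals, outdir / "tss.bed")
    write_bed(dataset.ancestral_peaks, outdir / "ancestral_peaks.bed")
    write_bed(dataset.peaks, outdir / "peaks.bed")
    write_repeatmasker_table(dataset.repeats, outdir / "repeats.tsv")
    with open(outdir / "copies.fa", "w") as fh:
        for cid in sorted(dataset.copy_sequences):
            fh.write(f">{cid}\n{dataset.copy_sequences[cid]}\n")
    dataset.truth.table.sort_index().to_csv(outdir / "truth.tsv", sep="\t")

    files = [
        "genome.fa", "genome.chrom.sizes", "tss.bed", "ancestral_peaks.bed",
        "peaks.bed", "repeats.tsv", "copies.fa", "truth.tsv",
    ]
    digests = {name: _sha256(outdir / name) for name in files}
    manifest = {
        "config": dataset.config.to_dict(),
        "seed": dataset.config.seed,
        "digests": digests,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return digests
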