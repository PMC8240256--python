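# Methods

This note documents the models, conventions, and design choices behind
`exapt`, in the spirit of a statistical-software methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Interval model and RABS classification

All coordinates are 0-based half-open. BED is read natively; the UCSC
RepeatMasker track dialect is also 0-based, with `milliDiv` converted to
percent divergence and `Low_complexity`/`Simple_repeat` records dropped on
ingest.

A peak is classified RABS when a **single** repeat covers at least
`min_fraction` (default 0.5, inclusive `>=`) of the peak's length. The
inclusive threshold follows the operational semantics of the standard
interval-intersection tools (`-f 0.5`) rather than a strict "more than
half" reading. Overlap is attributed to one best repeat — maximal overlap,
ties to the leftmost repeat start, then leftmost end — never to a union of
repeats: union coverage would relabel edge cases that single-repeat
semantics define unambiguously, and it would detach the attribution from a
concrete repeat copy. Non-RABS peaks still report their best overlap
fraction (possibly 0) but carry no repeat.

Nearest-feature distance is the edge gap in bp; overlapping *and bookended*
intervals have distance 0, keeping distance continuous with overlap. On
ties the upstream (leftmost-start) subject is reported. Strand is carried
on all intervals but ignored by overlap and distance operations.

Interval joins use start-sorted arrays with a running maximum of interval
ends (candidate slice = searchsorted bounds, then exact filtering). Tests
verify classification and nearest-distance against exhaustive pairwise
oracles on random instances.

## The constrained-shuffle null and the binomial test

The null preserves two properties of the repeat annotation: the number of
copies per chromosome, and each copy's distance to its nearest TSS. The
implementation re-anchors each copy independently: record the signed offset
from the copy's start to its nearest TSS, draw a TSS uniformly on the same
chromosome, place the copy at the drawn TSS plus the same offset.
Out-of-bounds placements are redrawn (up to 100 attempts) and finally
clamped to the boundary; clamps are counted on each replicate so they can
be checked to be rare. Per-element re-anchoring was chosen over resampling
a family-wide offset distribution because it preserves both constraints
exactly, copy by copy. Replicate *k* is seeded by a deterministic function
of (master seed, *k*).

Per-family expected counts are bootstrap means over replicates (default
1000; the pipeline default is 200, which leaves the expectation's standard
error below ~2% at the count scales the generator produces). "Observed"
counts *peaks* attributed to the family (a toggle counts distinct copies
instead). Significance is the exact two-sided binomial with
`p0 = expected_mean / n_peaks` under the minimal-likelihood convention —
sum all outcome probabilities not exceeding that of the observed count —
with `min(1, 2·min(tails))` available as an option. Families are reported
regardless of the `observed > 50` count filter; the filter is a flag, so
borderline families remain visible with their p-values.

The binomial treats peaks as independent trials. That approximation holds
when one shuffled copy rarely covers several peaks at once (per-copy peak
multiplicity `n_peaks · w_eff / L` well below ~0.05, where
`w_eff = copy_length + peak_width − 2·ceil(min_fraction·peak_width) + 1` is
the number of admissible copy starts per peak). The bundled null scenario
is sized to that regime; in much denser geometries the counts overdisperse
and the test becomes anti-conservative, which is a property of the
binomial reduction, not of the shuffle.

## Motif scanning and statistics

IUPAC columns are probability columns uniform over their allowed bases
against a fixed 0.25 background, so every window matching an *m*-column
motif scores `Σ log2(4/|allowed_i|)` bits and the null score distribution
is exactly computable by dynamic programming over columns. Thresholded
scanning reports windows whose score has null probability ≤ `p` (default
0.01); at maximal stringency it coincides with exact scanning. Windows
containing `N` never match. Minus-strand hits are reported in plus-strand
coordinates; for palindromic motif *patterns* (e.g. `CACGTG`) the redundant
minus self-hit is collapsed onto the plus strand, so the expected hit
density of a palindromic 6-mer on random sequence is `(1/4)^6` per window,
and `2·(1/4)^6` for a non-palindromic one. Degenerate patterns such as
`CACRTG` are not palindromic, and a palindromic *sequence* matching them is
reported once per strand.

Overlapping hits merge into maximal chains spanning their union with the
arithmetic mean score (strand-agnostic, mirroring `bedtools merge` with
score averaging). Density profiles are center-anchored, orientation-flipped
for minus-strand regions, and mask (rather than zero-fill) positions
truncated by a sequence end; the profile value at an offset is the mean
over covering regions of the summed merged-hit score at that position.

Nearest-motif spacing is **start-to-start** to the nearest non-overlapping
retained hit (by default only maximal-score hits are retained). This
convention is fixed so that a motif pair separated by a 6-nt spacer yields
a 12-bp spacing — the geometry of the consensus E-Box pair; an edge-gap
convention would report 6 and break that correspondence.

Discriminative k-mer enrichment collapses each k-mer with its reverse
complement, compares per-set containment fractions, and uses the one-sided
hypergeometric tail (exact Fisher). It stands in for external
discriminative motif-discovery tools; its contract, exercised in tests, is
recovering planted discriminative motifs. The motif-gain fold change is
the ratio of per-sequence mean hit counts (bound over unbound), computed
independently per species on ortholog sets; a zero denominator returns a
flagged infinity rather than raising.

## Maturation model

Proto-motifs are windows within a small Hamming distance of a canonical
motif, scanned on both strands (IUPAC-aware, so a degenerate canonical
column accepts any allowed base). Substitution paths are defined only for
equal-length strings — the maturation argument is purely substitutional,
and gapped paths are out of scope. A path event is deamination-consistent
iff it is C→T with the source C immediately followed by G, or G→A with the
source G immediately preceded by C, evaluated on the **pre-mutation**
(source) sequence with up to 1 nt of flanking context; motif-edge positions
whose required neighbour is unavailable are conservatively classified
non-consistent. When a degenerate canonical column mismatches, the concrete
target base prefers the deamination product (T from C, A from G) before
falling back alphabetically.

Per-copy maturation calls map consensus proto-motif columns through an
alignment; copies with a gap inside a motif window are flagged uncallable
for that motif. A proto-motif that is already canonical in the consensus
(the antisense RORE) is trivially "matured" in an unmutated copy.

K2P divergence uses transitions/transversions over ungapped compared
columns; inputs where `1−2P−Q ≤ 0` or `1−2Q ≤ 0` return a flagged undefined
result. For unaligned input a fixed-score global aligner (match +1,
mismatch −1, gap −2, deterministic first-alignment traceback, backed by
Biopython's PairwiseAligner) is applied first, so alignment-dependent
results are bit-reproducible. Jukes–Cantor is deliberately not offered.

## The synthetic generator

The generator emulates the study system, not any particular dataset:

* **Consensus.** The bundled 147-nt consensus is a *synthetic* stand-in
  built on a screened random background (no spurious window within Hamming
  distance 1 of `CACGTG`, nor exact E-Box/RORE/D-Box matches, before or
  after maturation). It carries the motif layout that matters: a perfect
  antisense RORE, two imperfect sense ROREs, a central one-mismatch E-Box,
  and a pair of CpG-path E-Boxes (`CACGCG`) separated by a 6-nt spacer near
  the 3' end. Perfecting all motifs changes 7 nt.
* **Burst.** Copies radiate independently from the consensus (star
  phylogeny — no subfamily structure, matching the single-burst picture).
  Each site mutates with probability `mu`, multiplied by `kappa` (default
  10, capped so the product stays a probability) at the C or G of a CpG in
  the source; CpG mutations take the deamination channel (C→T / G→A)
  specifically, with a uniform-channel toggle for sensitivity checks.
* **Defaults as study conditions.** 20-Mb genome (4 × 5 Mb), 2000 TSS, 150
  ancestral sites of 200 bp, an 8000-copy focal burst plus an 8000-copy
  motif-free control family, `mu = 0.025`. `kappa·mu = 0.25` sits near the
  maturation-yield optimum of the CpG-rich E-Box pair — the maturing C must
  flip while the window's three other CpG-hypermutable bases must not — so
  roughly 1% of copies mature the pair while most accumulate breaking
  substitutions; the resulting sub-1% bound fraction matches the regime of
  a real SINE family in which a few hundred of >10⁵ copies are bound.
* **Placement and binding.** Insertions avoid ancestral sites and each
  other; a `proximity_bias` fraction (default 0.3) lands within 10 kb of a
  random ancestral site. A copy binds (emits a 200-bp peak) only if its
  designated E-Box pair matured, with probability 0.1 for distal copies
  boosted to ~1.0 for proximal ones — a strong context effect chosen to
  reproduce the order-of-magnitude contrast between bound-copy and
  background distances to pre-existing sites seen in the real system.
  Ancestral sites always emit peaks and constitute the Non-RABS population.
  A `binding_noise` knob (default 0) lets unmatured copies bind.
* **Lineages.** Each copy spawns mouse-like and rat-like descendants with
  independent post-split mutations; a 0.4 loss fraction in the rat-like
  lineage (emulating untraceable orthologs, ~60% traceable) defines the
  ortholog map. Loss is uniform random, not sequence-dependent.

What the generator does **not** emulate: read-level noise, mappability,
chromatin signal, GC/composition heterogeneity, nested or truncated
insertions, within-burst subfamily structure, or selection. Passing
recovery tests therefore shows the *methods* are correct and calibrated on
data satisfying their assumptions — not that real ChIP-seq data satisfies
those assumptions.

Two coordinate-level scenario builders support the statistical checks. The
null scenario places ~20 families uniformly with per-copy peak multiplicity
~0.04 and expected counts ~15 per family, the regime where the binomial
reduction is valid. The planted scenario centers peaks on focal copies and
solves the chromosome length from saturating uniform-overlap geometry
(`y = 1 − exp(−n·w_eff/L)`) so observed/expected hits a target ratio; it
plants a single family because exclusive best-repeat attribution would
otherwise be won by the planted family in the observed data but shared
under the null, biasing both families' ratios.

## Pipeline, determinism, and problem sizes

Every stage is driven by explicit integer seeds; replicate and sub-stream
seeds derive deterministically from them, and identical configurations
reproduce reports and written datasets byte-for-byte (content digests are
recorded in dataset manifests and report provenance). Intermediate tables
are materialized when an output directory is configured, so each stage can
be audited and re-run.

Test and acceptance problem sizes are desk-scale by design: 200 null
datasets × 200 bootstrap replicates for calibration, a planted scenario
with ~250 attributed peaks, the default 8000-copy burst for proximity,
spacing, and divergence summaries, and a 4000-copy lineage comparison.
These sizes keep Monte-Carlo standard errors small relative to the effects
asserted while completing in minutes on one CPU.

## Known limitations

* The binomial enrichment test inherits the independence approximation
  discussed above; dense peak geometries overdisperse it.
* The shuffle slightly clusters placements around TSS anchors, which
  under-counts distinct attributed peaks by a few percent at desk scale —
  conservative for enrichment, slightly anti-conservative for depletion.
* Maturation calls on heavily gapped alignments reduce coverage (windows
  with gaps are uncallable rather than re-aligned).
* The K2P estimator is undefined past saturation (`P + Q` large); such
  copies are flagged and excluded from summaries.
* `matched_random_repeats` samples from the full annotation including the
  originally bound copies; with small families the control set can overlap
  the RABS set.
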