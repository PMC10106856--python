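# Methods

This note records the models, parameter choices and numerical decisions
behind `centroscape`, and what the synthetic-data validation does and does
not demonstrate.

## Mutation model and LTR insertion-time estimation

All simulated divergence is substitution-only Jukes–Cantor (JC69).
`mutate_sequence(seq, K)` flips each site independently with probability
p = (3/4)(1 − e^(−4K/3)) to a uniformly chosen different base; this is
exactly the JC69 marginal transition matrix, so mutating two copies of a
template with per-branch divergence K yields an expected pairwise observed
mismatch fraction of (3/4)(1 − e^(−4·(2K)/3)).  No indels are introduced:
the dating step's divergence estimate is then exactly invertible, and
indel robustness is an aligner concern tested separately against
dynamic-programming oracles.

Dating inverts this model.  For an element with 5′/3′ LTR copies:

- p_obs = mismatches / (matches + mismatches), i.e. gap columns are
  excluded — substitution-clock logic.
- K = −(3/4)·ln(1 − (4/3)·p_obs) (JC69, default) or the Kimura
  2-parameter form −(1/2)·ln(1−2p−q) − (1/4)·ln(1−2q) from the
  transition/transversion split.  p_obs ≥ 0.75 (or a K2P log-domain
  violation) marks the age unreliable; such elements are excluded from
  mean-age summaries rather than clamped.
- age = K / (2μ) with μ = 1.5×10⁻⁸ substitutions·site⁻¹·year⁻¹ by
  default.  μ and the model are configuration, not constants: both are
  stamped into outputs.

**Equal-length LTR pairs are compared site by site rather than through an
edit-distance alignment.**  A minimum-edit alignment of two diverged
substitution-only copies will occasionally replace two or more
substitutions with a compensating gap pair, deflating the gap-excluded
mismatch fraction; on simulated elements this produced a systematic
−0.025 MYA bias near 0.55 MYA, which the site-wise comparison removes
(residual −0.006 ± 0.005 MYA).  Unequal-length copies are aligned end to
end first.

Elements at 0.5 MYA exactly are classified *young* (the boundary is
inclusive); strictly older elements are *old*.

Precision limit: with 1 kb LTRs the mismatch count is binomial, so the
age estimate carries an irreducible sampling error of roughly 0.13–0.19
MYA (1 s.d.) for true ages of 0.5–2 MYA at the default μ.  Over ages
drawn U(0, 2) MYA this floor corresponds to a mean absolute error around
0.13 MYA and a truth–estimate Pearson r near 0.95.  Longer LTRs tighten
both in proportion to 1/√length.

## Synthetic chromosomes

Layout: telomere – arm – pericentromere – centromere – pericentromere –
arm – telomere; spans are configurable (defaults 3 Mb chromosome, 500 kb
centromere, 2 × 400 kb pericentromere, 5 kb telomeres).  Arms are i.i.d.
uniform nucleotides at the configured GC (0.36), the simplest null that
still exercises probe-mapping false positives.  Satellite compartments
are head-to-tail monomer arrays in alternating blocks of the role's
monomers, each copy independently mutated at K = 0.02 — enough per-copy
divergence to make identity heatmaps block-like without modelling
higher-order repeat structure.  The default monomers are synthetic stand-ins
(176 bp centromeric; 238 bp and 1022 bp pericentromeric; 7 bp telomere
motif TTTAGGG) generated from a fixed seed: the real satellite sequences
are not public inputs here and no sequence fidelity to them is claimed.

LTR elements are built per family from one random template (LTR with
TG…CA termini + internal region), so same-family elements are homologous;
each planted copy's two LTRs and internal region are mutated at
K = μ·T per branch.  Ages are drawn per compartment from a normal
truncated at zero whose **realised** mean equals the configured value —
naive truncation would inflate a configured 0.14 MYA mean to ~0.19 — with
defaults centromere (0.14, 0.15), pericentromere (0.51, 0.35), arm
(0.32, 0.30) MYA.  A configurable fraction (default 0.1) of elements is
re-inserted inside an older element of the same compartment; children are
recorded with their immediate parent, and grandparent chains are allowed.

The optional hidden repeat (default 630 bp) is embedded inside a subset of
pericentromeric elements and dispersed as single copies through the
pericentromeric satellite (each copy mutated at K = 0.02).  Copies are
dispersed rather than tandemly abutted so that merged-hit counting counts
copies; the discovery stage in turn merges only strictly overlapping
hits, so abutting tandem copies would still be counted individually.

One seeded generator drives everything: a fixed `SimConfig` reproduces
byte-identical FASTA and truth tables.

What passing on this simulator does **not** show: robustness to indels,
assembly gaps or errors, higher-order satellite repeat structure,
N-runs, sequencing artefacts, or the divergence structure of real TE
families.  It shows that each analysis step correctly inverts the model
it assumes.

## Alignment primitives

Local alignment is seed-and-extend: exact 13-mer seeds (vectorised
2-bit hashing; k-mers containing non-ACGT never seed), clustered by
diagonal (gap tolerance = the band pad), each cluster resolved by a
banded local Gotoh DP with match +1, mismatch −2, gap open −3, gap
extension −1, band ±32 diagonals around the seeded range.  Within its
band the DP is exact — on planted-homology instances the best hit equals
a full-matrix exhaustive aligner cell for cell, which the test suite
asserts on randomized instances.  Overlapping hits are reduced to the
highest-scoring one (conflict = target overlap exceeding half the shorter
hit).  The extension is windowed DP rather than greedy X-drop extension:
equally sensitive at these scales and directly comparable to the
exhaustive oracle.

Global identity uses an exact edit-distance alignment (edlib) with gap
columns counted as columns: identity = matches / (matches + mismatches +
gap columns).  The `band` argument is a feasibility check on the length
difference; the alignment itself is computed unbanded, which can only
improve on a banded score.  N is never counted as a match.

There is no e-value: an explicit (identity ≥ 0.8, length) threshold pair
plays that role throughout, with the minimum length expressed per use
(half the monomer for probe mapping, 100 bp for discovery).

## Probe tracks, compartment calls, telomeres

Density is the covered-bp fraction of each window (500 kb window, 100 kb
step; the trailing partial window is normalised by its real width), with
hits unioned per role first so fragmented or overlapping monomer hits are
not double counted.  Region calling is a run-length rule on the track:
windows ≥ threshold (default 0.1) form runs, runs shorter than 2 windows
are dropped, runs separated by ≤ 2 below-threshold windows merge, and the
boundary snaps to the outermost probe-hit endpoints inside the merged
span.  The criterion is stated explicitly because no numeric rule is
standard; every output carries the parameter snapshot.  Pericentromere
calls come from the pericentromeric track only and keep only the parts
flanking (not inside) a called centromere.  Elements are assigned to the
compartment containing their midpoint, centromere taking precedence —
unambiguous for boundary-straddling elements.

Telomeres: a chromosome end is telomeric when exact motif matches (either
strand) cover ≥ 0.2 of the terminal 10 kb; both numbers are configurable
and recorded.  Exact matching is appropriate for the 7 bp motif, whose
mutated copies are not meaningful hits at this length.

## Identity landscapes

Bins are non-overlapping 10 kb (trailing partial bin dropped), forward
strand by default (a reverse-complement-aware option exists and is
recorded in the matrix metadata).  The k-mer estimator (containment of
15-mer sets, raised to 1/15) is labelled an estimate and validated
against alignment identity (r ≥ 0.9 on synthetic matrices).
`segment_blocks` is a minimal recursive bisection: accept a cut when mean
within-block identity exceeds between-block identity by ≥ 0.1.  It is an
interpretive aid for block-structured matrices, not an inference method.

## Repeat discovery

Self-clustering builds a graph whose nodes are hit intervals from
all-vs-all element alignment; edges join the two sides of each alignment
and intervals on the same element with reciprocal overlap ≥ 50%;
connected components are candidate units, represented by their
highest-scoring interval, with occurrences counted per input sequence
record (duplicating an input doubles its count).  Filters: keep
self-occurrences ≥ 50 (the boundary case 49 is always rejected); keep
pericentromere hits strictly > 1000 (exactly 1000 is rejected), counting
disjoint intervals after merging strict overlaps.  Candidates with any
hit ≥ 50% identity over ≥ 100 bp against a known probe are flagged and
excluded from the novel list.  The sources the filter texts derive from
state the self-occurrence boundary inconsistently (one side excludes 50,
the other includes it); this implementation keeps ≥ 50 and exposes the
threshold.

## Statistics

Compartment age contrasts use the two-sided Welch (unequal-variance)
t-test by default — the conservative choice when the variant is not
specified — with a pooled-variance option; both are cross-checked against
a permutation oracle in the tests.  Both groups constant and equal gives
p = 1, t = 0 by convention.  No multiple-testing correction is applied
across the small fixed set of compartment contrasts; report footnotes say
so.  Coverage fractions merge features before intersecting and equal a
per-base counting oracle exactly.

## Problem sizes

The validation suite uses 3 Mb chromosomes (20 replicates for boundary
recovery), 200 planted elements for dating recovery, 2.6 Mb
pericentromere-heavy genomes (20 planted + 20 null) for discovery, 120 kb
two-array regions (20 seeds) for identity blocks, and 100-seed power runs
for the contrast — sizes chosen so the full suite runs in minutes on one
CPU while keeping every per-run statistic comfortably away from its
decision threshold.  `scripts/acceptance.py` re-runs the same analyses at
slightly reduced replicate counts (printed in its output as `n`).

## Known limitations

- The structural LTR finder is a labelled simplification (exact-repeat
  pair search with k-mer frequency masking and satellite-mask support);
  it is not LTR_retriever and should not be used on real assemblies.
- Discovery counts and representative boundaries depend on the declared
  merge rules; other reasonable conventions shift hit counts by small
  amounts.
- JC69/K2P assume no rate variation across sites and no gene conversion
  between LTRs; real elements violate both, typically biasing ages down.
- The simulator does not model Hi-C, reads, assembly error, genes,
  expression or methylation; conclusions about those layers are out of
  scope.
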