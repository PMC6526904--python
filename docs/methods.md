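# Methods

## The clan test

An unrooted tree on leaf set L defines, per edge, a bipartition of L; each
side is a *clan*. For an asserted taxon group C and a gene-family tree, the
test resolves every leaf to its taxon, collects the leaves of the members
of C present in the family, and asks whether that leaf set is one side of
some single edge. Conventions, chosen once and applied everywhere:

- **Vacuous pass.** If ≤ 1 member of C is present, or the present members'
  leaves are the entire leaf set, the clan is *untestable* and counts as a
  pass: an untestable assertion cannot be violated. (Whether a
  whole-tree-spanning clan should instead count as tested-and-passed is
  ambiguous; we classify it untestable and exclude it from violation-rate
  denominators, which is the conservative reading.)
- **Polytomies.** A clan must sit on a single edge as-is; no resolution of
  polytomies is attempted.
- **Multicopy taxa.** A clan containing taxon X requires *all* leaves of X
  inside the block. The filter itself, however, requires single-copy input
  and raises otherwise — duplicate pruning comes first.
- **Decision rule.** One violated clan ⇒ remove the family. A `tolerance`
  parameter (number of present members that may be dropped to rescue a
  clan) exists but defaults to 0, which is the rule the method is built
  around.

Trees are parsed with dendropy and converted to a plain adjacency model
with genuinely unrooted semantics: degree-2 nodes (rooted-newick artifacts)
are suppressed with their incident edge lengths summed, so equality is by
split set. Internal node labels (support values from tree inference) are
ignored with a logged warning; the newick dialect is unquoted labels with
optional branch lengths. Serialization sorts children by minimum descendant
label, so output is deterministic.

## Worst-case late-loss enumeration

R duplication rounds strictly before the speciations of three ingroup
lineages leave 2^R copies arranged in a complete binary copy tree; each
lineage then retains exactly one copy. The divergence of two lineages is
the speciation time of their species-tree MRCA if they kept the same copy,
else the age of their copies' most recent common duplication. The
supported triplet is the pair with the minimum divergence.

Comparisons use time *ranks* under the strict order
t(SP2) < t(SP1) < t(DUP_R) < … < t(DUP_1) rather than numeric ages, making
ties impossible by construction (the minimum is always achieved by exactly
one pair: either some pair shares a copy, giving a speciation rank below
every duplication rank, or all copies are distinct and three leaves of a
binary tree have a unique shallowest pairwise MRCA). At R = 2 this yields
64 combinations: 24 supporting the true topology (4 of them all-same-copy
ortholog families), 20 for each alternative. The two alternatives tie for
every R by exchangeability of the two deeper pairings. The enumeration
assumes exactly one surviving copy per lineage; families absent from a
lineage are outside its scope (the simulator's occupancy model covers
those).

The test suite checks the classification of every combination for R = 1–4
against an independent oracle that builds the literal copies-over-species
locus tree in dendropy and reads pairwise MRCA ages.

## Simulators

**MSC (`ils_only`).** Standard multispecies coalescent on a rooted
ultrametric species tree in coalescent units: within each species-tree
branch, k gene lineages coalesce pairwise at rate k(k−1)/(2θ) until the
branch's parent age; survivors pass upward; the root branch coalesces to
completion. θ = 1 per branch by default — dimensionless, with closed forms
available for calibration: the suite verifies the 3-taxon mismatch
probability (2/3)e^(−T) at T ∈ {0.5, 1, 2} within 3 Monte-Carlo standard
errors at 10,000 draws.

**Duplication + late loss (`dup_late_loss`).** `rounds` duplications on the
root stem (spaced `dup_spacing` = 1 coalescent unit apart, all strictly
older than the root) create 2^rounds locus copies, each propagating through
the species tree; every sampled taxon independently retains one copy chosen
uniformly — the worst-case late-loss model, matching the enumeration (the
suite confirms the 3-ingroup topology spectrum is consistent with 24:20:20
by chi-square at α = 0.01 on 10,000 families). An optional ILS layer
(`ils_under_duploss`) additionally runs the coalescent within each copy; it
is off by default so that the duplication signal is isolated and the
documented violation-rate claims refer to a fully specified generative
model.

**Occupancy.** Per-taxon independent inclusion with probability 20/33
(families average ~20 of 33 taxa, the family-size profile the validation
experiment emulates), rejected below 6 taxa; a family-size histogram mode
with uniform taxon choice is available instead. A hard floor of 4 taxa
applies in all modes.

**Randomness.** One root seed; replicates draw from `SeedSequence.spawn`
substreams, so runs are byte-reproducible and replicate-order independent.

## The validation experiment

For each replicate, `n_families` families are simulated and the clan filter
applied; the reported statistic is the fraction of *testable*
(family × clan) evaluations that are violated, averaged over replicates.
Untestable (vacuous) evaluations are excluded from the denominator. On the
default configuration (33-taxon fixture model, 7 clans, 100 replicates of
768 families) the ILS-only mean is well under 5% and the two-round
duplication + late-loss mean is well over 72% — the separation that makes
clan violations usable as a paralogy signal. Both figures depend on the
fixture model's branch lengths and the loss model; they are bounds-style
statements about this documented configuration, not universal constants.

## The fixture species model

33 taxa: 8 Anura, 5 Caudata, 5 Gymnophiona (Batrachia topology:
Anura + Caudata sisters) and 15 outgroup vertebrates spanning mammals,
birds, non-avian reptiles, fishes and a cyclostome. Seven clans: mammals,
birds, birds + reptiles, frogs, salamanders, caecilians, tetrapods.

Node ages (coalescent units) were fixed once on the principle that deep
vertebrate divergences are many coalescent units while within-group
radiations are few: group crowns at 0.3–2.5, group stems ≥ 3.2 (birds) up
to 7.5 (mammals), basal vertebrate splits at 10–24. This produces visible
ILS at short internal branches (the 3-taxon mismatch machinery is fully
exercised) while keeping group-level monophyly essentially safe under ILS
alone — the regime in which the filter is claimed to be unbiased. Real
data differ in ways the generator does not model: gene-tree estimation
error, alignment error, rate variation among lineages and sites, missing
data correlated with clade, gene flow. Passing the validation experiment
therefore shows the filter separates *these two generative regimes*; it
does not bound false-positive rates on inferred trees, where
reconstruction error can mimic clan violations.

## Alignment screens

**Saturation.** Pairwise p-distances (pairwise deletion of gaps/X; 0 with a
warning when no comparable sites) and multiple-hit-corrected distances
d = −ln(1 − p − 0.2 p²) (Kimura's closed-form protein correction — a
deliberate, documented stand-in for a full empirical-matrix ML distance;
the correction is increasing, convex, and ≥ p on its domain p < 0.854).
Pairs beyond the domain are capped at 5.0 and reported — saturation being
visible is the point of the screen. Neighbor joining (Saitou–Nei, via
scikit-bio; negative branch estimates clamped to zero with the deficit
logged) is run on both matrices; the statistic is the ratio of total branch
lengths (corrected / p), 1.0 for invariant alignments and increasing with
divergence. Outliers are flagged by an explicit rule — ratio above
median + 5·MAD across families, or above an absolute cap of 3.0 — replacing
a by-eye inspection with something reproducible; both thresholds are
exposed.

**Composition.** Per taxon, a chi-square test of its amino-acid counts
(gaps/X excluded) against alignment-wide frequencies, with degrees of
freedom = (states observed alignment-wide) − 1 — robust to sparse usage in
short alignments. Reported per family as the fraction of testable taxa with
p < α (default 0.05); taxa with no scorable sites are excluded with a
warning.

**Bias report.** Mann-Whitney rank-sum comparison of per-family average
branch length (sum of all branch lengths / number of branches, internal
and external) between kept and removed families — a reporting-layer check
that the filter is not simply removing fast-evolving families.

## Problem sizes and numerics

- Acceptance computations: full enumeration (64 combinations, exact); the
  violation experiment at 100 replicates × 768 families per regime
  (~2–3 minutes total); MSC calibration at 10,000 draws per depth.
- The default test suite uses the same generators at reduced family counts
  (chosen as comfortable Monte-Carlo sizes for the quantities asserted;
  the experiment's means have replicate-level standard deviations under
  0.015, so bounds at 5% / 72% have wide margins).
- Branch lengths serialize via `repr` (shortest round-trip float), so
  parse → serialize → parse is exact.
- Duplicate pruning resolves ties (equal sequence lengths) to the
  lexicographically smallest label, for determinism.
- `prune_species_duplicates` relies on edge blocks forming a laminar
  family: maximal same-taxon blocks are disjoint, so reductions commute.

## Known limitations

- The clan filter tests observed gene trees as given; uncertainty in tree
  inference (support values) is passed through, not used.
- The duplication model places all duplications on the root stem; mid-tree
  duplications (which create clan violations only in descendant groups)
  are not simulated.
- The loss model's one-survivor-per-taxon rule conditions on survival;
  family extinction in a lineage is handled only through the occupancy
  distribution, independently of copy history.
- The saturation screen's corrected distance is a fixed closed form, not a
  model-fitted distance; its purpose is ranking families, not estimating
  substitutions.
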