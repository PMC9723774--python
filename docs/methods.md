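# Methods

This note documents the statistical conventions, the synthetic-data model
and the design decisions behind `mycodiv`, in the spirit of a model
description a maintainer or reviewer would want next to the code.

## Study design assumed by the package

The analyses target a two-block tree-diversity experiment: 80 plots
crossing tree species richness (1, 2, 4) with plot mycorrhizal
composition (AM-only, EM-only, mixed), built from a pool of five
AM-dominated and five EM-dominated deciduous tree species, two
monocultures per species (one per block), and one root sample per
plot × tree species (200 samples at richness 20·1 + 30·2 + 30·4, of which
a few percent are typically lost to sampling error). Each sample carries a
count vector over AMF virtual taxa and EMF ASVs. Nothing in the library is
hard-wired to these numbers — they are the defaults of `DesignParams` —
but treatment labels (`AM-1` … `Both-4`) assume the 3 × 3 crossed layout
minus the impossible `Both-1` cell.

## Taxon consolidation

* **VT merging** sums read counts of ASVs sharing a virtual-taxon ID;
  per-sample totals are conserved exactly, and re-merging merged output is
  the identity.
* **Monophyletic clustering** of unassigned ASVs reads "monophyletic
  clusters with more than 97% sequence identity" as: a clade qualifies
  when *every pair* of its tips (complete linkage) has identity strictly
  greater than the threshold. Clades are taken greedily from the root, so
  the *maximal* qualifying clade wins and nested candidates are absorbed —
  the choice that minimises the final taxon count, matching the merging
  intent. Only unassigned ASVs participate; VT-assigned taxa are never
  re-clustered. Singleton tips keep their ASV IDs. Merged clusters are
  named `add_cluster1…k` by decreasing total read abundance, ties broken
  lexicographically by sorted member IDs, making the naming deterministic.
  Correctness is checked against exhaustive clade enumeration on random
  trees (≤ 12 tips, thresholds 0.95/0.97/0.99).
* **Guild filtering** keeps taxa of the target guild whose assignment
  confidence is in {possible, probable, highly probable} (case-insensitive
  after whitespace normalisation; a missing confidence passes on guild
  match alone, mirroring exports that omit the field). Filtering only
  removes whole columns; samples emptied by it are retained and flagged.

## Richness additivity

Observed richness of a mixture plot is the union of taxa over its samples
(shared taxa counted once). Expected richness sums each component
species' monoculture richness *without* deduplicating taxa shared between
monocultures ("summing up" taken literally); a deduplicating union
variant exists but is off by default. Because each species has two
monocultures, a policy selects which one enters the sum: the default
`same_block` uses the monoculture in the mixture's block (the same
pairing rule the beta-diversity analysis uses) and falls back to the
cross-block mean, rounded half-up at the plot total, when that
monoculture is missing; a `mean` policy always averages. Per treatment,
Pearson r (df = n − 2, two-sided p, unadjusted) and the OLS line of
observed on expected are reported, plus a flag for all points lying
strictly below the 1:1 line. Treatments with fewer than 3 plots or
zero variance are reported untestable rather than raising — low-detection
treatments are a real outcome, not an error.

## Specialisation scores

The phi coefficient is computed from the 2 × 2 presence/group margins and
equals the Pearson correlation of the indicator vectors (verified to
1e-12 on random instances). Presence means count > 0; there is no
abundance weighting. Phi is undefined (NaN) for taxa present in all or no
samples of the analysis set.

The null model permutes the host-mycorrhizal-type labels across samples
(group sizes preserved), 100 draws by default, and the score is
(φ − null mean)/null SD; if the null SD is zero the score is 0 when the
observed phi equals the null mean and undefined otherwise. Specialists
are called one-sidedly at score strictly > 3. Under label independence
the score is approximately standard normal (empirical SD within
[0.8, 1.2] at n_null = 100), so the 3-SD call is conservative.

Two stratification modes exist. The default `pooled` mode computes one
score per taxon over all samples in which the guild was detected
(per-guild analysis sets are "samples with ≥ 1 read of that guild"),
against the guild's own host type (AMF → AM trees, EMF → EM trees); this
is the mode whose scores feed the AMF-vs-EMF Wilcoxon rank-sum comparison
(continuity-corrected normal approximation for large/tied samples, exact
otherwise — the R `wilcox.test` convention). A `per_treatment` mode
stratifies by composition × richness; note that single-type strata
(AM-1/2/4, EM-1/2/4) have no host-type contrast and yield undefined
scores there by construction, which is why pooled is the default.
Per-taxon permutation substreams are derived from the master seed and the
taxon/stratum IDs (CRC32-keyed `SeedSequence`), and samples are processed
in sorted-ID order, so results are independent of input order and of
which other taxa are present.

## Phylogenetic diversity and mixed models

Faith's PD is the rooted convention: the sum of branch lengths on the
union of root paths of the present tips, so a single taxon has positive
PD and the empty set has PD 0. Taxa absent from the tree raise unless the
caller opts into pruning. Samples with no detection of the response guild
are excluded from PD models by default (absence, not zero diversity),
with an option to include them as 0.

The PD model has four fixed terms — target tree species identity
(categorical), neighbour-species same/different, neighbour-mycorrhizal-
type same/different, and plot richness (numeric) — fit separately within
AM-tree and EM-tree subsets. Neighbour covariates are encoded at plot
grain (planting positions are not part of the data model): a sample's
neighbour contrast is "different" when its plot contains another species,
or a species of the other mycorrhizal type; monocultures are same/same.
The random structure is a block intercept plus a plot-within-block
variance component, fit by REML through `statsmodels`' `MixedLM`. With
only two blocks the block variance is frequently inestimable, so the
fitter uses a fallback chain — full model, then dropping the block
intercept (keeping plot-in-block), then dropping the plot component —
taking the first converged fit and recording which structure was used in
the output's `model_note`. Term significance is a Type II Wald χ² on each
term's coefficient block (df 4 for species with a 5-species pool, df 1
otherwise). Calibration simulations (null responses on a 40-plot design)
put each term's type-I error at the nominal 5% within [2%, 9%], and a
planted neighbour-type effect of 1 residual SD is detected in ≥ 80% of
runs.

## Beta diversity

Similarities are unweighted Sørensen on presence/absence, consistent with
the richness-level analyses. For each guild, focal trees are mixture
samples of the guild's own host type (AMF → AM focal trees, EMF → EM; a
flag exposes the complementary combinations). Two pair categories:
(1) focal tree vs the same species' monoculture individual *in the same
block* — no cross-block fallback, a missing monoculture skips the pair
and is counted; (2) focal tree vs every different-species sample in its
plot (all unordered pairs, each attributed once). Pairs where either
community is empty in the guild are dropped and counted. Within each
stratum (focal type × richness) the categories are compared two-sidedly
by Wilcoxon rank-sum. Under host-species-specific synthetic communities
monoculture pairs dominate; under plot-driven communities the ordering
reverses — both directions are recovered in simulation.

## UpSet intersections

A taxon belongs to a treatment set when detected in ≥ 1 sample of that
treatment. Intersection sizes use exclusive (UpSet) semantics — taxa in
exactly a given subset of treatments and no others — so sizes over all
non-empty subsets partition the union, and each treatment's set size is
the sum of the exclusive sizes of subsets containing it. Rows are ordered
size-descending, then subset cardinality, then lexicographically. Tables
are computed; figure rendering is out of scope.

## Synthetic-data model

The generator reproduces the *statistical structure* of the design, not
its exact field layout: mixture compositions are drawn uniformly from the
admissible species combinations (within a block no composition repeats;
the original experiment fixed its mixtures by a design table, which only
matters for field logistics, not for testing the statistics). Replicates
are balanced over the two blocks; sample dropout is independent Bernoulli
at 6% (≈ 12/200, the rate of unattributable root samples).

Communities follow an occupancy model: taxon *t* is present in sample *s*
with probability `in_group_occupancy` (default 0.8) when *s* matches
*t*'s affinity target — a host mycorrhizal type, or a host species in the
`species` affinity mode — and `out_group_occupancy` (0.05) otherwise;
generalists use a flat 0.30 everywhere. Default specialist fractions
(AMF 0.6, EMF 0.2) plant the AMF-specialist / EMF-generalist contrast
this system exhibits. Conditional on presence, counts are Gamma–Poisson
(negative binomial, dispersion 0.5) scaled to a nominal depth of 10,000
reads and floored at one read. The count model is a plausibility
stand-in: every downstream claim is presence/absence-based, so only
occupancy structure matters to the statistics. Phylogenies are random
bifurcating trees with exponential branch lengths, and pairwise identity
is an affine decreasing map of patristic distance spanning (0.9, 1) —
adequate for exercising threshold clustering, not a sequence-evolution
model. The ASV-split stage divides each taxon's counts multinomially over
1–3 raw ASVs (totals conserved exactly) and withholds the VT assignment
from a configurable fraction of taxa to exercise the clustering path.

What the simulator does *not* emulate: spatial autocorrelation between
plots, read-depth variation between samples, chimeras or index-hopping,
taxonomic mis-annotation, and any abundance-level host effects. Passing
tests therefore demonstrate that the statistical machinery recovers known
structure from data of this shape — not that real sequencing artefacts
are handled.

## Determinism and numerics

Every generator and every permutation draw descends from a master seed
via named `SeedSequence` substreams keyed by entity IDs, so outputs are
bit-reproducible and invariant to sample/taxon ordering; the pipeline
writes byte-identical outputs for identical config + seed (the manifest
records parameters and per-stage counters, deliberately no timestamps).
Ties are broken lexicographically wherever an order matters. Degenerate
inputs (constant responses, zero-variance expected richness, empty
communities, all-tied rank tests) return flagged NaN/p = 1 results
rather than raising, except where the input violates a precondition
(empty designs, mismatched vectors, unknown plots), which raise with the
offending entity named.

Problem sizes in the test-suite simulations (200-instance oracles,
100-run model calibrations, 50-run direction checks, reduced taxon pools
in pipeline tests) were chosen as the smallest sizes at which the checked
proportions are stable, keeping the default suite fast while leaving the
full-scale defaults (62 + 174 taxa, 200 samples) to the end-to-end runs.

## Known limitations

* Neighbour effects are plot-grain; with planting positions one could
  define true nearest-neighbour contrasts.
* The block random intercept is weakly identified with two blocks; the
  fallback chain makes this explicit rather than hiding it.
* Expected richness under the `mean` policy can be fractional before
  rounding; the half-up rounding at the plot total is a convention.
* `per_treatment` specialisation in single-type strata is undefined by
  construction (no host-type contrast within the stratum).
* Identity matrices are validated to 1e-6 symmetry; files written by
  other tools with looser formatting may need re-rounding.
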