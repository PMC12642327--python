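# Methods

## Setting and model

The package analyses two-group DIA proteomics experiments at the level of
*detection*: a protein × run matrix of log2 quantities with explicit missing
cells, reduced per protein to the pair of counts (k_dep/n_dep, k_non/n_non)
of replicates per group in which the protein was quantified. The underlying
assumption is the DIA missingness mechanism: a precursor is absent from the
report chiefly because its intensity fell below the limit of detection
(missing not at random), so detection itself is an abundance-driven,
biologically meaningful event. All downstream statements (Venn partition,
evidence tiers, power) depend only on the missingness pattern, never on the
quantitative values, and are therefore invariant to monotone transformations
of intensity.

## Report filtering

Rows are retained when all three q-values satisfy `q ≤ threshold`
(default 0.01 each, inclusive comparison). Zero-quantity rows survive
filtering but are treated as *not quantified* downstream, keeping "detected"
synonymous with "quantified". Filtering is idempotent and monotone in the
thresholds; per-threshold rejection counts are logged and recorded in the
run manifest.

## MaxLFQ aggregation

For each protein, the precursors × runs matrix of log2 intensities yields,
for every pair of runs sharing ≥ 1 precursor (configurable), the median of
the per-precursor log2 differences r_ij. Run-level protein quantities x
minimize Σ (x_i − x_j − r_ij)², solved per connected component of the
run-sharing graph via the graph-Laplacian normal equations. The system is
singular only along the constant vector; the gauge is fixed by anchoring the
component mean of x to the mean of the per-run mean observed precursor
intensity. The anchor is a declared convention — it preserves the overall
intensity scale and makes the single-precursor case an exact identity — and
is one of several reasonable choices; only between-run differences carry
meaning. No cross-component ratio is invented: disconnected components are
anchored independently. The estimator is scale-equivariant (multiplying raw
intensities by c shifts all outputs by log2 c) and is verified in the test
suite against an independently formulated constrained least-squares oracle
(KKT system) to 1e-9 on randomized instances.

Normalization across runs and protein inference beyond the report's
protein-group column are out of scope.

## Detection rule and Venn partition

A protein is detected in a group when quantified in ≥ `min_reps` replicates
(default 2; a single replicate is too easily produced by carry-over or a
spurious match). The partition into group-unique / shared / undetected is a
true partition: the "detected in neither group" bucket is reported
explicitly rather than dropped, so the output always accounts for every
profiled protein. For heat-map selection, proteins are ranked by
|k_dep/n_dep − k_non/n_non| with lexicographic tie-break, optionally
restricted to proteins with zero detections in the opposite group.

## Evidence tiers

Labels are assigned in strict precedence: strong-dep (≥ 0.75 of Dep and
≤ 0.20 of Non-dep), strong-nondep (≥ 0.80 and ≤ 0.25), moderate-dep
(≥ 0.50 of Dep with clear preference), moderate-nondep (≥ 0.60), shared
(≥ 2 replicates in both groups), weak. The asymmetric strong-tier constants
are the proportion forms of count thresholds at group sizes 4 and 5
(3/4 vs 1/5, 4/5 vs 1/4); expressed as proportions they generalize to other
designs. "Clear preference" is operationalized as the minimal rule
consistent with every published moderate-tier example: the comparison group
detected in at most 1 replicate *and* a strictly greater preferred-group
proportion. Profiles with substantial detection in both groups fall through
to shared; those below all preference thresholds to weak. The classifier is
total and deterministic; mutual exclusivity of the two strong conditions and
group-swap symmetry under symmetric thresholds are asserted by exhaustive
enumeration in the tests.

## Exact power and sample size

For detection probabilities p₁, p₂ in groups of n₁, n₂, the detection counts
are independent binomials and the comparison is Fisher's exact test on the
2×2 table — the only exact test at group sizes this small. Power is the sum
of joint binomial probabilities over the rejection region, enumerated over
all (n₁+1)(n₂+1) outcomes; no approximation enters. Conventions: two-sided
p-values use the point-probability method (sum of all tables, given the
margins, with conditional probability ≤ the observed table's, with a 1e-9
relative guard against floating-point ties); the doubling convention is
available behind a flag; rejection is strict (p < α, default α = 0.05). The
one-sided alternative (direction p₁ > p₂) is exposed.

At the default design (n = 4 vs 5), enumeration gives power 1.0 for
100 % vs 0 % detection rates and 0.3716 for 75 % vs 20 %. For equal groups
at 75 % vs 20 %, the two-sided target of 0.8 is first reached at
n = 16/group; the one-sided test reaches it at n = 12/group (power 0.848,
with the sawtooth dips characteristic of discrete tests — the sample-size
search therefore reports the full power curve, not just the crossing point).
The test being exact and discrete is also why size never exceeds α
(conservatism, asserted across a grid of null probabilities).

Study-wide power across hundreds of proteins with multiplicity adjustment is
out of scope.

## Over-representation analysis

Query gene lists (e.g. all strong+moderate proteins of one group) are tested
against GMT gene-set collections with the hypergeometric upper tail
P(X ≥ k) and BH FDR across all tested terms. The background defaults to the
detected proteome — proteins detected in either group — because that is the
sampling frame actually available to a presence/absence experiment; a
whole-genome background would overstate significance. Term memberships are
intersected with the background before testing; protein groups are collapsed
to gene symbols, and proteins without a symbol are excluded with a logged
count.

## Tryptic digestion and peptide uniqueness

Digestion follows the Trypsin/P rule (cleave after every K or R, including
before proline; pyteomics' cleavage machinery with rule `[KR]`), with up to
1 missed cleavage and peptide length 6–30 by default — matching common
search-engine settings. Uniqueness of a target proteome's peptides against a
host proteome is the set difference of the full digests; because I and L are
isobaric and indistinguishable by MS, an optional flag collapses them before
comparison while reporting peptides in their literal target sequence.
N-terminal methionine excision and other search-engine modifications are not
modeled.

## Synthetic data generator

The generator emulates the features that make the pipeline's statistics
meaningful, per protein and run:

- **abundance mode** — run-level protein log2 abundance = group mean +
  Normal(0, replicate_sd); precursor intensity adds a fixed per-precursor
  offset ~ Normal(0, precursor_offset_sd) and Normal(0, 0.2) measurement
  noise; a row is emitted only if the intensity clears the detection limit.
  This produces genuine MNAR missingness (the censoring probability is
  decreasing in abundance, verified empirically).
- **probability mode** — detection is Bernoulli per protein × run with the
  group's probability, intensities drawn above the limit. This mode has
  closed-form binomial expectations, used to validate the classifier and
  power enumeration by Monte Carlo.

Defaults: 4 vs 5 runs, replicate_sd 0.5 log2 units, precursor offsets 1.0
log2 unit, 2 % spurious rows whose global q-value lies in (0.011, 0.05) —
planted with a `DECOY-` protein-id prefix so filter rejections are
attributable. All draws descend from one `numpy.random.default_rng` seed;
identical configurations are byte-identical. The study-shaped fixture plants
611 proteins as 140/67/404 (preferred-group detection probability 0.9–1.0,
off-group 0–0.2, shared 0.9–1.0 in both).

What the generator does *not* emulate: chromatographic structure, sex
covariate effects (recorded in annotations but not modeled), realistic
protein abundance distributions, or correlated missingness between proteins.
Passing tests therefore demonstrate correctness of the computational
machinery under the stated missingness model, not recovery of any particular
biology from real data. Because off-group detection probabilities extend to
0.2, a planted group-preferred protein is sometimes realized with ≥ 2
off-group detections; recovery tests compare against the realized detection
pattern (enumerable from the report) or against Poisson-binomial
expectations, not against the planted labels verbatim.

## Pipeline and PCA

`run_pipeline` wires the stages, writes every intermediate as TSV/JSON with
a manifest echoing parameters and row counts, and is deterministic given its
inputs. PCA of runs uses complete-case log2 quantities by default (no
imputation — imputing an MNAR matrix injects the very group structure under
study) with a binary-detection fallback when too few proteins are complete.
Axis signs are fixed by requiring the first nonzero loading of each axis to
be positive; 95 % confidence ellipses are emitted as parameters (center,
semi-axes from the chi-square quantile of the group covariance, rotation
angle), not rendered graphics.

## Problem sizes

The test suite and the acceptance script run on enumerations (≤ 30 joint
outcomes), randomized matrices up to 5×5, Monte-Carlo checks of 10⁴–10⁵
draws, and synthetic reports of ~600 proteins × 9 runs — sizes chosen so the
full suite completes in well under a minute while keeping every statistical
tolerance at 3 standard errors.
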