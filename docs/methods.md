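# Methods

## Data model

A profile matrix holds non-negative relative intensities (samples ×
metabolites) with sample metadata: cultivar (two levels), treatment
(irrigated `IR` / water deficit `D`), day, replicate. Missing measurements
are explicit NaN — they are excluded pairwise downstream and never coerced to
zero, mirroring incomplete profiling runs. Metabolite ids are trimmed but
case-preserving, so names like `trans-5-O-caffeoyl-D-quinate` survive
verbatim. When the same metabolite is measured on both platforms the merge
keeps one representative column (GC by default; LC or suffixed duplicates by
policy) because the platforms disagree often enough that a silent average
would be misleading.

## Differential abundance

Per cultivar × day stratum, an equal-variance two-sample Student's *t*
contrasts D against IR replicates. The equal-variance form is the named
test of record; Welch is available by flag. Degenerate strata get explicit
conventions: identical constant groups → t = 0, p = 1 (a non-result, not an
error); constant groups with different means → p = 0. BH adjustment runs
across metabolites within each stratum. Fold changes are ratios of
untransformed group means, displayed as log10; a zero IR mean leaves FC
undefined (NaN) rather than infinite.

The *consistency* call per metabolite × cultivar requires (i) the same
fold-change direction on every tested day and (ii) significance on at least
one day. Rule (ii) gates on raw p < 0.05 by default with a strict q ≤ 0.05
mode, since both criteria are part of the workflow and the choice of gate is
genuinely open; the default follows the per-day t-test that marks individual
entries. The first design day is pre-divergence (treatments identical until
then), so the pipeline defaults exclude it from per-day testing — a
treatment contrast on that day would be a null comparison that can only
break rule (i) by noise.

## Correlation networks

Pairwise Pearson coefficients are computed on pairwise-complete
observations (≥ 4 pairs by default); p-values use the exact t transform
t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom, two-sided. Zero-variance
or under-sampled pairs are *non-tests*: undefined, and excluded from the BH
pool (they do not inflate m). BH runs per data matrix — each condition
network is built from its own matrix, so its significance calibration is
local to that dataset.

Edges require r ≥ 0.9 (positive sign mode; |r| by flag — the threshold is
conventionally printed as a signed bound and stress coordination is a
positive-correlation phenomenon) and q ≤ 0.01. Nodes are exactly the edge
endpoints, so a matrix with no significant pair yields the empty ("non-
viable") network. Correlations for network construction are computed on
log10-scale profiles in the pipeline: intensities are log-normal, and the
latent structure the generator plants (and that profiling data plausibly
carries) is linear on that scale.

Samples are pooled across sampling days within one cultivar × treatment;
pre-divergence samples are assigned to *both* arms by default (they are
draws from the common baseline), excludable by flag. Pooling across days
means progressive treatment trends contribute to correlations — that is a
property of the design, not an artifact, and it is why stressed arms gain
trend-driven edges on top of the within-class block structure.

Statistics: average degree 2E/N, density 2E/(N(N−1)), clustering
(mean local coefficient over nodes of degree ≥ 2 by default; global
transitivity by flag — the concept is standard but the variant is a choice),
diameter as the longest shortest path on the largest connected component
(reported with component size; an infinite-diameter convention for
disconnected graphs would be unreportable). All statistics of an empty
network are undefined (NaN), never 0. A single-edge network has no node of
degree ≥ 2, so its mean-local clustering is likewise undefined.

## Network comparison

Edge identity is the unordered node pair; correlation magnitudes ride along
as attributes but do not affect identity — two conditions "share" an edge
when the pair recurs. The comparison partitions the edge union into shared /
A-specific / B-specific, from which follow the symmetric difference network,
the specificity ratio R = n_B-specific / n_A-specific (reported to 2
decimals, "1 to R"), per-node condition-specific contributions
deg(v, difference)/deg(v, condition), and nodal-degree ratios with explicit
`lost_all` / `gained_all` flags for nodes isolated on one side.

## Permutation test

Null model: each metabolite column shuffled independently within each arm,
preserving marginals exactly and destroying cross-metabolite structure in
expectation. Both arms are re-permuted at every iteration (the closest
reading of permuting "each metabolite for each variety under both
regimes"), both networks rebuilt with q-values recomputed inside the
iteration, and the parameter difference (arm A minus arm B) recorded.

Exceedance is directional by default — permuted differences at least as
large in the observed direction — matching a test of one observed contrast;
a two-sided |diff| mode is available and is the right choice when the
direction is not fixed a priori: under a sign-symmetric null the directional
mode, whose direction is chosen by the data, is anti-conservative by about a
factor of two. The calibration test in the suite therefore exercises the
two-sided mode. p = (c+1)/(n_iter+1) is strictly positive; with n_iter =
1000 its floor is 1/1001 ≈ 0.000999.

Non-viable permuted networks have undefined parameters; those iterations
count as non-exceedances and are tallied in a per-arm node-count histogram.
At r ≥ 0.9 / q ≤ 0.01 with ~24 samples this is the typical outcome: the
smallest of ~4600 null p-values rarely clears the BH hurdle, so permuted
networks are almost always empty. If the *observed* network is non-viable in
exactly one arm, the test is not refused: the undefined parameter enters the
observed difference as 0 and the result is flagged `observed_degenerate` —
the non-comparability argument, since no permutation of either arm can
reproduce a structured-vs-empty contrast. Both observed arms non-viable is
an error (there is no observable difference to test). Randomness uses one
master seed with per-iteration child seeds, so runs are bit-reproducible.

## Communities and enrichment

Greedy modularity maximization (deterministic) by default, Louvain (seeded)
as an alternative, and an annotation-imposed partition for the reading in
which modules *are* the compound classes; modularity is reported for either
so the two can be compared. Community ids are canonicalized (largest first,
ties by smallest member), making partitions invariant to node input order.
Enrichment per (community, class) is the one-sided hypergeometric tail
P(X ≥ k) with N = network nodes, K = class size, n = community size, k =
members inside, BH-adjusted across all rows; unannotated nodes form class
"other".

## Synthetic data generator

The generator *is* the study conditions for every test: 69 GC + 27 LC leaf
metabolites in six compound-class blocks (15 amino acids, 18 organic acids,
16 sugars, 20 other / GC, 14 phenylpropanoids, 13 flavonoids / LC), 2
cultivars × 2 treatments × days (4, 18, 26, 34) × 6 replicates, log-normal
noise with sigma = 0.15 on the log10 scale.

Within-class correlation comes from one latent factor per class and sample:
log10 value = mu_m + log10(effect) + sigma·(√rho·L + √(1−rho)·ε), so the
expected within-class correlation is exactly rho and is verifiable in closed
form. The study-like preset plants rho(Sh,D) = 0.95 > rho(Sh,IR) = 0.90 >
rho(Cs,D) = 0.85 ≈ rho(Cs,IR) = 0.84, which makes stressed Shiraz the
densest network, in the qualitative order the analysis is meant to detect.

Treatment effects are per-metabolite per-day D/IR fold factors. Named
magnitudes follow the published day-34 values (Pro 251× in Sh / 162× in Cs,
Val 33/26, Leu 43/22, Thr 12/13, Trp 17/9, Phe 52/21, Glu 1.5/0.5,
glycerate 1/32 / 1/40, galactonate 1/27 / 1/11, nicotinate with explicit
per-day trajectories 1.44/2.2/2.2 and 1.25/1.99/1.81); unnamed amino acids
rise moderately (4×/3×), unnamed organic acids fall (0.4/0.6), flavanols
fall, stressed-Shiraz-only rises for quercetin-3-O-galactoside (1.4×) and
rutin (1.9×). Day-34 endpoints ramp across days as fractions (0, 0.4, 0.75,
1.0) of the log10 effect — a smooth progressive-stress trajectory. The first
day is generated pre-divergence: effect 1 and the irrigated rho for both
arms.

Trait couplings are signed target correlations applied on the log10
metabolite scale: Psi_l from Pro at r = −0.978, osmolality from Psi_l at
−0.883, g_s from Psi_l at +0.90, ABA from g_s at −0.916, A_N from g_s, C/N
from Pro. The published magnitudes are kept; signs follow the physiology
(Pro and osmolality rise as water potential falls, ABA rises as stomata
close). Trait values are affine maps of the coupled z-scores with loose
clipping into physical ranges (Psi_l ≤ −0.05 MPa, pi ≥ 150 mmol/kg, g_s ≥
0.005 mol m⁻² s⁻¹).

A `pro_decoupled` toggle reproduces the scenario in which proline abandons
its network role under stressed Shiraz while still accumulating: its latent
loading is cut and its private noise widened (×8) in that condition only, so
its pairwise correlations fall below threshold and the node drops out of the
stressed network.

What the generator does **not** emulate: instrument drift and batch effects,
heteroscedastic per-metabolite noise, missing values, non-linear or lagged
trait–metabolite relations, and any mechanistic metabolic coupling beyond
the one-factor blocks. Passing tests therefore demonstrate that the pipeline
recovers planted linear-Gaussian (on log scale) structure at realistic
sample sizes — not that real leaf profiles satisfy those assumptions.

## Suberin quantification

Blue channel only; pixels strictly below the background level 30 are
dropped (30 itself is kept — the literal reading of "values lower than 30"),
the retained histogram's mean is the per-image value, and the group fold
change is the ratio of the means of per-image means. An image with no pixel
at background is undefined, never 0.

## Numerical and testing choices

Problem sizes in the test suite are chosen to exercise the method at the
study's own scale where that is cheap (96 metabolites × 24–30 samples for
network building and the 1000-iteration permutation test) and at reduced
scale where repetition matters (type-I calibration: 50 repeats × 200
iterations on 20-metabolite arms at relaxed thresholds r ≥ 0.2, q ≤ 1.0 so
permuted networks stay viable; fold-change recovery: 100 generator draws).
Acceptance-style checks of published numbers use the printed values as
inputs — 870 edges at mean degree 22.6 imply 77 nodes and density 0.30;
specificity counts 319/801 and 99/1064 give ratios 2.51 and 10.75; densities
0.62 vs 0.45 differ by 0.17 — since the original raw tables are not bundled,
these are internal-consistency checks, not re-derivations from data.

BH adjustment, t-tests and hypergeometric tails are delegated to
statsmodels/scipy; the test suite checks each against an independent
brute-force oracle (step-up enumeration, pooled-variance hand formula,
binomial-coefficient summation). Graph statistics are cross-checked against
a from-scratch adjacency-matrix oracle on every graph with ≤ 7 nodes.

Known limitations: the permutation test assumes complete matrices (impute
or drop before testing); the directional default should not be used for
direction-agnostic screening; pooling days makes edges reflect both
replicate-level covariation and shared trajectories, which cannot be
disentangled within a single condition network; and greedy modularity has a
resolution limit on small dense networks (the annotation-imposed partition
is the remedy when classes are the question).
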