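# Methods

This note documents the models, conventions and design choices behind
`t2drisk`, in the order the pipeline runs them, followed by what the
synthetic cohort does and does not emulate.

## Synthetic cohort

The generator emulates a cross-sectional urban adult screening population:
men and women in a 0.566 : 0.434 ratio, ten continuous covariates (age,
BMI, waist, SBP, DBP, GLU, CHOL, TG, HDL, LDL) with per-sex means and SDs
typical of such a cohort (e.g. men: waist 84.87 ± 9.50 cm, age
46.52 ± 16.2 y), Bernoulli family history (13.7% men, 17.8% women), 6.21%
prevalent diabetes, and a six-year incident process calibrated to 4.5
cases per 1000 person-years overall.

**Joint distribution.** Only marginal moments are available for the kind of
population being emulated, so the correlation matrix is a declared modelling
assumption, shipped as an editable default: BMI–waist 0.80, SBP–DBP 0.70,
TG–HDL −0.40, CHOL–LDL 0.85, adiposity–lipid coupling ≈ 0.25–0.40, and
glycemia correlated ≈ 0.25–0.35 with age, adiposity and TG. The glycemia
couplings sit at the upper end of what is reported for metabolic covariates
because the category structure the model encodes (a high-glycemia tier that
is also the most adipose and dyslipidemic) requires a genuine impaired-
fasting-glucose/metabolic-syndrome association; a weaker coupling produces
tiers whose covariate means no longer order.

**Truncation.** Covariates are truncated multivariate normal: rows with any
value below its physiologic floor (age 20 y, BMI 13, GLU 2.5 mmol/L, …) are
redrawn. Redrawing whole rows conditions the joint distribution, which
biases the means of everything correlated with a binding floor (the TG
floor binds ~10% of raw draws). Latent locations are therefore calibrated:
one-dimensional truncated-normal inversion seeds them, then a fixed-seed
Monte-Carlo loop (4 rounds × 100 000 draws, cached per spec structure)
removes the residual multivariate bias, so post-truncation marginal means
match the targets to well within sampling error. Truncation still shrinks
SDs slightly for heavily truncated variables (TG); only means are
moment-matched.

**Latent clusters.** Three components (weights 0.55/0.27/0.18): a reference
group, an older group (+1 SD age), and an elevated-risk group (+0.8 SD
BMI/waist/TG, −0.5 SD HDL, smaller shifts elsewhere). Displacement vectors
are mean-centred across the mixture so they shape the joint distribution
without moving marginal means.

**Outcome processes.** Prevalent diabetes is Bernoulli in a logistic model
on spec-standardized covariates (per-SD log-odds: age 0.9, GLU 1.1, waist
0.35, TG 0.3, HDL −0.3, PSH 0.7, …), OR-ed with GLU ≥ 7.0 mmol/L; the
intercept is solved at generation time so the marginal prevalence hits the
target. The incident process reuses the linear predictor with its own
intercept calibrated to the six-year cumulative risk. Follow-up assumes
complete observation over the follow-up window.

One printed source of the per-sex GLU moments is internally inconsistent
(per-sex SDs double the total-column SD; per-sex means both above the total
mean); the generator uses the consistent per-sex values of the same
survey's follow-up subcohort (4.74 ± 0.62 / 4.76 ± 0.61 mmol/L).

**What the generator does not emulate:** measurement error and digit
preference, skewness (TG is lognormal-like in reality; here it is a
truncated normal), missing data, non-random attrition, secular drift, and
the tail dependence of real metabolic syndrome (a Gaussian copula
understates joint extremes). Tests passing on this cohort therefore
demonstrate correctness of the pipeline's computations and the qualitative
behaviour of the method, not its real-data operating characteristics (AUC,
cutoffs, accuracies).

## Variable selection

C4.5-style trees are grown without pruning, with gain-ratio splits
(base-2 entropy; split information as denominator; splits with non-positive
gain discarded) and candidate thresholds at midpoints between consecutive
distinct values. Ties within 1e-12 resolve by variable name order, then
the smaller threshold — reproducibility over arbitrariness. Growth stops on
purity, a minimum child size (default 25), or maximum depth (default 12);
the two limits keep unpruned trees finite on continuous data.

"k-fold cross-validation without pruning" is read as: one tree per training
fold (10 per sub-cohort, 50 in total over the five sub-cohorts), all of
them counted. Occurrences within the first eight levels above a threshold
of 4 (strictly greater; the alternative threshold 5 is configurable) give
the tree set. The age strata split at 50 with 50 itself in the upper
stratum (a partition is required; the convention is documented rather than
discovered). Variables with more than 30% missingness are dropped before
anything runs; complete-case analysis follows.

The logistic screen is one maximum-likelihood fit on the full cohort
(statsmodels; Newton first, L-BFGS fallback near quasi-separation, perfect
separation raised as an error naming a separating variable when one exists
alone). The final set is (tree ∩ logistic) ∪ overrides − exclusions. The
shipped override keeps HDL (an established protective factor the trees
favour even when its multivariate p exceeds 0.05); the shipped exclusion
removes GLU, whose role is the absolute criterion, not a model covariate.
A CHOL×sex product term can be added by configuration; it is not part of
the default nine-variable model. The glycemia cut-point is the modal
glucose split threshold (0.05 mmol/L bins, ties toward the shallowest
level), falling back to 5.85 mmol/L when no tree splits on glucose.

## Clustering

Standardization uses the sample SD (n−1). K-means is Lloyd's algorithm run
to an assignment fixed point (so the centroid-equals-member-mean and
stable-assignment invariants hold exactly), initialized by k-means++ with
five seeded restarts (best SSE kept); empty clusters re-seed from the
farthest point. A nested-refinement mode initializes k from the k−1
solution plus the worst-fit point, making R² provably non-decreasing in k.

The cubic clustering criterion follows the SAS A-108 formulation: eigen-
decomposition of the covariance, scale factors u_j = s_j/c with
c = (∏_{j≤p*} s_j / q)^{1/p*}, the effective dimension p* the largest one
whose scaled eigenvalue still reaches 1 (solved by scanning, since c and
p* are interdependent), the published E(R²) approximation, and
CCC = ln[(1−E(R²))/(1−R²)]·√(np*/2)/(0.001+E(R²))^1.2. On well-separated
data CCC ≫ 10; on unstructured data it is near zero or negative. The
selection rule keeps the smallest k with CCC ≥ 10 whose R² increment is
maximal, falling back (with a warning) to the max-CCC k when nothing
passes. Because the synthetic clusters overlap realistically, CCC rarely
clears 10 there; the shipped default is k = 3, with the scan available by
configuration. Subjects are assigned at assessment time to the nearest
centroid in standardized space.

## Risk model

One logistic fit per cluster, on all subjects of the cluster (prevalent
diabetics included — the construction scores everyone against within-
cluster prevalence). K-means splits happily on standardized binary columns,
so a cluster can be constant in sex or PSH; such terms are unidentified
within that cluster and are dropped from its model with a warning.
Calibration is summarized by the Hosmer–Lemeshow decile-of-risk test
(equal-size groups by sorted predicted probability, degenerate groups
merged leftward, dof = groups − 2). The G−2 reference distribution is the
published calibration for *fitted* probabilities; with known probabilities
the statistic carries ~G dof and the test mildly over-rejects — documented,
and relevant only to simulation use.

The reference grid holds 24 cells per cluster: twelve half-open 5-year age
bins [20,25) … [70,75) plus [75,∞), crossed with sex. P₀ is the cluster
logit evaluated **at the cell's mean covariate vector** — deliberately not
the mean of individual probabilities (the two differ by a Jensen gap; the
at-mean convention is the model's definition). Empty cells resolve at
lookup to the nearest populated bin of the same cluster and sex (bin-index
distance, ties toward younger), logged. Ages below 20 are outside the
model's domain and raise. RR = P_k/P₀ is computed for everyone; prevalent
diabetics carry a flag and are excluded from grid construction and
category counts but can still be scored.

Sex is coded 1 = male / 0 = female and PSH 0/1 throughout, recorded in the
model files. A trained model persists as three JSON files (cluster model,
logits, grid) plus a rule YAML and a manifest (version, settings, config
hash); the bundle round-trips bit-exactly and fully defines assessment.

## Cutoff and CCRA

The RR cutoff is trained on the model population itself: ROC of RR against
prevalent diabetes, thresholds at distinct scores with ties grouped,
trapezoidal AUC (equal to concordance with half credit for ties), cutoff at
the operating point closest to (0,1) in Euclidean distance, distance ties
(within 1e-12) toward higher specificity. Assessment-only runs take the
cutoff from configuration, default 2.2.

The cascade: GLU strictly above the glycemia cut-point → high; else RR at
or below the RR cutoff → non; else the degree (count of satisfied
cluster criteria, strict ">") maps 3 → high, 2 → medium, 1 → low. Degree 0
with RR above the cutoff is assigned **low**: the RR alone already signals
elevated risk, and silently inventing a fifth category would break the
four-tier contract. This default is configurable. Only the reference
cluster's criteria are published (BMI > 26.8, CHOL > 5.18, TG > 1.7); the
other clusters' rules are reconstructed as the cluster's 75th percentiles
of BMI, CHOL and TG on the training cohort, shipped in the model file,
flagged `reconstructed`, and fully overridable.

## Validation

Jackknife: every subject's three-way label (non-risk / different-risk /
prevalent diabetes) under a model trained without them is compared with
their label under the full-data model. The default mode refits only the
per-cluster logits and the grid per fold — the components that actually
vary under leave-one-out — keeping selection, clustering, rules and cutoffs
frozen; a `full` mode retrains everything and is practical for small
cohorts. A fold whose retraining fails (e.g. separation at tiny n) is
scored incorrect and logged, and the run continues.

Incidence: person-years are n_baseline × years (complete follow-up — the
convention under which the published rates are exactly cases/(n·6)·1000),
rates per 1000 person-years, 95% intervals by the exact Poisson (Garwood)
method on case counts. The intervals printed alongside the original
follow-up table match no standard method (exact Poisson, Wald, binomial)
and their construction is unstated; the Garwood choice is documented here
and not treated as a discrepancy to reproduce.

## Problem sizes

The test suite and the acceptance script choose cohort sizes as the
package's own defaults: unit tests run at n ≈ 2000, oracle-equivalence
checks at n ≤ 50 (where exhaustive enumeration is feasible), parameter-
recovery and type-I-error Monte-Carlos at 100–200 seeded replicates, the
stratification-ordering check at n = 20 000 (large enough that systematic
ordering dominates sampling noise), and the acceptance run at n = 10 000
with the full 50-tree selection protocol. All randomness flows from a
single integer seed through fixed-offset substreams.

## Known limitations

- The CCC's E(R²) is an approximation; its absolute scale is trustworthy
  for the ≥ 10 decision rule, not for fine comparisons between close k.
- Reconstructed cluster rules are stand-ins, not published values.
- The ROC-trained cutoff equals an observed score, so subjects scoring
  exactly at the cutoff sit on a strict boundary; comparing runs across
  serialization requires identical floating-point inputs.
- Real-cohort operating characteristics (AUC ≈ 0.8, cutoff 2.2, jackknife
  accuracy ≈ 91%) are properties of an unavailable population and are not
  reproduced by the synthetic cohort; the package reproduces the
  construction, its arithmetic, and its qualitative behaviour.
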