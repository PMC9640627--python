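# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## 1. Purity-adjusted lncRNA screen

**Model.** For each (lncRNA, mRNA) pair the screen computes a first-order
partial correlation given tumor purity, its normal-approximation p-value
(z = PCC·√((n−3)/(1−PCC²)), two-sided), and the signed rank index
RI = −ln(P)·sign(PCC). mRNAs are ranked by descending RI per lncRNA; a
weighted Kolmogorov–Smirnov running sum (hit increments ∝ |RI|^w, uniform
miss decrements; default w = 1, the preranked-GSEA convention) gives an
enrichment score ES ∈ [−1, 1] for the target gene set. Significance comes
from gene-label permutations: null sets of equal size drawn uniformly,
p = (1 + #{|ES_null| ≥ |ES_obs|}) / (n_perm + 1). The permutation p-value is
compared on magnitude so that it is uniform for an exchangeable set; the
observed ES sign carries the direction. Benjamini–Hochberg adjustment is
applied across the lncRNAs of one screen invocation (one family), and
TES = (1 − 2·P_adj)·sign(ES). Candidates must satisfy |TES| > 0.95 and
P_adj < 0.05.

Notes on TES: |TES| is large both when P_adj ≈ 0 (strong enrichment) and
when P_adj ≈ 1 (strong *anti*-concordance with the permutation null); the
conjunction with the FDR gate is what makes the rule selective. Output
tables are sorted by |TES| descending, so non-candidates with P_adj ≈ 1 can
head the table — read `is_candidate`, not the order, for calls.

**RI convention.** The formula −ln(P × sign(PCC)) is undefined for negative
sign; the implemented reading RI = −ln(P)·sign(PCC) is the only one
consistent with ranking positive associations at the top.

**Numerics.** All-pairs correlations run as one matrix pass over
standardized rows (O(n·G·L), no per-pair loops). P-value underflow caps RI
at ±745 (−ln of the smallest double). ES running sums accumulate per-step
increments so that a sequential oracle reproduces them bit for bit; an
exact tie between the positive and negative extremes resolves to the
negative one. Constant lncRNAs are skipped with a warning; a constant
purity vector disables the adjustment (plain Pearson) rather than failing,
which is also how "screen without purity adjustment" comparisons are run.

**Permutation caveat.** Gene-label permutation assumes genes are
exchangeable under the null. Genes that share a latent factor *after*
purity adjustment violate this and inflate |ES| for noise lncRNAs — the
screen's false-positive rate is therefore honest only when residual
intra-set co-expression is weak. The synthetic generator's defaults respect
that regime (below); on real data, strongly co-expressed target sets will
yield anticonservative permutation p-values, a known limitation of all
gene-permutation GSEA.

## 2. ssGSEA and the pathway survival screen

Per sample, genes are ranked by expression (average ranks on ties) and a
set's score is the integrated difference between the in-set
rank^τ-weighted CDF and the unweighted out-of-set ECDF, τ = 0.25 by
default; τ and cohort-level min–max normalization (off by default) are
exposed because the upstream convention varies between implementations.
Scores depend only on within-sample ranks (invariant to monotone
transforms).

Each pathway score is screened by a univariate Cox proportional-hazards fit
(lifelines); the coefficient is reported as log2 HR, so positive = risk,
negative = protective. Ties are handled by Efron's method — the only one
lifelines implements; it coincides with Breslow for untied times, and all
synthetic cohorts draw continuous times. The significance default α = 0.05
is a convention, not a claim about the source analyses. A multi-cohort
intersection utility combines per-cohort screens by pathway name.

## 3. Consensus subtyping

Candidate-lncRNA expression (standardized per lncRNA by default) is
clustered by k-means (seeded k-means++, Euclidean) on 500 random 80%
subsamples for each k ∈ [2, 10]; pairwise co-assignment counts normalized
by co-selection counts form the consensus matrix. The number of clusters is
the largest k whose relative gain in area under the consensus-CDF exceeds
0.15; final labels cut an average-linkage tree of (1 − consensus). The
elbow threshold encodes "where the CDF stops moving": at desk scale the
relative gain collapses from ≈ 0.4 at the true k to ≈ 0.08–0.10 just past
it, so 0.15 separates elbow from plateau with margin (0.1 sits inside the
plateau's sampling noise). The k-means is an in-package vectorized
implementation (4 restarts, early-stopped Lloyd) because the resampling
loop runs tens of thousands of fits; it is cross-checked against
scikit-learn's KMeans in the test suite.

Subtype-wise pathway differences use Kruskal–Wallis per pathway with BH
adjustment; groups under 3 samples are dropped, constant pathways get
p = 1 with a `degenerate` flag.

## 4. Risk model and survival utilities

β comes from a Cox fit of the key-lncRNA expression — joint
(multivariate, the default, matching the procedure that defines the risk
groups) or per-lncRNA (univariate); both modes exist because the source
conventions for this step conflict, and the discrepancy is surfaced rather
than hidden. Risk score = Σ βᵢ·EXPᵢ; samples above the median score are
"high" risk, ties go to "low" (deterministic). Groups are compared by
log-rank test with Kaplan–Meier curves (lifelines).

Calibration caveat: refitting β and log-rank-testing the induced median
split *on the same samples* is anticonservative by construction (the fit
maximizes the association the test then measures; measured median null p
≈ 0.03). Null calibration holds for coefficients fixed independently of
the tested cohort — the saved-model path (`RiskModel.from_dict` +
`survival_curves`), which is how external validation should be done.

## 5. Synthetic cohorts

Per sample: purity ~ Beta(5, 2) (a high-purity tumor cohort; configurable),
standardized analytically to P′; latent pathway activity
A = ρP′ + √(1−ρ²)Z with ρ = `purity_confounding` — bulk pathway activity
co-varies with purity, which is precisely what makes unadjusted
correlation screens chase it. Genes have unit variance around a
gene-specific baseline (~N(5, 0.5²)):

* pathway mRNA: 0.15·A + ρ·P′ + noise. The direct purity loading matches
  the background so per-sample ranks track activity, while the activity
  path adds the *differential* purity covariation (0.15·ρ) that an
  unadjusted screen mistakes for signal.
* background mRNA / inert lncRNA: ρ·P′ + noise.
* active lncRNA: a·Z + ρ·P′ + subtype shift + unit noise, with a ≥ 0
  solved in closed form so the marginal corr with A equals `effect_r`
  (subtype-shift variance included). `effect_r = 0` sets a = 0 — the
  conditionally-null case needed for false-discovery checks — rather than
  forcing the marginal correlation to zero, which would require a negative
  loading canceling the purity path. Configurations where no nonnegative
  solution exists (effect_r too close to 1 given the confounding) are
  rejected at validation.

The per-gene activity loading 0.15 keeps residual intra-set co-expression
weak enough that the gene-permutation null is honest (see §1) while the
set-level ssGSEA signal stays strong (corr(score, A) ≈ 0.7 over 40 genes).

Subtypes: equal-probability labels; centroids drawn at random in
active-lncRNA space, centered, and scaled so subtypes differ by
`subtype_shift` expression units per active lncRNA on average. Survival:
exponential event times with hazard 0.1·exp(hazard_beta·A + optional
per-subtype offsets); censoring is independent Uniform(0, u) with u solved
numerically so the expected censored fraction equals `censor_rate`.

**What a green test establishes — and what it does not.** The generator
emulates correlation structure, confounding, cluster structure and
proportional hazards. It does **not** emulate RNA-seq count noise,
library-size or batch effects, heavy-tailed expression, gene-length biases,
non-proportional hazards, or informative censoring. Recovery results here
certify the machinery, not performance on any real cohort. One interaction
deserves note: when active lncRNAs track activity strongly (effect ≥ 0.5),
that shared factor dominates their within-subtype covariance and blurs
Euclidean clustering regardless of the planted shift — so subtype-recovery
checks run the generator's subtype axis with the association axis off.

## 6. Pipeline

Stages run in the order scoring → pathway screen → lncRNA screen →
subtyping → risk. Samples are aligned once at load (intersection of
expression/purity/survival ids; the manifest records drops). Key lncRNAs
for the risk model are the screen candidates that are individually
prognostic in univariate Cox at α = 0.05 (all candidates if none pass).
All randomness derives from the single config seed through
`SeedSequence(seed).generate_state(...)` in a fixed stage order; writers
use a fixed float format, so reruns are byte-identical. A YAML config must
contain either real input paths or a synthetic block, never both.
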