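# Methods

This note documents the models, the numerical choices, and what the
synthetic studies do and do not emulate. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model

A cohort is a long-format table of (individual, age, metabolite,
concentration in µmol/l) plus per-individual metadata (progression group,
sex, IAA status, end of follow-up). Visits are complete profiles: a visit
missing any panel metabolite is dropped on read with a logged count rather
than imputed, because the emission model below assumes a complete profile
per visit. Ages stay in the input's native unit (weeks for mice, years for
children); no unit conversion is attempted — cross-cohort comparison happens
in latent state space, where it is meaningful, not in age space.

Concentrations are modelled on the log2(x + 1) scale by default
(`AnalysisConfig.log_transform`). Lipid concentrations are right-skewed and
non-negative; the Gaussian emission model wants approximate symmetry. The
transform is invertible given the pseudocount and can be switched off to
model raw concentrations.

## Progressive hidden Markov model

States k = 1..K (default K = 3) with initial distribution pi, transition
matrix A, and diagonal-Gaussian emissions N(m_k, diag(v_k)) over the d-lipid
panel. The transition mask allows only k -> k and k -> k+1: progression
cannot reverse and cannot skip a state; the last state is absorbing. An
upper-triangular mask (skips allowed) is available via `allow_skips` for
the looser reading of "no return" progression. Individuals are assumed to
share the state sequence but traverse it at their own pace; per-group models
are fitted by pooling all individuals of the group.

*Why diagonal covariance:* with d up to 154 and cohorts of ~13-30
individuals a full emission covariance is unidentifiable.

*Fitting:* standard multi-sequence Baum-Welch. Expected transition counts
are accumulated only on the allowed band, so structural zeros are exact at
every iteration; a state with no outgoing mass keeps a self-loop of 1.
Variances are floored at 1e-6 of the per-metabolite pooled variance.
Convergence: relative log-likelihood change < 1e-6, at most 500 iterations.
The forward-backward pass uses the scaled linear-space recursion (per-visit
emission rows rescaled by their maximum, alphas by their sum) and falls back
to a log-space implementation if a scaling constant underflows; the
public log-likelihood function is the log-space forward pass.

*Initialization:* deterministic and seed-free. Each individual's visits are
split into K contiguous time blocks and block moments pooled across
individuals. Because state dwell times are typically far from uniform (a
late absorbing state dominates a long follow-up), a single equal-width split
often starts EM inside a local optimum that merges the early states; the
fitter therefore tries three block-boundary curvatures — equal, front-loaded
(short early states) and back-loaded — runs EM from each, and keeps the
best-likelihood fit. pi starts at (1, 0, ..., 0); banded rows start at 0.8
self / 0.2 forward.

*Decoding:* posteriors by forward-backward; hard paths by log-space Viterbi
restricted to the band, with ties resolved toward the lower state index at
each step of the backward trace (so among equally likely paths the least
progressed one is reported).

*Occupancy curves:* per age bin (native sampling grid by default), the mean
posterior state probability over individuals with a visit in the bin; rows
therefore sum to 1. Empty bins are NaN, not zero. Bands come from
bootstrap resampling of individuals.

*Group comparison:* the point difference is m_P,k − m_NP,k per state and
metabolite. Bands come from a nonparametric bootstrap whose resampling unit
is the individual (the whole trajectory): resample within group, refit with
EM initialized at the group point estimate, realign states to it by greedy
nearest emission means. Band endpoints are symmetric quantiles of the
centered bootstrap distribution (point +/- the (1 − alpha) quantile of
|replicate − point|), widened by the standard sqrt(n/(n−1)) finite-sample
variance inflation (harmonic-mean group size): plain percentile endpoints
are measurably anti-conservative at cohort sizes of a few dozen, and the
symmetric construction halves the Monte-Carlo noise of the endpoints at
moderate bootstrap sizes. Cells are labelled `<1%` when the 99% interval
excludes zero, `1-10%` when the 90% interval does, `ns` otherwise. Replicates whose EM fails are
dropped and counted, never imputed. The full-study bootstrap size is 5000
(`AnalysisConfig.bootstrap_n`); tests and the pipeline default use smaller
sizes (40-200) chosen so the whole analysis runs at desk scale, and the
calibration tests measure the bands' actual null behaviour at exactly those
sizes.

## Cross-dataset matching

Given X (Nx x dx) and Y (Ny x dy) with no shared features, the method
alternates (i) ridge-regularized CCA on the currently matched row pairs and
(ii) a globally optimal linear assignment (Jonker-Volgenant via scipy)
minimizing squared distance in the projected subspace, until the matching is
a fixed point. The objective reported per iteration is the sum of canonical
correlations; the best iterate across restarts is returned.

Two numerical points matter at desk scale (tens of rows and features):

* **Ridge strength.** With n ~ 50 pairs and d ~ 20 features, a weakly
  regularized CCA reaches near-perfect correlations for an *arbitrary*
  permutation — the objective then cannot distinguish right from wrong
  matchings. The default ridge is 0.1 x the mean diagonal covariance of
  each block, at which the objective separates cleanly; it is configurable.
* **Initialization.** The top-r left singular vectors of each centered
  matrix span its dominant sample-space subspace, and when the matrices
  share latent factors these subspaces agree up to an orthogonal transform.
  Candidate starting matchings are built by enumerating axis permutations
  and sign flips of those components (r capped at 4 for the enumeration),
  each refined by rigid iterative-closest-point (orthogonal Procrustes +
  assignment), plus a rotation-invariant norm-rank pairing and a fixed set
  of random rotations; candidates are ranked by registration cost. Seeded
  random matchings top up the restart list. The rank default r = 3 mirrors
  the three-state structure.

To pair the *lipids* of two studies (rather than samples), pass matrices
with lipids as rows; the pipeline uses each lipid's fitted per-state
emission means (progressor and non-progressor, K values each) as its
descriptor vector.

## Two-way effect decomposition

For one matched metabolite pair measured per individual in two organisms and
two disease groups, cell means of the 2x2 design are decomposed with
sum-to-zero contrasts: cell(o, g) = grand + organism(o) + disease(g) +
interaction(o, g), each factor's effects summing to zero. Least squares on
cell means weights each cell equally, so unbalanced cells do not tilt the
organism term; "removing the organism effect" is literally subtracting one
mean parameter. The reconstruction identity holds exactly on every input.
CIs are percentile bootstrap, resampling observations within cell
(stratified, preserving the design). The resampling unit is the observation;
resampling individuals instead would widen intervals when one individual
contributes several visits — noted as the alternative.

## Surrogate risk marker

lysoPC (µmol/l) = PC(16:0/0:0) + PC(18:0/0:0) at the visit nearest 8 weeks;
standardized over the cohort to lysoPC_S (population SD by default, sample
SD via a flag — the defining rule says only "zero mean and unit variance");
Marker = lysoPC_S if IAA-negative, −lysoPC_S if IAA-positive (IAA positivity
with high lysoPC is protective, hence the flip); Marker >= −0.1 calls high
risk, the boundary inclusive. The −0.1 threshold is a fixed constant of the
rule, kept as a config default rather than calibrated from data.

Evaluation: Pearson chi-square without continuity correction on the 2x2
risk-by-outcome table; relative risk RR = P(progression | high) /
P(progression | low); lower tolerance bound = 5th percentile of RR over
bootstrap resamples of individuals (default 1000). Any table or resample
with a zero cell gets 0.5 added to every cell before the ratio.

## Per-lipid statistics

* Wilcoxon rank-sum, two-sided: exact null for combined n <= 12 without
  ties, otherwise the normal approximation with tie and continuity
  corrections (the R `wilcox.test` defaults). The continuity correction
  matters downstream: without it the discrete null p-distribution puts too
  little mass near 1 and biases the pi0 estimate low.
* Storey q-values: pi0 from the p-value tail; for m < 100 a single fixed
  lambda = 0.5 (the smoother is unstable on small batteries), otherwise a
  cubic fit to pi0(lambda) on lambda = 0, 0.05, ..., 0.90 evaluated at the
  grid maximum, clipped to [1/m, 1]. q_i = min over p_j >= p_i of
  pi0 * m * p_j / rank(p_j); with pi0 = 1 this is exactly Benjamini-Hochberg.
* Fold difference: log2(median_high / median_low); positive = up in the
  high-risk group.
* Correlation distance: 1 − Pearson r (range [0, 2]); 1 − |r| available via
  a flag. The variant choice is exposed because only the "correlation
  based" nature of the original distance is documented.
* Ward clustering on the correlation distance for lipid heatmaps
  (scipy agglomeration; deterministic, equal-distance merges resolve to the
  earlier-encountered pair); reference-normalized profile matrices
  (divide by reference-group mean, log2, unit variance) cluster with
  Euclidean metric and complete linkage.
* HOMA-IR = fasting insulin (µIU/ml) x fasting glucose (mmol/l) / 22.5.

## Synthetic studies

`GeneratorSpec` defaults emulate the female-mouse study arm: 12 progressors
/ 14 non-progressors, weekly visits from 3 to 36 weeks, 154 lipids, and
progressor censoring at a geometric onset time (hazard 0.10/week after week
10, matching a colony in which onset is late). Emissions are Gaussian per
state *on the log2 scale* with mean dwell of 3 weeks per state
(stay probability 2/3); stored concentrations are 2^z − 1 clipped at 0, so
the default modelling transform recovers the emitted values exactly. The
default truth means mimic the qualitative disease pattern — early-state
phospholipid decrease and late-state lysoPC increase in progressors — with
magnitudes exposed as free parameters (`state_step`, `noise_sd`,
per-group `hmm_truth`), since true effect sizes are not tabulated anywhere;
recovery tests use a separation of 3 noise SDs between adjacent states.

The cross-species generator draws shared latent factors Z ~ N(0, I),
maps them through per-dataset random loadings, adds isotropic noise and
returns the true row permutation. The marker-cohort generator plants
elevated lysoPC in IAA-negative progressors and divides the progression odds
of IAA-positive individuals with above-median lysoPC by `protection_odds`;
with zero shift and odds 1 it is an exact null.

What the generators deliberately do **not** emulate: measurement drift and
batch effects, missing visits, covariance between lipids within a state
(emissions are independent given the state), irregular per-individual
sampling, and sex differences beyond "no group difference". Passing tests
therefore demonstrate correctness of the estimators under the stated model,
not robustness to those real-data artifacts.

## Problem sizes used in tests and the acceptance script

Simulation sizes are chosen to keep a full run at desk scale: parameter
recovery uses 30 individuals x 30 visits x 10 metabolites; null calibration
of the difference bands uses 50 replicate cohorts with 60 bootstrap refits
each; the matching benchmark is n = 50 rows at noise SD 0.2; two-way
coverage uses 200 null replicates of 10 observations per cell with 400
bootstrap draws; the Wilcoxon/pi0 null calibration uses batteries of 154
tests at the study's 12-vs-14 group sizes. The end-to-end pipeline runs the
full 26-individual, 154-lipid default study.

## Known limitations

* Model selection over K is out of scope; K is fixed (default 3).
* The bootstrap difference bands come from refits initialized at the point
  estimate; even with the symmetric construction and finite-sample
  inflation they remain slightly anti-conservative with groups of ~15
  individuals (the calibration test quantifies this at the sizes used).
* The matching initializer enumerates subspace alignments only up to rank
  4; higher ranks rely on the rotation-invariant and random starts.
* Occupancy bins assign each visit to the nearest bin centre; unequal bin
  widths are the caller's responsibility.
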