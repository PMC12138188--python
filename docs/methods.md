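# Methods

## Model

`phyloccm` models the joint evolution of *n* binary features (gene or
element presence/absence) along a rooted phylogeny as a continuous-time
Markov chain on the 2<sup>n</sup> joint states. A state is a vector
x = (x₁, …, xₙ) with xₖ ∈ {−1, +1}. From state *i* exactly one feature
can flip at a time, at rate

log τ<sub>i,k</sub> = αₖ − β<sub>kk</sub> x<sub>i,k</sub> −
Σ<sub>h≠k</sub> β<sub>hk</sub> x<sub>i,k</sub> x<sub>i,h</sub>.

αₖ sets the overall tempo of change for feature *k* (log-rate units, per
unit branch length). β<sub>kk</sub> is half the difference between the
gain and loss **log**-rates: the gain rate is exp(αₖ + β<sub>kk</sub>),
the loss rate exp(αₖ − β<sub>kk</sub>), so positive β<sub>kk</sub>
favours presence. β<sub>hk</sub> is the interaction: positive values
lower the rate of breaking a concordant configuration and raise the rate
of restoring it, which is the model's operationalisation of coevolution;
negative values encode repulsion. One coefficient serves each unordered
pair (β<sub>hk</sub> = β<sub>kh</sub>), giving 2n + n(n−1)/2 free
parameters — five for the pairwise case the scan uses throughout.

States are indexed by bₖ = (xₖ+1)/2 with feature 0 in the
least-significant bit; this convention is fixed so serialised matrices
are reproducible. The dense generator is built only for n ≤ 10 (the scan
itself only ever needs n = 2; the guard exists because the state space is
exponential).

Model assumptions worth keeping in mind: a single stationary CCM process
per comparison (no rate variation across branches), independent feature
pairs (each pair is fit in isolation), and a known, fixed tree with
branch lengths proportional to expected amounts of change.

## Likelihood and root distribution

The likelihood of the observed leaf states is computed by Felsenstein's
pruning algorithm: a post-order pass propagating per-state partial
likelihood vectors, with per-node renormalisation and accumulated log
scalers so large trees do not underflow. Transition matrices exp(Qt) are
obtained from one eigendecomposition of Q reused across all branches
(with a per-branch Padé `expm` fallback whenever the eigenbasis is
ill-conditioned or the reconstructed matrices miss row-stochasticity by
more than 1e−9); rows are clipped to [0, ∞) and renormalised, and the
row-sum contract is 1e−10.

The root state distribution is uniform over the 2<sup>n</sup> states by
default. It adds no estimable parameters, is symmetric under
presence/absence relabelling, and factorises across features (which makes
the β₁₂ = 0 likelihood exactly the sum of the two single-feature
likelihoods — a property the tests exploit). The distribution is an
explicit argument, so the stationary distribution of Q can be substituted.

## Estimation and testing

For each feature pair the five parameters are estimated by BFGS
(quasi-Newton) on the negative pruning log-likelihood, gradient tolerance
1e−6, at most 500 iterations. Finite-difference gradients near an optimum
often end with scipy's "precision loss" status; such fits are accepted as
converged when the final gradient is small. The reported optimum is never
allowed to be worse than the start point.

Initialisation: interaction and asymmetry terms start at 0; each αₖ
starts at the log of the Fitch-parsimony change count per unit total tree
length (clipped to ±3), a scale-aware start that costs one linear pass.

Standard errors come from the inverse of a central-difference Hessian of
the negative log-likelihood at the optimum (relative step 1e−4). If the
Hessian is not positive definite the fit is flagged invalid — never
patched. The Wald statistic Z = β̂₁₂ / SE(β̂₁₂) is referred to the
standard normal for a two-sided P-value. No multiple-testing correction
is applied; users filtering thousands of pairs should account for the
number of tests themselves.

An optional ridge penalty on the β terms (default weight 0) is available
for exploratory use on small trees where the likelihood can be flat.

Validity screening: a fit is invalid when it did not converge, when
standard errors are unavailable, or when |Z| exceeds a cap (default 100).
Weakly identified pairs — e.g. near-perfectly concordant profiles on
small trees — produce runaway estimates with |Z| in the 10³–10⁵ range or
enormous standard errors; the cap separates that failure regime from
genuine signal (|Z| < 10 in realistic scans) by two orders of magnitude.
Invalid pairs are reported as NA in the output matrices, distinguishing
"untested or unusable" from Z = 0.

## Tree normalisation

The scan requires a rooted, strictly binary tree with branch lengths.
A tree whose basal node has ≥ 3 children is treated as unrooted and
midpoint-rooted: the root is placed halfway along the longest
leaf-to-leaf path, with ties broken toward the lexicographically smallest
endpoint pair so the placement is deterministic. Multifurcations are
resolved randomly (seeded, default seed 42, a CLI option) with zero-length
edges, preserving all path lengths. Genome IDs in the feature table must
all have leaves; leaves without table rows are pruned, suppressing
unifurcations and summing their edge lengths, so retained pairwise
distances are unchanged. Missing branch lengths are an error rather than
being imputed — the CTMC is meaningless without them. The normalised tree
is written alongside the matrices so downstream analyses see exactly the
tree that was used.

## Filtering and pair selection

Abundance bounds are absolute presence counts, inclusive at both ends;
features outside them are removed and reported. Near-ubiquitous and
near-absent features carry almost no signal for a pairwise rate model and
mostly produce invalid fits. Prefix subsets (`compare_from`/`compare_to`)
use literal string prefixes; a pair is tested when one member matches a
FROM prefix and the other a TO prefix in either orientation, each
unordered pair once. An empty prefix list means the full feature set.

## Parallel orchestration

The work unit is one feature pair. The pair list is fixed before
dispatch, workers receive a pre-flattened tree index, and results are
gathered in plan order, so written outputs are byte-identical for any
worker count. A pair whose fit raises an exception is recorded as NA and
the scan continues (mirroring how non-converged comparisons are screened
out rather than aborting a large run); I/O and tree errors abort.

## Synthetic data

The simulator evolves profiles under exactly the model above: the root
state is drawn from the likelihood's root distribution (uniform, keeping
simulation and inference consistent) and each child state is drawn from
the branch's exact transition matrix — no event-level approximation, so
arbitrary branch lengths are handled exactly. Trees are sampled by
uniform random coalescence with i.i.d. exponential branch lengths
(default mean 0.3, chosen so a few-hundred-leaf tree produces profiles
with intermediate frequencies and multiple independent gains/losses, the
regime where pairwise rate models are informative). Default generating
parameters for calibration studies are α = 0, β_diag = 0 with β₁₂ the
quantity varied.

What the simulator does **not** emulate: annotation noise and
misclassification, assembly artifacts, correlated sampling of genomes,
tree estimation error, or donor/recipient mechanics of lateral transfer
beyond the CCM's rate coupling. Passing calibration tests therefore show
the estimator is correct *under the model*, not that real annotations are
noise-free.

Multi-feature fixtures are simulated as independent coupled pairs
(`pairN_a`/`pairN_b` share an interaction, distinct couples are
independent), so tables of any width stay within the pairwise model while
providing known truth for end-to-end scans.

## Calibration results and problem sizes

The test suite checks, at fixed seeds: agreement of pruning with
exhaustive enumeration on 3–4-leaf trees (1e−8), the closed-form
two-state chain, factorisation at β₁₂ = 0, CTMC contracts
(Chapman–Kolmogorov at 1e−8), estimator bias within Monte-Carlo error and
95% Wald coverage at β₁₂ ∈ {0, 1} on 200-leaf trees (100 replicates per
setting), type-I error at the 0.05 level across 200 valid null fits
(exact binomial 99% band), worker-count determinism of a 20-genome ×
30-feature scan, and serialisation round-trips. The replicate counts and
tree sizes are the package's calibration conditions; the acceptance
script reruns scaled versions of the same studies (100 replicates per
setting) from a user-supplied seed.

## Known limitations

- Pairs whose profiles are almost perfectly concordant or anti-concordant
  on small trees are weakly identified; expect NA (invalid) results for
  them rather than significant P-values. More genomes, not looser
  screening, is the remedy.
- Maximum-likelihood estimates of β₁₂ carry the usual O(1/n) small-sample
  bias, negligible against typical standard errors at a few hundred
  leaves; the recovery tests bound it at Monte-Carlo precision rather
  than estimating it.
- The Wald test relies on asymptotic normality; for trees with few
  informative state changes the likelihood-ratio test would be more
  robust but is intentionally not provided (one test statistic, one
  screening rule).
- Abundance thresholds are counts, not proportions; convert explicitly
  for very small genome sets.
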