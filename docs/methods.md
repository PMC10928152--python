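# Methods

This note documents the models, estimators and numerical choices behind
`mdstates`, and what the synthetic benchmarks do and do not establish.

## Preprocessing

ROI time series are cleaned by (1) nuisance regression on the six
realignment parameters (3 translations, 3 rotations), (2) linear
detrending, (3) normalization. `regress_nuisance` and `detrend_linear`
exist as standalone steps in that order; `preprocess_run` projects the
intercept, linear trend and motion regressors out in a *single* joint
least-squares step before z-scoring. The joint projection is deliberate:
applying the two projections sequentially lets the detrend step reintroduce
motion components (the trend is not orthogonal to the motion series), which
would break idempotence of the chain. After `preprocess_run` the output is
exactly orthogonal to every motion regressor and to the trend, has zero
mean and unit sample variance (ddof = 1) per column, and is a fixed point
of the chain to machine precision.

"Normalization" is implemented as z-scoring; constant motion columns are
dropped from the design with a warning; a zero-variance ROI raises an error
naming the ROI.

## The brain-state model

A Gaussian-emission hidden Markov model over the observed ROI space,
estimated by variational-Bayes EM.

Priors and defaults:

| parameter | default | role |
|---|---|---|
| `K_init` | 15 | initial (generous) state count |
| `alpha_pi`, `alpha_trans` | 1e-3 | sparse Dirichlet concentration on p(i) and on each row of A; drives automatic pruning |
| `beta0` | 1e-3 | Normal–Wishart mean-precision scale (weak) |
| `nu0` | D + 2 | Wishart degrees of freedom (weakest proper) |
| `W0` | diag(1/var(data))/nu0 | prior expected precision matches the data's inverse variances |
| prune threshold | 1/(10·K_init) | minimum expected usage for a state to survive |
| convergence | rel. ELBO change < 1e-6, max 500 iterations | |
| restarts | 5 | k-means initializations; best final ELBO wins |

The per-iteration objective is the exact ELBO for this factorization,
`sum_runs log Z~ − KL(q(θ) ‖ prior)`, with `log Z~` from forward–backward
under the geometric-mean ("expected log") parameters of q. The trace is
non-decreasing and is stored in `fit_diagnostics`. For K = 1 the bound is
tight: the tests verify it against the closed-form Normal–Wishart evidence
computed independently through the sequential multivariate-t predictive.

**Inference numerics.** Forward–backward runs in a max-shifted hybrid of
log and probability domain. This matters because the expected-log emission
terms scale with the Wishart degrees of freedom: log-likelihood gaps of
thousands of nats between states are routine, and a plain scaled-probability
implementation overflows in the backward pass. Chains reset to p(i) at
every run boundary; runs of equal length are processed as one vectorized
batch. Pairwise transition marginals are normalized per timepoint (they sum
to one exactly), avoiding large intermediate scale factors.

**Pruning and merge refinement.** After convergence, states with expected
usage below 1/(10·K_init) are removed and the model refit, repeating until
stable. On top of that, near-duplicate states can survive as *shallow local
optima* with a few percent usage each — empirically these solutions sit
hundreds of nats below the basin in which the duplicates are merged. The
fitter therefore attempts ELBO-guided merges: the most-overlapping state
pair (smallest symmetrized KL between expected Gaussians) has its
responsibilities combined and the model refit; the merge is accepted only
if the bound improves. This changes no prior and no objective — it is purely
a better optimizer for the same model.

**Exported parameters and TPP convention.** The model exposes p(i), A(i,j)
and per-state (μ_k, Σ_k) with Σ_k the inverse expected precision
(ν_k W_k)⁻¹. The official per-run TPPs are computed by one exact
forward–backward pass under these point parameters — both at fit time and
in `apply_model` — so fitted and transferred posteriors coincide by
construction and agree with any independent implementation of the smoother
given the same frozen parameters.

**Transfer ("analysis with priors").** Global latent variables (p, A, state
Gaussians) are data-instance independent and are held fixed; local
variables (the TPPs) are recomputed for new runs by a single
forward–backward pass. This is the mechanism behind cross-task temporal
closeness.

## State matching

Space closeness c = 1/KLD. The KL direction between two fitted states is a
convention with no canonical choice, so the default divergence is the
symmetrized (Jeffreys) form and both one-way KLs are always reported; the
tested contract is the *identity of the argmax*, which is stable across
conventions on well-separated inventories. c = ∞ (identical Gaussians) is
reported as an infinity sentinel with a flag.

Temporal closeness r correlates TPP columns over runs concatenated in
sorted subject order; the per-run correlation array is retained so that a
few dominating subjects can be spotted. A state never visited under one
model yields a zero-variance column and a NaN, flagged rather than silently
dropped.

Permutation significance: the null statistic is the closeness of a
uniformly drawn pair of distinct states from the pooled inventory of both
models (same-task pairs allowed), excluding the observed pair;
p = #(null ≥ observed)/n_perm with n_perm = 100 by default, reported at the
1/n_perm floor when no null sample reaches the observed value. Raw
exceedance counts are always kept alongside p. Calibration is verified by
simulation: when the observed pair is itself drawn from the null process,
the p-values pass a KS uniformity test.

Near-ties in c (relative gap below 1e-9) are broken by temporal r and
flagged.

## Virtual lesions

`remove_roi` is exact Gaussian marginalization (drop the mean entry and the
covariance row/column). For a state pair, delta_ROI = |KLD(full) −
KLD(lesioned)| and impact = 1/delta, capped at a configurable ceiling when
delta < 1e-12 (flagged). The reported convention: high impact = removing
the ROI barely perturbs the divergence = the ROI carries structure shared
by the two states. Both delta and 1/delta are emitted so the opposite
reading remains recoverable.

A caveat discovered while validating the planted-ROI benchmark: "identical
marginal in ROI j" only implies "ROI j contributes nothing to the
divergence" when ROIs are independent. With correlated covariances,
marginalizing ROI j also reshapes the Schur-complement structure of the
remaining ROIs, and the planted ROI need not attain the top rank. The
recovery benchmark therefore plants the similarity-carrying ROI in states
with diagonal covariance; on real (correlated) states the impact profile is
reported as-is and interpreted as a whole.

The optional per-ROI permutation p-value — observed lesioned-pair closeness
against lesioned random pairs from the pool — is this package's own
reconstruction of a significance recipe whose original details are not
public; it is off by default and labeled as such.

## Behavioral indices

All indices are oriented so larger = better cognitive control:
AxCPT z(AY RT) − z(BX RT); CuedTS and Stroop −(incongruent − congruent) RT
with the signed cost also emitted; Sternberg and RP accuracy/RT on the
demanding condition, z-scored; SST 1000/SSRT in 1/s. SSRT uses the
integration method of the independent race model — the n-th percentile go
RT at n = P(respond|stop) (index ⌈p·n⌉ of the sorted sample) minus the mean
SSD, with go omissions replaced by the maximum go RT — following consensus
guidelines; a mean-method variant sits behind a flag. SSRT is flagged
inestimable when P(respond|stop) ∈ {0, 1}. Paired condition contrasts use
the two-tailed paired t-test with Cohen's d_z = mean(diff)/sd(diff)
(pooled-sd d behind a flag).

## Brain–behavior statistics

CCA whitens both standardized blocks by Cholesky factors of their
(optionally ridge-regularized) covariances and takes the SVD of the
whitened cross-covariance; singular values are the canonical correlations.
Rank-deficient blocks get a 1e-6 ridge, flagged. Component selection is
operationalized as the component whose behavioral scores correlate most
strongly (in absolute value) with a supplied control-orientation index,
sign-fixed so that alignment is positive; all components are always
reported. Significance: permutation of subject rows (1000 by default,
seeded), statistic = the selected component's canonical r.

Predictive LOO CCA refits with each subject held out, selects the component
by the same rule on the training fold, sign-aligns the fold weights to the
full-sample solution (canonical weights are sign-indeterminate), projects
the held-out subject, and correlates the n held-out brain scores with the
n held-out behavior scores. Under the null this statistic is centered at
zero; under planted coupling it is positive and smaller than the in-sample
canonical r (shrinkage) — both verified by simulation.

Univariate occupancy–behavior links are two-tailed Pearson correlations
(t-distribution, n − 2 df). The specificity screen correlates every state's
occupancy with the index and flags states that are significantly *positive*;
p-values are not adjusted for multiple comparisons by default, with a
Benjamini–Hochberg option behind a flag.

## Synthetic cohorts

The generator emulates the data layout the pipeline expects: per subject
and task, a run of T timepoints over D = 11 ROIs from a sticky first-order
Markov chain (default self-transition 0.85, in the range typical of
task-fMRI state analyses) with Gaussian emissions. State means are drawn at
z-scale (sd 1.0, well-separated relative to near-unit covariances); state
covariances are random correlation-like matrices shrunk 40% toward the
identity for conditioning. State 0 can be planted as a shared state with
identical (optionally jittered) parameters in every task. Between-subject
occupancy variation comes from a per-subject logit shift (sd 0.6) of the
shared state's self-transition; the behavioral index per task is
`coupling · z(realized shared-state occupancy) + noise`, and
`coupling_for_correlation(r)` converts a target population correlation into
the matching slope/noise pair. Optional nuisance structure — linear drift
and six smooth random-walk motion series linearly mixed into the data — is
off by default and switched on by the preprocessing tests, since the clean
condition is the relevant one for model-recovery benchmarks. No
hemodynamic convolution is applied (states are defined on the observed ROI
series; a toggle exists but defaults off and is intentionally unmodeled).

What passing tests show — and do not. The benchmarks establish internal
correctness (exact inference, calibrated permutation nulls, unbiased
recovery at realistic SNR) under Gaussian, first-order-Markov,
convolution-free data with stationary states shared exactly across
subjects. Real BOLD violates all of these to some degree (autocorrelated
noise, HRF smoothing, subject-level state variation), so recovery rates
here are upper bounds, not field performance estimates.

## Problem sizes used in the checks

Recovery uses the full pinned configuration (K_true = 4, D = 11, 40
subjects × T = 300, K_init = 15, 5 restarts). Replicate-heavy checks run at
reduced scale chosen once for tractability: match consistency at 8 subjects
× T = 200, K_true = 3, K_init = 7, 2 restarts, 40 replicates; permutation
calibration with directly sampled state inventories (the test consumes only
state Gaussians, so no HMM fit is needed), 500 replicates; brain–behavior
with generator-truth occupancies at n = 50 (the statistics, not the HMM
fit, are under test there); SSRT at 600 go / 200 stop trials, 50
replicates. `scripts/acceptance.py` uses the same designs with a
20-subject recovery cohort and 10 matching replicates.

## Known limitations

* The latent states live in observed ROI space; no learned low-rank
  subspace is fit (every downstream quantity consumes only μ, Σ, p, A and
  TPP, which are exposed in full).
* Group-level fitting only: one model per task, subject variation enters
  through per-run posteriors, not random-effects parameters.
* The permutation p floor (1/n_perm) bounds reportable significance at
  0.01 for the default 100 permutations; raw counts are reported so users
  can pool or increase n_perm.
* Dwell-time distributions and entropy rates are not computed.
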