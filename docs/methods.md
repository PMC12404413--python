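# Methods

`latentwb` models resting-state fMRI of disorders-of-consciousness (DoC)
cohorts in a low-dimensional latent space: parcellated BOLD series are
projected to ~15 latent dimensions, a stochastic whole-brain model is fitted
per subject by maximizing the structural similarity (SSIM) between empirical
and simulated latent functional connectivity (FC), and two biomarker
families are extracted — graph measures of the fitted coupling (the
generative effective connectivity, GEC) and the fitted local node
parameters. This note records the models, the numerical choices, and what
the synthetic cohorts do and do not establish.

## Latent projection

Each time point of a parcellated recording (d_init regions, TR = 2 s;
recordings with a coarser TR are linearly interpolated onto a 2-s grid) is
one training vector. Two reductions are available:

* **Auto-encoder** — dense layers of widths 0.75, 0.5 and 0.25 x d_init,
  a bottleneck of size d_latent in [2, 25], and a mirror-image decoder.
  tanh activations and the Adam optimizer (defaults: learning rate 1e-4,
  batch 20, 15 epochs). Inputs are z-scored per region over the training
  set; the activations and standardization are this package's choices —
  they are standard for small dense auto-encoders on roughly standardized
  signals.
* **Linear (PCA)** — the principal-subspace projection of the pooled
  time-point vectors; its held-out MSE equals the discarded-eigenvalue sum
  divided by d_init, which the tests use as an exact oracle.

The latent dimension is selected by two criteria: the elbow of the
10-fold (subject-split) cross-validated reconstruction-MSE curve,
operationalized as the interior point of maximum discrete curvature of the
axis-normalized curve (the original criterion is visual; maximum curvature
makes it deterministic and testable), and the smallest dimension whose
latent-FC classification accuracy is at least the natural-space accuracy.
Classification uses an SVM (polynomial kernel, degree 3, C = 0.1,
gamma = 7.5) on upper-triangle-vectorized FC matrices, with each series
split into 4 contiguous windows for augmentation and leave-one-subject-out
cross-validation so no subject appears on both sides of a fold.

## Whole-brain models

Both models run on the d_latent latent nodes coupled by a matrix that the
fitting stage estimates. Integration is RK4 on the drift with step
dt = 0.05 s plus an additive Gaussian increment sigma*sqrt(dt)*N(0,1) per
step, subsampled at TR. Output series are z-scored before FC computation.

**Hopf (Stuart–Landau)** — each node is a noisy oscillator near a
supercritical Hopf bifurcation with bifurcation parameter `a`, noise
`sigma`, and intrinsic frequency omega_i set to the spectral edge frequency
at 50% power (SEF50) of that node's empirical signal; diffusive coupling
G*sum_j C_ij (x_j - x_i) with G fixed to 1 (any global gain is absorbed
into the fitted C). Fitted node parameters: a in [-0.5, 0.5], sigma in
[0.5, 7.5].

**AHP (neuron–astrocyte)** — per node: mean voltage h, synaptic
facilitation x and depression y in [0, 1] (clipped each step), with
afterhyperpolarization implemented as a piecewise equilibrium/timescale
(T0, tau0): bursting/rest (tau0 = tau from 1/SEF50, T0 = 0) while the
depression pool is full (y > Y_AHP = 0.85) and h >= H_AHP = -7.5; medium
AHP (tau_mAHP, T0 = T_h < 0) once the pool is releasing and depleted below
Y_h = 0.5; slow AHP (tau_sAHP, T0 = 0) while releasing with a replenished
pool or hyperpolarized voltage. The releasing condition is evaluated as
y < 1/(1 + L x (h - T0)+) with the current T0. The guards do not cover the
whole state space; when none fires, a node holds its previous phase — the
guards read as transitions of a burst cycle, so hysteresis is the
consistent completion. Regime guards are evaluated once per step and
(tau0, T0) held through the RK4 substages. Long-range input to node i is
sum_j J_ij x_j y_j (h_j - T0_i)+, taken literally with the receiving
node's T0. Fixed constants: K = 0.037 Hz, L = 0.028 Hz, facilitation
timescale 0.9 s, depression timescale 2.9 s (labelled per the
local-model equations). Fitted node
parameters and ranges: sigma [0.5, 7.5], X_eq [0.01, 0.21], Y_eq [0.1, 1],
T_h [-50, -10], tau_mAHP [0.05, 0.5] s, tau_sAHP [0.75, 15] s.

**Stability.** The Stuart–Landau cubic is stiff for RK4 at dt = 0.05 s:
for sigma above roughly 4.5 noise excursions beyond radius ~4 diverge.
Blow-up raises `IntegrationError`; the node search rejects such candidates
and keeps sampling; the cohort generator rejection-samples parameter draws;
the GEC descent reports non-convergence. This keeps the stated integrator
and ranges while making every stage total.

**Burn-in.** Fitting simulations and cohort generation integrate and
discard 30 leading seconds. All runs start from the same deterministic
state, and when several runs are averaged the shared initial transient
survives averaging while the noise shrinks — without the discard this
inflates the simulated FC's contrast.

**Balloon–Windkessel** — the standard four-state hemodynamic system
(vasodilatory signal, inflow, venous volume, deoxyhemoglobin; kappa = 0.65,
gamma = 0.41, tau = 0.98 s, alpha = 0.32, rho = 0.34, V0 = 0.02) with the
nonlinear BOLD readout, RK4 at dt. Latent signals are encodings of BOLD,
so by default models are fitted on their raw output without this stage;
it is available behind a flag (`--bold`).

## Fitting

The objective everywhere is the windowed SSIM between connectivity
matrices, with c1 = (0.01 L)^2, c2 = (0.03 L)^2, L = 1, and a 7x7 uniform
sliding window — the largest standard odd window that still slides within
a 15x15 matrix; matrices smaller than the window are scored as a single
window.

Calibration alternates two stages for 4 (Hopf) / 6 (AHP) outer iterations,
with the coupling initialized at the empirical FC:

1. **Node search** — N_max(iter) = (4 - iter) x 1000 candidates (1000 from
   iteration 4 on) drawn uniformly from the authorized ranges, each scored
   by the FC of N_sim(iter) = 10 x iter + 15 (50 from iteration 4 on)
   averaged 300-s simulations against the subject's FC, early-stopping at
   SSIM >= 0.9. After each outer iteration the ranges are re-centred on
   the best value with width halved (the shrink factor is this package's
   choice), clipped to the authorized bounds. Simulated runs are averaged
   as series before correlating (the average of per-run FCs is available
   behind a flag). Candidate seeds derive from (subject seed, outer
   iteration, candidate index), so fits are reproducible.
2. **GEC descent** — GEC_ij += eps [(FC_emp - FC_sim) + (FC_emp^tau -
   FC_sim^tau)]_ij with eps = 0.01, lag tau = 3 x TR = 6 s, N_sim = 5
   simulations per iterate, stopping when the combined score (mean of the
   direct-FC and shifted-FC SSIM — the two mismatch terms enter the update
   with equal weight, so their scores are averaged the same way) exceeds
   0.95 or after 1000 iterations. The shifted FC entry (i, j) is the
   Pearson correlation of series i shifted forward by tau against
   unshifted series j.

**Early stopping in the descent.** Each iterate's score is estimated from
finitely many stochastic simulations, so the descent's objective is noisy;
iterated indefinitely it overfits the sampling noise of the single
empirical target and the score degrades after a mid-descent peak. The
descent therefore keeps the best-scoring coupling seen and stops once 100
iterations pass without improvement, returning that iterate; the terminal
SSIM is the best score. On self-generated AHP subjects (300 s, TR 2 s)
the terminal combined SSIM plateaus around 0.83–0.90 — the same plateau
regime this procedure reaches on real DoC recordings — rather than the
nominal 0.95 stop; the acceptance script reports the measured value.

## Synthetic cohorts

Patient recordings cannot be redistributed, so a seeded generator emulates
their statistical structure; every downstream stage is tested against it.

* **Coupling** — symmetric, zero-diagonal two-clique matrices (split 8/7
  at d_latent = 15): within-clique entries positive, inter-clique entries
  negative, drawn independently per pair. Condition presets differ only in
  the densities — within-clique positive 0.66 / 0.65 / 0.60 and
  inter-clique negative 0.49 / 0.50 / 0.54 for CNT / MCS / UWS — mirroring
  the finding that effective connectivity, not local parameters, carries
  the diagnosis. Edge magnitudes (AHP 1.5/0.75, Hopf 0.5/0.25) are free
  knobs calibrated once so latent FC off-diagonals have realistic
  resting-state magnitude (mean |r| ~ 0.2–0.5) and two same-parameter runs
  have FC SSIM near or above 0.8.
* **Dynamics** — each subject is simulated by the package's own models
  (default 600 s at TR 2 s, i.e. ~300 time points), with node parameters
  drawn uniformly in the authorized ranges (the fitting prior) and
  per-node intrinsic frequencies in the 0.05–0.1 Hz BOLD band. One master
  seed spawns per-subject seeds through a counter-based splitter.
* **Natural-space surrogates** — latent series lifted to 100 regions by a
  random orthonormal mixing map plus Gaussian noise; noise-free surrogates
  are exactly invertible by least squares.
* **Metadata** — age uniform in [18, 85], gender and etiology categorical,
  serial CRS-R diagnosis sequences built per outcome category; an effect
  specification can tie any node parameter to outcome severity through a
  logit shift, for testing cluster/outcome analyses.

What the synthetic cohorts do *not* emulate: scanner and motion artifacts,
lesion-dependent signal dropout, subject-specific parcellation error,
inter-site heterogeneity, and any empirically realistic relation between
node parameters and diagnosis (conditions differ only through coupling).
Green tests on these cohorts establish that the pipeline recovers planted
structure of the kinds listed; they do not establish clinical validity on
real recordings.

## Biomarkers

* **GEC graphs** — the fitted GEC splits into positive- and negative-edge
  subgraphs (directedness preserved; diagonal excluded). Per node, the
  maximum clique containing it (Bron–Kerbosch; deterministic
  lexicographic tie-break) against the complement yields boundary-edge
  means/stds, aggregated as unweighted means over nodes. Scalars:
  sparsity = #{|GEC| < 0.015}/n^2; asymmetry = mean |GEC - GEC^T| / 2
  (halved for the double count of unordered pairs); mean and std of all
  entries. "Node centrality" and "clustering" are the generic toolkit
  defaults: unweighted degree centrality and the weighted clustering
  coefficient (|w| as weight on the negative subgraph). Groups are
  compared by pairwise two-sample Kolmogorov–Smirnov tests with the usual
  star thresholds.
* **RSN decoding** — single latent dimensions (or GEC cliques) are decoded
  by zeroing all other dimensions, decoding each subject and averaging the
  decoded signals over subjects; the result's FC is matched by SSIM
  against 7 resting-state-network reference FCs built by keeping cohort
  data only on one network's regions and replacing the rest with 1e-3
  uniform noise (keeping correlations defined). Decoded series are
  z-scored before FC to neutralize decoder gain. The repository's
  100-region network lookup is a synthetic stand-in with Schaefer-like
  block proportions, not an atlas product.
* **Node-MBB clustering** — per-patient fitted parameter vectors (6 AHP /
  2 Hopf columns, fixed order), z-scored per column (the parameters have
  incommensurate units), embedded by UMAP (n_neighbors 5, min_dist 0.1,
  seeded) and clustered by HDBSCAN (min_samples 3, min_cluster_size 3).
  CRS-R sequences collapse to five outcomes: Dead (terminal death),
  Emerged (final EMCS), else Increasing / Decreasing / Stable by final
  vs initial level on the scale coma < UWS < MCS- < MCS < MCS+ < EMCS
  (unsplit MCS between MCS- and MCS+; intermediate excursions ignored, so
  a sequence returning to its initial level is Stable). Composition
  tables group Increasing/Stable/Decreasing as "DoC".

## Known limitations

* The GEC pseudo-gradient is a heuristic, not the gradient of SSIM; with
  a noisy FC target it overfits sampling noise, so the fitted GEC should
  be read as a descriptor of the empirical (shifted) FC seen through the
  model, not as a consistent estimator of the generative coupling. On
  two-clique synthetic data the empirical-FC initialization already
  correlates ~0.8 with the truth and the descent does not systematically
  improve that correlation.
* At the upper end of the authorized noise range the AHP model's FC is a
  rough function
  of its coupling, which bounds reachable SSIM well below 1 for 150-sample
  targets; fit-quality numbers must be compared at matched series length.
* The Hopf model is integrable only for sigma below ~4.5 at dt = 0.05 s
  (see Stability); draws above that are rejected rather than re-scaled.
* Problem sizes in the test-suite and acceptance runs are scaled down
  (e.g. 500-candidate node search with 15 simulations per candidate;
  10-subject recovery cohorts; 300-subject-per-group density-ordering
  cohorts); full-schedule fits use the budgets in the Fitting section.
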