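# Methods

This note documents the generative model, the estimation machinery, the
numerical choices behind them, and what the synthetic validation does and
does not establish about real data.

## Generative model

**Neural dynamics.** Each subject's `n` regions evolve as
`dz/dt = A_eff z + C u(t) + v(t)`. `A_eff` has the between-region rate
constants (Hz) off the diagonal — entry `(i, j)` is the influence of
region `j` on region `i` — and `−0.5·exp(s_i)` Hz on the diagonal, so a
region with zero log-scaling `s_i` relaxes at the default −0.5 Hz and
positive `s_i` means stronger self-inhibition. Stability requires every
eigenvalue of `A_eff` to have negative real part; graphs within 0.05 Hz of
instability are shifted to stability by deepening all self-connections
(subtracting `(max real eigenvalue + 0.1)·I`, re-expressed through the
log-scalings).

**Fluctuations and noise.** The endogenous input `v` is a stationary
Gaussian process with one-sided power spectral density
`α_v f^(−β_v)` ((state units)²/Hz); observation noise has its own law
`α_e f^(−β_e)`. Both are generated by spectral synthesis: Fourier
amplitudes shaped to the target density, complex-Gaussian phases, inverse
FFT, zero-frequency bin forced to zero (every series is DC-free).

**Haemodynamics.** Neural states are convolved with a fixed double-gamma
kernel (response peak 6 s, undershoot peak 16 s, undershoot ratio 1/6,
unit peak, 32 s support). The kernel is a model constant, shared exactly
between the simulator and the inverse model; estimating haemodynamic
parameters per region is out of scope and keeps the inverse problem
well-conditioned at desk scale. This is a deliberate simplification
relative to full biophysical haemodynamic models: linear convolution with
a canonical kernel is sufficient for validating the statistical pipeline,
which is what this package is for.

**Integration.** The neural ODE is discretized exactly (matrix
exponential with zero-order hold) at TR/8, convolved at the fine rate,
downsampled to the TR, and mean-corrected per region. Exact
discretization is unconditionally stable for stable `A_eff`, so step-size
artifacts cannot masquerade as connectivity.

## Synthetic study conditions

The default `SimulationConfig` emulates a fast-TR acquisition:
TR = 0.72 s, run length 207 s (287 samples), 5 regions, 50 subjects,
block schedule of an 8 s countdown followed by 5 cycles of
(20 s stimulus, 3 s response, 15 s fixation). Schedule and run length are
configured independently; the scheduled blocks end at 198 s and the tail
of the run carries no input. The exogenous input drives the last region
(the fusiform node of the emulated five-node network: precuneus, STS,
angular gyrus, temporal pole, fusiform) with weight 0.3 Hz per unit
input.

Noise defaults: neural fluctuations `α_v = 0.01`, `β_v = 1` (pink, the
canonical slow endogenous regime) and white observation noise
`α_e = 0.02`, `β_e = 0`, giving BOLD signal-to-noise of roughly 5–10 —
representative of a principal-eigenvariate regional timeseries.
Between-subject variability adds independent Gaussian deviations
(sd 0.0625 Hz, one shrinkage-prior standard deviation) to the
between-region rates; draws violating the stability margin are redrawn
(at most 20 times) and then shifted.

**Rest/task pairs.** The two conditions share subjects: each subject's
coupling deviations are drawn once and reused, while the group-mean
(template) couplings are scaled per condition (defaults: rest 1×, task
2×) and only the task carries the block input. Scaling the template
rather than the per-subject graphs keeps the between-subject variance
identical across conditions, so the comparison isolates mean coupling
strength — scaling after adding deviations would confound the comparison
by doubling the task cohort's heterogeneity.

## Spectral features

Cross-spectral densities are estimated parametrically: ordinary
least-squares multivariate autoregression of order 8 on mean- and
linear-trend-corrected series, converted through the transfer function to
`S(f) = 2·TR·H(f) Σ H(f)^H` (one-sided density; the integral of the
diagonal over (0, Nyquist] approximates the variance). The default
frequency grid is 32 log-spaced points from max(1/window, 1/64 Hz) to
min(0.25 Hz, Nyquist). The 1/64 Hz floor matters: on ~300-sample windows
the MAR(8) estimate is biased by a factor of several below ~0.01 Hz, and
fitting those bins corrupts the inversion. The upper bound reflects where
the haemodynamic response still passes signal.

The deterministic input's spectrum (`schedule_power`) is evaluated
through the same AR(8) smoothing as the data, not as a raw windowed
periodogram: the model's input term must live in the same feature space
as the smoothed data spectra, and the raw boxcar power is spiky across a
coarse log grid.

## Inversion (variational Laplace)

The data vector stacks the real parts of the unique upper-triangle
entries and the imaginary parts of the strict upper triangle across the
grid. Three numerical choices shape the likelihood:

1. **Per-frequency normalization.** Each frequency's entries are divided
   by the mean observed diagonal power at that frequency. BOLD spectra
   span four orders of magnitude over the band; on the raw scale the
   lowest bins dominate the objective and coupling recovery collapses
   (correlation with ground truth ~0.5 instead of ~0.95 in our
   three-region experiments). After normalization the single residual
   log-precision hyperparameter (prior N(6, 1/128)) weights frequencies
   on a comparable relative-error scale.
2. **Effective observation count.** The stacked features are deterministic
   functions of the MAR fit, which has `8n² + n(n+1)/2` parameters —
   fewer than the `F·n²` stacked values. The likelihood is scaled by
   `min(1, mar_dof / n_features)`. Without this the posterior claims
   several times too much precision, pure-noise fits "earn" ~14 nats by
   absorbing feature noise into the coupling matrix, and the group-level
   between-subject precision estimates destabilize.
3. **Symmetry breaking for driving weights.** Input power enters as
   `U(f)·C C^T`, which is quadratic in `C`; the free-energy gradient with
   respect to `C` therefore vanishes identically at the zero prior mean.
   When an input is modelled, zero entries of `C` are initialized at 0.1
   so the ascent can recruit the input at all. All other parameters start
   at the prior mean.

Optimization is Gauss–Newton with Marquardt damping (λ starts at 1,
halves on accepted steps, doubles on rejected ones), an analytic
forward-model Jacobian (validated against finite differences to 1e−5),
and a Newton update of the residual log-precision after each proposal. A
proposal is accepted only if it increases the free energy, which makes
the accepted-step trace non-decreasing by construction. Convergence is
declared after 4 consecutive accepted steps with ΔF < 0.01 nats, at 64
iterations, or when the damping exceeds 1e8. Priors: between-region rates
N(0, 1/64) (shrinkage — zero coupling absent evidence), self log-scalings
N(0, 1/256), driving weights N(0, 1/64), spectral parameters
(log-amplitudes around α_v = 0.01 / α_e = 0.02, additive exponent
deviations around β_v = 1 / β_e = 0) N(0, 1/64). The free energy is
reported with its exact decomposition `F = accuracy − complexity`, where
complexity is the Gaussian KL of the posterior from the prior.

## Group stage

**Reestimation.** All subjects of both datasets are re-inverted with the
prior mean over the connectivity block (between-region rates + self
log-scalings — the block shared by rest fits, which carry no `C`, and
task fits) replaced by the grand-average posterior mean, priors otherwise
unchanged. This can rescue subjects stuck in local optima; it does not by
itself shrink estimation scatter much, because the default prior
covariance is wide relative to the (over)confident subject likelihoods.

**PEB.** Each dataset's subject posteriors enter a hierarchical model
`θ_s = Xβ + ε_s`, `ε_s ~ N(0, Γ)`, consumed as Gaussian likelihood
ratios (posterior over own prior) so that replacing the first-level prior
by the group model is exact for linear-Gaussian beliefs — no timeseries
are refitted. `Γ = exp(−γ)·(within-prior covariance)/16`, with the single
log-precision `γ` given a tight N(0, 1/16) hyperprior and optimized by
bounded scalar search on the exact (given γ) marginal likelihood, plus a
Laplace correction from the numeric curvature at the optimum. The
`gamma_fixed` argument pins γ instead — used for degenerate limits (e.g.
forcing Γ → 0 with identical subjects, where the group mean provably
equals the shared subject mean). The default design matrix is an
intercept only.

## Comparison indices

All three indices are computed from the same PEB belief per dataset.
Certainty is `−½ ln|2πeΣ|` via a Cholesky log-determinant; parameter gain
is the closed-form Gaussian KL; model gain builds the default model space
(the fully connected model plus one model per between-region connection
with exactly that connection switched off — 21 structures for 5 regions;
a custom-mask escape hatch exists since alternative spaces are equally
admissible), scores each structure by Bayesian model reduction of the
group belief (switched-off connections get reduced prior variance 1e−6
about zero — not exact zero, for numerical stability), normalizes with
log-sum-exp, and returns KL(posterior ‖ uniform) ∈ [0, ln M]. Group-level
BMR pruning of redundant parameters is deliberately not applied anywhere:
the network structure may genuinely differ between conditions, and a
compromise model would contaminate both datasets' summaries. Differences
are reported as best-minus-worst with the conventional nats labels
(1.1 / 3 / 5).

## What the synthetic validation shows — and does not

On 20-subject cohorts at the default conditions (207 s runs, task
coupling 2× rest plus block input, matched noise and between-subject
variability), the pipeline consistently (10/10 seeds in our runs) assigns
higher information gain over parameters to the task-like dataset, with
margins of ~10–25 nats — the qualitative signature that stronger evoked
coupling yields more informative data, driven by the parameter means
rather than the precisions.

Parameter *certainty*, by contrast, systematically favors the rest-like
dataset by ~1–6 nats under these conditions. This is a real property of
the estimation problem, not an artifact: per-subject estimation scatter
scales with coupling strength (relative error is roughly constant, so a
2×-coupling cohort scatters about twice as much in absolute Hz), the
estimated between-subject covariance tracks that scatter, and the
certainty difference is `~(P/2)·ln` of the scatter-variance ratio over
P = 25 parameters. Near-equal certainties would require per-subject
estimation error well below the 0.0625 Hz between-subject sd, which
~300-sample runs cannot deliver. On real data with similar coupling
scales across conditions this term largely cancels, which is why
empirical rest/task comparisons can show negligible certainty differences
alongside very strong information-gain differences; a synthetic design
that doubles the coupling should be expected to show a certainty gap.

Other limitations of the generator: linear neural dynamics and linear
haemodynamics (no saturation, no balloon-model nonlinearity), no
physiological noise structure beyond power laws, no voxel level (regional
timeseries only), and a forward model that exactly matches the simulator
— real-data misspecification (haemodynamic variability across regions,
non-stationarity) is not represented, so passing tests certify the
statistical machinery, not robustness to misspecification.

## Problem sizes used in the test-suite

Validation runs are sized for a single CPU: recovery tests use 3-region
subjects with 10-minute runs; the rest/task comparison uses 5 regions ×
20 subjects × 10 seeds at the default 207 s run length; pure-noise
shrinkage uses 80-minute windows (the regime where the spectral estimate
is consistent enough that shrinkage is identifiable); end-to-end pipeline
checks use 2–3 subjects with shortened runs.
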