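# Methods

## Model

The package simulates and fits discrete-time recurrent spiking networks of
Bernoulli-GLM neurons.  With `S[i, t] ∈ {0, 1}` the spike of neuron `i` in
10 ms bin `t`,

    P(S[i,t] = 1 | past) = σ(U[i,t]),
    U[·,t] = W S[·,t−1] + b + G X[·,t],

where `σ` is the logistic function, `W` the synaptic weight matrix (its
diagonal models post-spike self-effects), `b` per-neuron biases, and `G X`
an optional stimulus drive.  Only one history lag is modelled; multi-lag
filters, multi-spike bins and conductance-based dynamics are out of scope.

A mismatched stochastic leaky-integrate-and-fire simulator
(`netsim.simulate_lif`) drives the same input `U` through a leaky voltage
with additive Gaussian noise, threshold 0.5, and a post-spike reset that
enforces a one-bin absolute refractory period.  Its decay factor is
`γ = exp(−Δt/τ_m)` with `τ_m = 20 ms` (γ ≈ 0.607 at 10 ms bins); the
membrane timescale is specified as a time constant because a per-bin decay
factor must be dimensionless.

## Expected-loglikelihood (ELL) inference

The exact GLM loglikelihood sums over all T bins and cannot be evaluated
when spikes are unobserved.  The ELL route replaces per-bin terms with their
expectation under a Gaussian approximation of the input `U` (justified by a
central-limit argument across the N presynaptic terms), then profiles out
`b`.  The result depends on the data only through the mean spike
probabilities `m`, the lag-0 covariance `Σ⁰` and the lag-1 covariance `Σ¹`:

    max_b ln P(S|W,b) ≈ T Σ_i [ Σ_j W_ij Σ¹_ij − h(m_i) κ_i ],
    κ_i = sqrt(1 + (π/8) W_i Σ⁰ W_iᵀ),

with `h` the Bernoulli entropy.  The Gaussian integral of the softplus uses
the probit-style approximation `∫ln(1+eˣ)N(x|μ,σ²)dx ≈ κ softplus(μ/κ)`,
`κ = sqrt(1+πσ²/8)`; it is about 9% high at μ = −2 (verified against a 10⁶-
sample Monte-Carlo oracle), which matters at low firing rates.

Two gradients are implemented.  `objective` is the exact gradient of the
approximated objective (validated against finite differences to 1e−8).
`adjusted` — the default — differentiates the exact loglikelihood first and
then applies the expectation approximation:

    ∂/∂W_ij ≈ T ( Σ¹_ij + m_i m_j − m_j σ((μ_i + c_ij/m_j)/κ_i) ),
    c = W Σ⁰,  μ_i = κ_i logit(m_i)  (bias at its profile optimum).

The conditional-mean step uses E[U_i | S_j=1] = μ_i + Cov(U_i, S_j)/m_j.
On a 4-neuron network at ~3 Hz the adjusted gradient matches a 10⁶-bin
Monte-Carlo estimate of the exact expected gradient to within a fraction of
one Monte-Carlo standard error, while the objective-mode gradient is tens of
standard errors off — hence the default.  At high per-bin rates the two
modes nearly coincide.

Biases are recovered in closed form: `b_i = κ_i logit(m_i) − Σ_k W_ik m_k`.

### Optimization

The MAP problem `min −ELL/T + λ‖W_offdiag‖₁` decomposes over rows of `W` and
is solved by FISTA with soft-thresholding, per-row constant steps `1/L_i`
(`L_i` from the exact top eigenvalue of `Σ⁰`; a per-mode analytic bound
multiplies it), monotone restart in objective mode and gradient-map restart
in adjusted mode (the adjusted direction is not the gradient of the
surrogate, so the surrogate value is not a valid Lyapunov function for it).
Convergence is declared when the relative objective change falls below 1e−9
(objective mode) or the relative iterate change below 1e−7; the cap is
20 000 iterations.  Each iteration costs O(N³) regardless of T — the raster
is touched exactly once, during moment accumulation.

Two numerical policies deserve note:

* **Box bound (|W| ≤ 8).**  The profile surrogate is *unbounded below*
  along directions where the entropy curvature `h(m)κ` is weaker than the
  linear `Σ¹` term — a real feature of the approximation at low rates, most
  visible on the unpenalized diagonal.  All iterates are clipped to a box
  far outside the physiological weight range; the prox of L1 + box is still
  exact, so this only rules out runaway solutions.
* **Non-PSD `Σ⁰`.**  Under partial observation the per-entry-normalized
  covariance estimate need not be PSD.  By default each row quadratic form
  is clipped at zero; an eigenvalue-clipping projection of `Σ⁰` is available
  (`psd_policy="eigclip"`).

λ is matched to a target sparsity by bisection on log λ over
`[1e−6, max|Σ¹|]` (40 steps, ±2% relative tolerance, warm-started fits),
relying on the empirically verified monotonicity of the L1 path.

Never-co-observed moment entries are flagged by the moment estimator (NaN +
per-entry counts), entered into the objective as 0, and the corresponding
weights constrained to 0 with a warning — identifiability failures are
surfaced, never silently imputed.

## Observation schemes

Five mask generators: `fixed` (same subset always), `serial` (contiguous
block advancing cyclically; pairs farther than the block size are never
co-observed), `fully_random` (i.i.d. Bernoulli), `random_blocks` (random
subset held for a dwell period), and `double_serial` — two nested
lexicographic scanners: a fast scanner sweeps the population holding each
position `dwell` bins, a slow scanner advances one position per completed
fast sweep.  The nested construction guarantees that every ordered pair is
co-observed (at lag 0 and lag 1) within `N² · dwell · dwell_b` bins, for any
N.  (A "continuous two-scanner" variant with coprime dwell periods was
evaluated first and rejected: the mod-N windows of the two scanners need
not intersect for every pair, which leaves a fraction of pairs permanently
unobserved for many (N, dwell) combinations.)

## Moment estimation with missing data

Means and lag-0/1 covariances are estimated by ignoring unobserved entries
and renormalizing each sum by its own observation count (per-entry counts
kept).  Lag-1 averages use t = 2..T with no circular wrap; covariance
normalization is 1/valid-pair-count (the 1/T-vs-1/(T−1) distinction is
O(1/T) and unresolvable from the source).  Accumulation is chunked
streaming, verified to match the whole-matrix computation to 1e−10.

## Synthetic networks: what the generator emulates

`NetworkGenConfig` draws sparse Dale's-law networks: 20% inhibitory neurons,
off-diagonal density `p_conn` = 0.16, log-normal weight magnitudes
(excitatory median 0.178, σ_ln = 0.8 — most excitatory weights weak),
inhibitory weights 3× stronger at the median, fixed −1 self-weights.  The
default bias (−3.45 ± 0.3) puts a 50-neuron network near 3 Hz, the regime
of the fluorescence experiment.

The quantitative recovery benchmark (`benchmark_gen_config`) uses the same
weight statistics with biases drawn from N(−0.5, 0.1) — a high per-bin-rate
regime (m ≈ 0.35) in which second-order spike statistics remain informative
at very low observation probabilities.  This choice is deliberate: at 3 Hz
and p_obs = 0.04 each covariance entry accrues only ~3 observed spike
pairs over 5.5 hours (T p² m² counting), and no estimator can recover the
weights from that; the reference common-input experiments use the same
N(−0.5, 0.1) bias law.  With these settings the 5.5-hour, p_obs = 0.04
double-serial benchmark yields C ≈ 0.85–0.92 and 2–5 genuine sign flips
among ~450 nonzero weights (seeds 0–4).  Weight magnitudes are capped at 3:
the log-normal tails otherwise occasionally produce single synapses strong
enough to saturate the spiking nonlinearity, for which the profile
surrogate is unbounded even at noise-free moments (see the box bound), and
the reference weight distributions concentrate well below that range.

What the generator does *not* emulate: spatial structure (connection
probability independent of distance), synaptic transmission delays beyond
one bin, non-stationarity, and measured cortical weight distributions
beyond the log-normal shape.  Passing tests demonstrate correctness of the
estimator under the model's own assumptions, not performance on real
recordings.

The common-input demonstration network places 16 mutually unconnected
neurons under dense excitatory drive (density 0.5, 2× weight scale) from 34
hidden neurons with positive self-weights (+1.5).  The self-excitation
makes hidden activity autocorrelated — that is what converts shared input
into spurious *lagged* correlations, the quantity a GLM fit mistakes for
connectivity.  With temporally white hidden drivers the bias would be
nearly invisible in a lag-1 model.  Biases are compensated so block and
hidden rates sit near 0.4/bin.

## Fluorescence model and spike inference

Calcium follows an AR(1) driven by spikes, `c_t = d c_{t−1} + s_t` with
`d = exp(−Δt/τ)` and τ = 400 ms (GCaMP6f-like); fluorescence adds baseline,
unit-spike amplitude, and Gaussian noise of sd `snr × amplitude`.  "snr" is
a noise scale — 0.2 is the low-noise and 0.4 the high-noise regime.  Spike
inference is matched-kernel nonnegative deconvolution: a pool-adjacent-
violators pass solves `min ‖c−y‖²` s.t. `c_t ≥ d c_{t−1}`, `c ≥ 0`, and the
implied spike signal is thresholded at half the unit response.  It is
deterministic, training-free, and exact on noiseless isolated transients.

## Baselines

* `full_loglik` / `fit_map_full`: exact GLM likelihood (all T bins; the bin
  before the raster is taken silent) and its L1-MAP via the same FISTA,
  O(N²T) per iteration; full observation only.
* `gibbs_impute`: systematic-scan single-site Gibbs over missing entries in
  (t, i) order; each conditional multiplies the emission at `t` by the
  likelihoods of all bin-(t+1) spikes it feeds into (sparse columns of W).
  Default 31 sweeps = 30 burn-in + 1 retained sample.  Validated against
  exact enumeration on 2-neuron instances (χ², α = 0.001).
* `em_step`: Monte-Carlo EM — impute at the current estimate, recompute
  moments on the completed raster, refit with the ELL MAP.

## Experiment sizes in the test suite

The shipped tests scale the reference experiments to desk sizes chosen once:
recovery benchmark 5.5 h (T = 1.98·10⁶) at 3 seeds in the test and 5 seeds
in `scripts/acceptance.py`; common-input at T = 10⁶ (10 seeds) with the
shrink-with-T check at T = 10⁵; EM comparison at T = 10⁵ (2 seeds);
scaling collapse with (p_obs = 0.2, T = 2·10⁵) vs (p_obs = 0.1, T = 8·10⁵).
The N = 1000 experiment is provided as `scripts/large_network.py` and is not
part of the suite.

## Known limitations

* The profile surrogate can be unbounded at low rates (see box bound); the
  diagonal weights are the least reliable entries, consistent with the
  LIF-mismatch behaviour where the reset inflates apparent self-inhibition.
* The sparsity-matched λ is global; per-row matching is not implemented.
* `quality_metrics` includes the diagonal in C by default
  (`include_diagonal=False` gives the off-diagonal variant).
* Serial schemes leave specific pairs unidentifiable by design; the package
  flags them and constrains the matching weights to zero rather than
  completing the covariance by low-rank methods.
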