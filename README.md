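# shotgun-conn

Inference of synaptic connectivity in recurrent spiking networks from
heavily sub-sampled activity — the "shotgun" experimental design, in which
many overlapping subsets of a network are observed serially, so that over a
long experiment every neuron pair is eventually co-observed even though only
a small fraction of the population is imaged in any time bin.

It is written for computational neuroscientists who want to (a) simulate
spiking networks and partial-observation schemes, (b) estimate the synaptic
weight matrix from the resulting sub-sampled rasters or from calcium
fluorescence, and (c) quantify when such estimation succeeds.

## The method

Activity follows a Bernoulli-GLM network: neuron `i` spikes in 10 ms bin `t`
with probability `σ(U_{i,t})`, where `U_{·,t} = W S_{·,t−1} + b + G X_{·,t}`.
The exact likelihood cannot be evaluated with missing spikes.  The package
implements expected-loglikelihood (ELL) inference: a Gaussian (CLT)
approximation of the input turns the profile loglikelihood into

    max_b ln P(S|W,b) ≈ T Σ_i [ Σ_j W_ij Σ¹_ij − h(m_i) √(1 + (π/8) W_i Σ⁰ W_iᵀ) ],

which depends on the data only through the mean rates `m` and the lag-0/1
spike covariances `Σ⁰, Σ¹`.  Those moments are estimable under partial
observation by simply ignoring missing entries and renormalizing by
per-entry observation counts.  The L1-regularized MAP estimate is computed
by row-parallel FISTA in O(N³) per iteration — the raster is touched once,
at moment time — with λ optionally matched to a target sparsity.  Five
observation schemes (fixed, serial, fully random, random blocks, double
serial scanning), identifiability diagnostics, exact-likelihood and
Monte-Carlo-EM baselines, a GCaMP6f-like fluorescence forward model with
matched nonnegative deconvolution, and the quantitative evaluation harnesses
are included.

## Worked example

```python
import shotgun_conn as sc
from shotgun_conn.ell import offdiag_nonzero_fraction

# a 50-neuron sparse Dale's-law network in the high-activity regime
params = sc.generate_network(sc.benchmark_gen_config(N=50, seed=1))
T = sc.hours_to_bins(5.5)                        # 1_980_000 ten-ms bins
spikes = sc.simulate_glm(params, T, seed=2)

# double serial scanning: only 2 of 50 neurons observed per bin
mask = sc.make_mask(sc.SchemeConfig(scheme="double_serial", seed=3),
                    N=50, T=T, p_obs=0.04)
print(sc.check_identifiability(mask).fully_identifiable)   # True

moments = sc.estimate_moments(spikes, mask)
lam, fit = sc.select_lambda(moments, T,
                            offdiag_nonzero_fraction(params.W))
report = sc.quality_metrics(params.W, fit.W_hat)
print(f"C={report.C:.3f}  sign flips={report.n_sign_flips}"
      f"/{report.n_true_nonzero}")
```

Output:

    True
    C=0.920  sign flips=3/441

Even with 96% of the network unobserved in every bin, the weight matrix is
recovered with correlation ≈ 0.9 against ground truth, and only 3 of the
441 true connections come out with the wrong sign — because the double
serial scan covers *every* neuron pair over the 5.5-hour experiment, the
common-input bias that plagues fixed-subset recordings vanishes.

The same pipeline is scriptable from the shell:

    shotgun simulate --n 50 --t 100000 --out raster.h5
    shotgun observe --raster raster.h5 --scheme double_serial --p-obs 0.2 --out masked.h5
    shotgun moments --raster masked.h5 --out moments.h5
    shotgun fit --moments moments.h5 --match-sparsity 0.16 --out result.h5

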