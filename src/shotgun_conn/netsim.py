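"""Ground-truth network generation and spiking-network simulators.

The generative model is a discrete-time recurrent network of ``N`` Bernoulli-GLM
neurons.  At every time bin ``t`` each neuron ``i`` spikes with probability

    P(S_{i,t} = 1 | U_{i,t}) = logistic(U_{i,t}),
    U_{., t} = W S_{., t-1} + b + G X_{., t},

where ``W`` is the synaptic weight matrix (diagonal entries model post-spike
self-effects such as refractoriness), ``b`` the per-neuron biases and ``G`` an
optional gain on an external stimulus ``X``.  A mismatched stochastic
leaky-integrate-and-fire (LIF) simulator driven by the same ``U`` is provided to
probe robustness to model error.

Time bins are 10 ms throughout; experiment durations quoted in hours convert at
100 bins per second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

__all__ = [
    "BIN_WIDTH_S",
    "BINS_PER_HOUR",
    "NetworkParams",
    "NetworkGenConfig",
    "SpikeMatrix",
    "StimulusMatrix",
    "LIFConfig",
    "logistic",
    "hours_to_bins",
    "generate_network",
    "simulate_glm",
    "simulate_lif",
]

#: Width of a simulation time bin, in seconds.
BIN_WIDTH_S = 0.01

#: Number of time bins in one hour of experiment.
BINS_PER_HOUR = int(round(3600.0 / BIN_WIDTH_S))

#: Bins simulated and discarded before recording starts, to forget the
#: (all-zero) initial state.
BURN_IN_BINS = 1000


def hours_to_bins(hours: float) -> int:
    """Convert an experiment duration in hours to time bins (10 ms bins)."""
    return int(round(hours * BINS_PER_HOUR))


def logistic(u):
    """Numerically stable logistic function 1 / (1 + exp(-u)).

    Accepts scalars or arrays; ±inf map to 1/0.  NaN input raises.
    """
    u = np.asarray(u, dtype=float)
    if np.isnan(u).any():
        raise ValueError("logistic: NaN input")
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class NetworkParams:
    """Ground-truth generative parameters of a network.

    Attributes
    ----------
    W : (N, N) float array
        Synaptic weights; ``W[i, j]`` is the influence of a spike of neuron
        ``j`` at ``t-1`` on the input of neuron ``i`` at ``t``.  Diagonal
        entries are post-spike self-effects.
    b : (N,) float array
        Per-neuron biases (set the baseline firing probability).
    G : (N, D) float array or None
        Stimulus gain; None when the network has no external input.
    """

    W: np.ndarray
    b: np.ndarray
    G: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if not np.isfinite(self.W).all():
            raise ValueError("W must be finite")
        if self.b.shape != (self.W.shape[0],):
            raise ValueError("b shape inconsistent with W")
        if self.G is not None:
            self.G = np.asarray(self.G, dtype=float)
            if self.G.ndim != 2 or self.G.shape[0] != self.W.shape[0]:
                raise ValueError("G shape inconsistent with W")

    @property
    def N(self) -> int:
        return self.W.shape[0]

    @property
    def D(self) -> int:
        return 0 if self.G is None else self.G.shape[1]


@dataclass
class NetworkGenConfig:
    """Configuration of the random network generator.

    Defaults emulate a sparse cortical-like network: Dale's law with 20%
    inhibitory neurons, right-skewed (log-normal) excitatory weight magnitudes
    with median 0.178 so most excitatory weights are weak, inhibitory weights
    three times stronger at the median, negative diagonal (self-suppression),
    and biases chosen so a 50-neuron network fires near 3 Hz in 10 ms bins.
    """

    N: int = 50
    p_conn: float = 0.16          # off-diagonal connection probability
    fraction_inhibitory: float = 0.2
    exc_median: float = 0.178     # median excitatory weight magnitude
    exc_sigma: float = 0.8        # log-normal sigma of weight magnitudes
    inh_scale: float = 3.0        # inhibitory median = inh_scale * exc_median
    max_weight: float = 3.0       # magnitude cap on the log-normal tails
    diag_weight: float = -1.0     # fixed self-suppression weight
    bias_mean: float = -3.45
    bias_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_conn <= 1.0):
            raise ValueError("p_conn must be in (0, 1]")
        if not (0.0 <= self.fraction_inhibitory <= 1.0):
            raise ValueError("fraction_inhibitory must be in [0, 1]")

    @property
    def p_0(self) -> float:
        """Connection-sparsity parameter (proportional to ``p_conn``)."""
        return self.p_conn


@dataclass
class SpikeMatrix:
    """A binary spike raster.

    ``S[i, t]`` is 1 when neuron ``i`` spiked in bin ``t``.  ``n_stimulus``
    marks trailing rows that hold real-valued stimulus channels appended by
    :func:`shotgun_conn.ell.augment_stimulus`; the binary invariant applies to
    the spike rows only.
    """

    S: np.ndarray
    bin_width: float = BIN_WIDTH_S
    n_stimulus: int = 0

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S)
        if self.S.ndim != 2 or self.S.shape[1] < 1:
            raise ValueError("S must be N x T with T >= 1")
        n_spk = self.S.shape[0] - self.n_stimulus
        spk = self.S[:n_spk]
        if not np.isin(spk, (0, 1)).all():
            raise ValueError("spike entries must be 0/1")

    @property
    def N(self) -> int:
        return self.S.shape[0]

    @property
    def T(self) -> int:
        return self.S.shape[1]


@dataclass
class StimulusMatrix:
    """External stimulus, a real D x T matrix."""

    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be D x T")
        if not np.isfinite(self.X).all():
            raise ValueError("X must be finite")

    @property
    def D(self) -> int:
        return self.X.shape[0]

    @property
    def T(self) -> int:
        return self.X.shape[1]


@dataclass
class LIFConfig:
    """Discrete-time stochastic LIF parameters.

    ``gamma`` is the per-bin membrane decay factor, exp(-Δt/τ_m) with a 20 ms
    integration timescale by default (≈0.6065 at 10 ms bins).  ``noise_sd`` is
    the standard deviation of the per-bin Gaussian voltage noise, and a spike
    is emitted whenever the voltage crosses ``threshold``.
    """

    gamma: float = float(np.exp(-BIN_WIDTH_S / 0.020))
    noise_sd: float = 1.0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError("gamma must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# Network generation
# ---------------------------------------------------------------------------


def benchmark_gen_config(N: int = 50, seed: int = 0) -> NetworkGenConfig:
    """Generator settings of the quantitative recovery benchmark.

    Same sparse Dale's-law weight statistics as the defaults (excitatory
    median 0.178, log-normal spread 0.8, inhibitory three times stronger) but
    in the high per-bin-activity regime b ~ N(-0.5, 0.1) used by the
    common-input and recovery experiments, where second-order spike
    statistics are informative even at very low observation probabilities.
    """
    return NetworkGenConfig(N=N, bias_mean=-0.5, bias_sd=0.1, seed=seed)


def generate_network(cfg: NetworkGenConfig) -> NetworkParams:
    """Draw a random sparse Dale's-law network.

    Each presynaptic neuron (column of ``W``) is excitatory or inhibitory;
    off-diagonal entries are nonzero independently with probability
    ``cfg.p_conn``; magnitudes are log-normal, inhibitory ones
    ``cfg.inh_scale`` times stronger at the median.  Deterministic under
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    N = cfg.N
    n_inh = int(round(cfg.fraction_inhibitory * N))
    # presynaptic sign per column; inhibitory neurons are the last n_inh
    sign = np.ones(N)
    if n_inh > 0:
        sign[N - n_inh:] = -1.0

    conn = rng.random((N, N)) < cfg.p_conn
    np.fill_diagonal(conn, False)
    mag = rng.lognormal(mean=np.log(cfg.exc_median), sigma=cfg.exc_sigma, size=(N, N))
    mag = mag * np.where(sign[None, :] < 0, cfg.inh_scale, 1.0)
    # cap the heavy log-normal tails: single synapses beyond a few units
    # saturate the spiking nonlinearity and are not biophysically meaningful
    mag = np.minimum(mag, cfg.max_weight)
    W = np.where(conn, mag * sign[None, :], 0.0)
    np.fill_diagonal(W, cfg.diag_weight)

    b = rng.normal(cfg.bias_mean, cfg.bias_sd, size=N)
    return NetworkParams(W=W, b=b)


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------

_CHUNK = 1 << 16  # bins per random-draw chunk


@njit(cache=True)
def _glm_chunk(W, b, u_ext, s_prev, unif, S_out):  # pragma: no cover - numba
    N = W.shape[0]
    Tc = S_out.shape[1]
    for t in range(Tc):
        for i in range(N):
            u = b[i] + u_ext[i, t]
            for j in range(N):
                if s_prev[j]:
                    u += W[i, j]
            if u >= 0.0:
                p = 1.0 / (1.0 + np.exp(-u))
            else:
                eu = np.exp(u)
                p = eu / (1.0 + eu)
            S_out[i, t] = 1 if unif[i, t] < p else 0
        for i in range(N):
            s_prev[i] = S_out[i, t]


@njit(cache=True)
def _lif_chunk(W, b, u_ext, gamma, threshold, s_prev, v_prev, noise, S_out):  # pragma: no cover
    N = W.shape[0]
    Tc = S_out.shape[1]
    for t in range(Tc):
        for i in range(N):
            u = b[i] + u_ext[i, t]
            for j in range(N):
                if s_prev[j]:
                    u += W[i, j]
            if s_prev[i]:
                v = 0.0  # reset: voltage gated to zero after a spike
            else:
                v = gamma * v_prev[i] + (1.0 - gamma) * u + noise[i, t]
            S_out[i, t] = 1 if v > threshold else 0
            v_prev[i] = v
        for i in range(N):
            s_prev[i] = S_out[i, t]


def _run_chunked(params, T, stimulus, seed, step):
    """Shared chunked driver: burn-in then T recorded bins."""
    N = params.N
    if T < 1:
        raise ValueError("T must be >= 1")
    if params.G is not None:
        if stimulus is None:
            raise ValueError("network has stimulus gain G but no stimulus given")
        if stimulus.D != params.D or stimulus.T != T:
            raise ValueError("stimulus shape mismatch")
    rng = np.random.default_rng(seed)
    S = np.zeros((N, T), dtype=np.uint8)
    s_prev = np.zeros(N, dtype=np.uint8)
    state = {"v_prev": np.zeros(N)}
    total = BURN_IN_BINS + T
    done = 0
    while done < total:
        Tc = min(_CHUNK, total - done)
        rec_lo = max(done, BURN_IN_BINS)
        # external input for this chunk (zero during burn-in)
        u_ext = np.zeros((N, Tc))
        if params.G is not None:
            for k in range(Tc):
                tt = done + k
                if tt >= BURN_IN_BINS:
                    u_ext[:, k] = params.G @ stimulus.X[:, tt - BURN_IN_BINS]
        S_out = np.empty((N, Tc), dtype=np.uint8)
        step(u_ext, s_prev, rng, state, S_out)
        if rec_lo < done + Tc:
            lo = rec_lo - done
            S[:, rec_lo - BURN_IN_BINS: done + Tc - BURN_IN_BINS] = S_out[:, lo:]
        done += Tc
    return SpikeMatrix(S=S)


def simulate_glm(
    params: NetworkParams,
    T: int,
    stimulus: Optional[StimulusMatrix] = None,
    seed: int = 0,
) -> SpikeMatrix:
    """Simulate ``T`` bins of the logistic GLM network.

    The initial state is all-zeros and a 1000-bin burn-in is discarded before
    recording, so the returned raster is approximately stationary.  Output is
    bitwise reproducible for identical ``(params, T, seed)``.
    """
    W = np.ascontiguousarray(params.W)
    b = np.ascontiguousarray(params.b)

    def step(u_ext, s_prev, rng, state, S_out):
        unif = rng.random((params.N, S_out.shape[1]))
        _glm_chunk(W, b, u_ext, s_prev, unif, S_out)

    return _run_chunked(params, T, stimulus, seed, step)


def simulate_lif(
    params: NetworkParams,
    T: int,
    cfg: LIFConfig = None,
    seed: int = 0,
    stimulus: Optional[StimulusMatrix] = None,
) -> SpikeMatrix:
    """Simulate the mismatched stochastic LIF network.

    Voltage update: V_{i,t} = (γ V_{i,t-1} + (1-γ) U_{i,t} + ε_{i,t}) gated to
    zero in the bin after a spike of neuron ``i``; a spike is emitted when
    V_{i,t} crosses the threshold.  The post-spike gating enforces a one-bin
    absolute refractory period (the reset voltage 0 is below the 0.5
    threshold), so no row ever contains two consecutive spikes.
    """
    if cfg is None:
        cfg = LIFConfig()
    W = np.ascontiguousarray(params.W)
    b = np.ascontiguousarray(params.b)

    def step(u_ext, s_prev, rng, state, S_out):
        Tc = S_out.shape[1]
        noise = (
            rng.normal(0.0, cfg.noise_sd, size=(params.N, Tc))
            if cfg.noise_sd > 0
            else np.zeros((params.N, Tc))
        )
        _lif_chunk(W, b, u_ext, cfg.gamma, cfg.threshold,
                   s_prev, state["v_prev"], noise, S_out)

    return _run_chunked(params, T, stimulus, seed, step)
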