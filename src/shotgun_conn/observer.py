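"""Observation masks for sub-sampled recordings, and identifiability checks.

A recording observes only a subset of neurons in each time bin, encoded as a
binary mask ``O`` of the same shape as the spike raster (``O[i, t] = 1`` when
neuron ``i`` was observed in bin ``t``).  Five scanning schemes are provided:

* ``fixed`` — always observe the same subset (some neurons never observed);
* ``serial`` — a contiguous block sweeps cyclically over the population
  (some neuron *pairs* never co-observed);
* ``fully_random`` — each entry observed i.i.d. with probability ``p_obs``;
* ``random_blocks`` — a random subset is held for a dwell period, then redrawn;
* ``double_serial`` — two nested serial scanners (a fast sweep inside a slow
  one), which eventually co-observes every neuron pair.

Which first/second moments of the spike process are estimable depends only on
the mask's single-neuron and pairwise coverage; :func:`check_identifiability`
reports neurons and pairs with zero coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SCHEMES",
    "ObservationMask",
    "SchemeConfig",
    "IdentifiabilityReport",
    "make_mask",
    "pair_coverage",
    "check_identifiability",
]

SCHEMES = ("fixed", "serial", "fully_random", "random_blocks", "double_serial")


@dataclass
class ObservationMask:
    """A binary N x T observation matrix with its generating scheme."""

    O: np.ndarray
    scheme: str = "custom"
    p_obs_target: float = 1.0

    def __post_init__(self) -> None:
        self.O = np.asarray(self.O)
        if self.O.ndim != 2:
            raise ValueError("O must be N x T")
        if not np.isin(self.O, (0, 1)).all():
            raise ValueError("mask entries must be 0/1")

    @property
    def N(self) -> int:
        return self.O.shape[0]

    @property
    def T(self) -> int:
        return self.O.shape[1]

    @property
    def p_obs_empirical(self) -> float:
        return float(self.O.mean())


@dataclass
class SchemeConfig:
    """Scanning-scheme parameters.

    ``dwell`` is the number of bins a block is held before the scanner
    advances (serial) or the subset is redrawn (random_blocks).  For
    ``double_serial`` the two scanners are nested lexicographically: the fast
    scanner holds each position for ``dwell`` bins and sweeps the whole
    population, while the slow scanner advances one position only after
    ``dwell_b`` complete fast sweeps — so every ordered neuron pair is
    co-observed within ``N² · dwell · dwell_b`` bins, at lag 0 and lag 1.
    """

    scheme: str = "double_serial"
    dwell: int = 10
    dwell_b: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.dwell < 1 or self.dwell_b < 1:
            raise ValueError("dwell times must be >= 1")


def _serial_starts(T: int, dwell: int) -> np.ndarray:
    """Scanner start position per bin: advance one neuron every ``dwell`` bins."""
    return np.arange(T) // dwell


def _block_rows(starts: np.ndarray, k: int, N: int, T: int) -> np.ndarray:
    """Binary mask with a contiguous block of ``k`` rows (wraparound) per bin."""
    O = np.zeros((N, T), dtype=np.uint8)
    rows = (starts[None, :] + np.arange(k)[:, None]) % N  # k x T
    O[rows, np.arange(T)[None, :]] = 1
    return O


def make_mask(cfg: SchemeConfig, N: int, T: int, p_obs: float) -> ObservationMask:
    """Generate an observation mask for ``N`` neurons over ``T`` bins.

    Deterministic schemes (fixed, serial, double_serial) observe exactly
    ``ceil(p_obs * N)`` neurons per bin; ``random_blocks`` likewise;
    ``fully_random`` observes each entry independently with probability
    ``p_obs``.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if p_obs * N < 1:
        raise ValueError("p_obs * N must be >= 1 (at least one neuron per bin)")
    k = int(np.ceil(p_obs * N))
    rng = np.random.default_rng(cfg.seed)

    if cfg.scheme == "fixed":
        O = np.zeros((N, T), dtype=np.uint8)
        O[:k, :] = 1
    elif cfg.scheme == "serial":
        O = _block_rows(_serial_starts(T, cfg.dwell) % N, k, N, T)
    elif cfg.scheme == "fully_random":
        O = (rng.random((N, T)) < p_obs).astype(np.uint8)
    elif cfg.scheme == "random_blocks":
        n_blocks = (T + cfg.dwell - 1) // cfg.dwell
        O = np.zeros((N, T), dtype=np.uint8)
        for bidx in range(n_blocks):
            rows = rng.choice(N, size=k, replace=False)
            lo = bidx * cfg.dwell
            O[rows, lo: min(lo + cfg.dwell, T)] = 1
    else:  # double_serial: nested lexicographic two-scanner scan
        k_a = max(1, k // 2)
        k_b = k - k_a
        n_pos = (N + k_a - 1) // k_a  # fast-scanner positions per sweep
        starts_a = ((np.arange(T) // cfg.dwell) % n_pos) * k_a % N
        O = _block_rows(starts_a, k_a, N, T)
        if k_b > 0:
            sweep_len = cfg.dwell * n_pos * cfg.dwell_b
            starts_b = ((np.arange(T) // sweep_len) * k_b + N // 2) % N
            Ob = _block_rows(starts_b, k_b, N, T)
            O = np.maximum(O, Ob)
    return ObservationMask(O=O, scheme=cfg.scheme, p_obs_target=p_obs)


def pair_coverage(mask: ObservationMask, lag: int = 1) -> np.ndarray:
    """Empirical frequency of co-observed neuron pairs at lag 0 or 1.

    Entry ``(i, j)`` is the fraction of valid bins with ``O[i, t] = 1`` and
    ``O[j, t - lag] = 1``; lag-1 uses t = 2..T (no circular wrap).
    """
    if lag not in (0, 1):
        raise ValueError("lag must be 0 or 1")
    O = mask.O.astype(np.float64)
    if mask.T <= lag:
        raise ValueError("T must exceed lag")
    if lag == 0:
        return (O @ O.T) / mask.T
    return (O[:, 1:] @ O[:, :-1].T) / (mask.T - 1)


@dataclass
class IdentifiabilityReport:
    """Which moments a mask renders estimable.

    ``unobserved_neurons`` lists neurons with zero observation count (their
    mean rate is unidentifiable); ``unobserved_pairs_lag0/1`` list index pairs
    never jointly observed (their covariance entry is unidentifiable).
    """

    unobserved_neurons: np.ndarray
    unobserved_pairs_lag0: np.ndarray  # (n, 2) int array
    unobserved_pairs_lag1: np.ndarray
    fully_identifiable: bool

    def __str__(self) -> str:
        return (
            f"IdentifiabilityReport(fully_identifiable={self.fully_identifiable}, "
            f"unobserved_neurons={len(self.unobserved_neurons)}, "
            f"unobserved_pairs_lag0={len(self.unobserved_pairs_lag0)}, "
            f"unobserved_pairs_lag1={len(self.unobserved_pairs_lag1)})"
        )


def check_identifiability(mask: ObservationMask) -> IdentifiabilityReport:
    """Diagnose zero-coverage neurons and pairs for the given mask."""
    counts = mask.O.sum(axis=1)
    neurons = np.flatnonzero(counts == 0)
    cov0 = pair_coverage(mask, lag=0)
    pairs0 = np.argwhere(cov0 == 0)
    if mask.T > 1:
        cov1 = pair_coverage(mask, lag=1)
        pairs1 = np.argwhere(cov1 == 0)
    else:
        pairs1 = np.empty((0, 2), dtype=int)
    ok = len(neurons) == 0 and len(pairs0) == 0 and len(pairs1) == 0
    return IdentifiabilityReport(
        unobserved_neurons=neurons,
        unobserved_pairs_lag0=pairs0,
        unobserved_pairs_lag1=pairs1,
        fully_identifiable=ok,
    )
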