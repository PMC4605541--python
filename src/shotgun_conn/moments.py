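"""Approximate sufficient statistics: spike means and lag-0/lag-1 covariances.

The expected-loglikelihood objective depends on the raster only through

    m_i        = <S_{i,t}>_T                      (mean spike probability)
    Sigma0_ij  = <S_{i,t} S_{j,t}>_T   - m_i m_j  (lag-0 covariance)
    Sigma1_ij  = <S_{i,t} S_{j,t-1}>_T - m_i m_j  (lag-1 covariance)

Under partial observation these are estimated by simply ignoring unobserved
entries and renormalizing each empirical sum by its own observation count:

    m~_i       = <O S>_T / <O>_T
    Sigma~_ij  = <O_i O_j S_i S_j>_T / <O_i O_j>_T - m~_i m~_j

which is consistent whenever the mask is independent of the activity and every
neuron (resp. pair) is observed a growing number of times.  Entries whose
observation count is zero are NaN and flagged invalid rather than silently
zeroed — downstream policy decides how to handle them.

Accumulation is streaming (chunked over time), so rasters larger than memory
are supported; a one-pass accumulation equals the whole-matrix computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .netsim import SpikeMatrix
from .observer import ObservationMask

__all__ = ["MomentStats", "MomentAccumulator", "exact_moments", "estimate_moments"]


@dataclass
class MomentStats:
    """First/second spike moments with per-entry observation counts.

    ``count_m`` (N,), ``count0`` and ``count1`` (N, N) are the numbers of bins
    contributing to each estimate; entries with zero count hold NaN in the
    corresponding statistic and are reported by ``valid_*``.
    """

    m: np.ndarray
    Sigma0: np.ndarray
    Sigma1: np.ndarray
    count_m: np.ndarray
    count0: np.ndarray
    count1: np.ndarray
    T_effective: int

    @property
    def N(self) -> int:
        return self.m.shape[0]

    @property
    def valid_m(self) -> np.ndarray:
        return self.count_m > 0

    @property
    def valid0(self) -> np.ndarray:
        return self.count0 > 0

    @property
    def valid1(self) -> np.ndarray:
        return self.count1 > 0

    @property
    def fully_valid(self) -> bool:
        return bool(self.valid_m.all() and self.valid0.all() and self.valid1.all())


class MomentAccumulator:
    """One-pass accumulator of masked spike moments over time chunks.

    Feed consecutive time chunks of the raster and mask with :meth:`update`;
    lag-1 products across chunk boundaries are handled by carrying the last
    column.  :meth:`finalize` returns the :class:`MomentStats`.
    """

    def __init__(self, N: int):
        self.N = N
        self._sum_os = np.zeros(N)
        self._sum_o = np.zeros(N)
        self._P0 = np.zeros((N, N))
        self._C0 = np.zeros((N, N))
        self._P1 = np.zeros((N, N))
        self._C1 = np.zeros((N, N))
        self._T = 0
        self._last_os: Optional[np.ndarray] = None
        self._last_o: Optional[np.ndarray] = None

    def update(self, S_chunk: np.ndarray, O_chunk: np.ndarray) -> None:
        S = np.asarray(S_chunk, dtype=np.float64)
        O = np.asarray(O_chunk, dtype=np.float64)
        if S.shape != O.shape or S.shape[0] != self.N:
            raise ValueError("chunk shape mismatch")
        OS = O * S
        self._sum_os += OS.sum(axis=1)
        self._sum_o += O.sum(axis=1)
        self._P0 += OS @ OS.T
        self._C0 += O @ O.T
        if self._last_os is not None:
            OS_prev = np.concatenate([self._last_os[:, None], OS[:, :-1]], axis=1)
            O_prev = np.concatenate([self._last_o[:, None], O[:, :-1]], axis=1)
        else:
            OS_prev = OS[:, :-1]
            O_prev = O[:, :-1]
            OS = OS[:, 1:]
            O = O[:, 1:]
        self._P1 += OS @ OS_prev.T
        self._C1 += O @ O_prev.T
        self._last_os = np.asarray(S_chunk, dtype=np.float64)[:, -1] * np.asarray(
            O_chunk, dtype=np.float64
        )[:, -1]
        self._last_o = np.asarray(O_chunk, dtype=np.float64)[:, -1]
        self._T += S_chunk.shape[1]

    def finalize(self) -> MomentStats:
        if self._T < 2:
            raise ValueError("need at least 2 time bins for lag-1 moments")
        with np.errstate(divide="ignore", invalid="ignore"):
            m = np.where(self._sum_o > 0, self._sum_os / self._sum_o, np.nan)
            mm = np.outer(m, m)
            Sigma0 = np.where(self._C0 > 0, self._P0 / np.maximum(self._C0, 1), np.nan) - mm
            Sigma1 = np.where(self._C1 > 0, self._P1 / np.maximum(self._C1, 1), np.nan) - mm
        return MomentStats(
            m=m,
            Sigma0=Sigma0,
            Sigma1=Sigma1,
            count_m=self._sum_o.copy(),
            count0=self._C0.copy(),
            count1=self._C1.copy(),
            T_effective=self._T,
        )


def estimate_moments(
    spikes: SpikeMatrix,
    mask: ObservationMask,
    chunk: int = 1 << 16,
) -> MomentStats:
    """Estimate moments from a partially observed raster.

    With an all-ones mask the result is identical to :func:`exact_moments`
    (bitwise — both run through the same accumulator).
    """
    if spikes.S.shape != mask.O.shape:
        raise ValueError("spike raster and mask shapes differ")
    acc = MomentAccumulator(spikes.N)
    for lo in range(0, spikes.T, chunk):
        hi = min(lo + chunk, spikes.T)
        acc.update(spikes.S[:, lo:hi], mask.O[:, lo:hi])
    return acc.finalize()


def exact_moments(spikes: SpikeMatrix, chunk: int = 1 << 16) -> MomentStats:
    """Moments of a fully observed raster (all-ones mask)."""
    if spikes.T < 2:
        raise ValueError("need at least 2 time bins for lag-1 moments")
    ones = ObservationMask(O=np.ones_like(spikes.S, dtype=np.uint8), scheme="full")
    return estimate_moments(spikes, ones, chunk=chunk)
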