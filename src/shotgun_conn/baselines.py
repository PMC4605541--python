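"""Reference methods the ELL approach is compared against.

* exact GLM loglikelihood and its MAP fit on fully observed rasters;
* single-site Gibbs imputation of unobserved spikes given (W, b);
* Monte-Carlo EM: impute missing spikes at the current estimate, recompute
  moments on the completed raster, refit with the ELL method.

These are deliberately the "slow but exact" routes: the exact loglikelihood
touches the raster at every iteration (O(N² T) per gradient), and Gibbs
imputation costs O(connections) per missing entry per sweep.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from numba import njit

from . import ell as _ell
from .moments import exact_moments
from .netsim import SpikeMatrix, logistic
from .observer import ObservationMask

__all__ = ["full_loglik", "fit_map_full", "gibbs_impute", "em_step"]


def full_loglik(W: np.ndarray, b: np.ndarray, spikes: SpikeMatrix) -> float:
    """Exact GLM loglikelihood Σ_i Σ_t [S_it U_it − ln(1 + e^{U_it})].

    All T bins contribute; the bin preceding the raster is taken as silent
    (all-zero initial state), so U_{·,1} = b.
    """
    S = spikes.S.astype(float)
    S_prev = np.concatenate([np.zeros((spikes.N, 1)), S[:, :-1]], axis=1)
    U = W @ S_prev + np.asarray(b, dtype=float)[:, None]
    return float((S * U - np.logaddexp(0.0, U)).sum())


def fit_map_full(
    spikes: SpikeMatrix,
    prior: _ell.Prior = None,
    mask: Optional[ObservationMask] = None,
    max_iter: int = 5000,
    tol: float = 1e-9,
) -> _ell.InferenceResult:
    """L1-MAP on the exact loglikelihood (fully observed rasters only).

    FISTA jointly in (W, b) with b unpenalized; same solver contract as
    :func:`shotgun_conn.ell.fit_map` but each gradient costs O(N² T).
    """
    if mask is not None and not (mask.O == 1).all():
        raise ValueError(
            "fit_map_full requires full observation; use the ELL path "
            "(moments + fit_map) for partially observed data"
        )
    if prior is None:
        prior = _ell.Prior()
    S = spikes.S.astype(float)
    N, T = S.shape
    lam = prior.lam
    S_prev = np.concatenate([np.zeros((N, 1)), S[:, :-1]], axis=1)
    S_cur = S
    Tm1 = T

    penalty_mask = np.ones((N, N), dtype=bool)
    if not prior.penalize_diagonal:
        np.fill_diagonal(penalty_mask, False)

    # Lipschitz of the per-bin-normalized smooth part: (1/4) λmax of the
    # design Gram [S_prev; 1][S_prev; 1]^T / (T-1)
    design = np.vstack([S_prev, np.ones(Tm1)])
    gram = design @ design.T / Tm1
    L = 0.25 * float(np.linalg.eigvalsh(gram)[-1])
    step = 1.0 / max(L, 1e-12)

    W = np.zeros((N, N))
    b = np.zeros(N)
    Yw, Yb = W.copy(), b.copy()
    t_mom = 1.0

    def smooth_and_grad(Wm, bv):
        U = Wm @ S_prev + bv[:, None]
        f = -(S_cur * U - np.logaddexp(0.0, U)).sum() / Tm1
        R = _sigmoid(U) - S_cur  # negative-loglik residual
        gW = (R @ S_prev.T) / Tm1
        gb = R.sum(axis=1) / Tm1
        return f, gW, gb

    def penalized(Wm, bv):
        f, _, _ = smooth_and_grad(Wm, bv)
        return f + lam * np.abs(Wm[penalty_mask]).sum()

    trace = [penalized(W, b)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        _, gW, gb = smooth_and_grad(Yw, Yb)
        W_new = Yw - step * gW
        W_new = np.where(
            penalty_mask, _soft(W_new, lam * step), W_new
        )
        b_new = Yb - step * gb
        f_new = penalized(W_new, b_new)
        if f_new > trace[-1] + 1e-15:
            t_mom = 1.0
            Yw, Yb = W.copy(), b.copy()
            _, gW, gb = smooth_and_grad(Yw, Yb)
            W_new = Yw - step * gW
            W_new = np.where(penalty_mask, _soft(W_new, lam * step), W_new)
            b_new = Yb - step * gb
            f_new = penalized(W_new, b_new)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        Yw = W_new + ((t_mom - 1.0) / t_new) * (W_new - W)
        Yb = b_new + ((t_mom - 1.0) / t_new) * (b_new - b)
        W, b, t_mom = W_new, b_new, t_new
        trace.append(f_new)
        rel = abs(trace[-2] - trace[-1]) / max(abs(trace[-1]), 1e-12)
        if rel < tol:
            converged = True
            break

    flags = {} if converged else {"not_converged": True}
    return _ell.InferenceResult(
        W_hat=W, b_hat=b, lambda_used=lam,
        objective_trace=np.asarray(trace), iterations=it,
        converged=converged, flags=flags,
    )


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _soft(x, t):
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


# ---------------------------------------------------------------------------
# Gibbs imputation of missing spikes
# ---------------------------------------------------------------------------


@njit(cache=True)
def _softplus_nb(x):  # pragma: no cover - numba helper
    if x > 30.0:
        return x
    if x < -30.0:
        return np.exp(x)
    return np.log(1.0 + np.exp(x))


@njit(cache=True)
def _gibbs_sweeps(S, O, W_idx, W_ptr, W_val, b, n_sweeps, unif):  # pragma: no cover
    """Systematic-scan single-site Gibbs over missing entries, in (t, i) order.

    ``W_idx/W_ptr/W_val`` encode the *columns* of W in CSC-like form: the
    postsynaptic targets j with W[j, i] != 0 for each presynaptic i, so the
    future-bin terms only sum over actual connections.  ``unif`` supplies
    one uniform per missing site per sweep.
    """
    N, T = S.shape
    # current input matrix U[:, t] = W S[:, t-1] + b for t >= 1
    U = np.empty((N, T))
    for t in range(T):
        for j in range(N):
            U[j, t] = b[j]
    for t in range(1, T):
        for i in range(N):
            if S[i, t - 1]:
                for p in range(W_ptr[i], W_ptr[i + 1]):
                    U[W_idx[p], t] += W_val[p]
    ctr = 0
    sp = np.empty(N)  # cached softplus of the next column's current inputs
    for sweep in range(n_sweeps):
        for t in range(T):
            if t + 1 < T:
                for j in range(N):
                    sp[j] = _softplus_nb(U[j, t + 1])
            for i in range(N):
                if O[i, t]:
                    continue
                # log-odds of S[i, t] = 1 given everything else
                if t == 0:
                    lo = 0.0  # initial column: flat prior, no input term
                else:
                    lo = U[i, t]
                si = S[i, t]
                if t + 1 < T:
                    for p in range(W_ptr[i], W_ptr[i + 1]):
                        j = W_idx[p]
                        w = W_val[p]
                        u_cur = U[j, t + 1]
                        sp_cur = sp[j]
                        if si:
                            u0 = u_cur - w
                            sp0 = _softplus_nb(u0)
                            u1 = u_cur
                            sp1 = sp_cur
                        else:
                            u0 = u_cur
                            sp0 = sp_cur
                            u1 = u_cur + w
                            sp1 = _softplus_nb(u1)
                        sj = S[j, t + 1]
                        lo += sj * (u1 - u0) - sp1 + sp0
                p1 = 1.0 / (1.0 + np.exp(-lo))
                new = 1 if unif[ctr] < p1 else 0
                ctr += 1
                if new != si:
                    if t + 1 < T:
                        d = 1.0 if new == 1 else -1.0
                        for p in range(W_ptr[i], W_ptr[i + 1]):
                            j = W_idx[p]
                            U[j, t + 1] += d * W_val[p]
                            sp[j] = _softplus_nb(U[j, t + 1])
                    S[i, t] = new


def gibbs_impute(
    spikes: SpikeMatrix,
    mask: ObservationMask,
    W: np.ndarray,
    b: np.ndarray,
    sweeps: int = 31,
    seed: int = 0,
) -> SpikeMatrix:
    """Impute unobserved spikes by single-site Gibbs sampling.

    Each missing entry is resampled from its full conditional under the GLM
    with parameters (W, b): proportional to the emission term at bin t times
    the likelihood of every bin-(t+1) spike it feeds into.  Observed entries
    are never modified.  ``sweeps`` counts total systematic sweeps; the state
    after the last sweep is returned (default 31 = 30 burn-in + 1 sample).
    """
    if sweeps < 1:
        raise ValueError("sweeps must be >= 1")
    if spikes.S.shape != mask.O.shape:
        raise ValueError("shape mismatch")
    S = spikes.S.astype(np.uint8).copy()
    O = mask.O.astype(np.uint8)
    n_missing = int((O == 0).sum())
    if n_missing == 0:
        return SpikeMatrix(S=S, bin_width=spikes.bin_width)
    W = np.asarray(W, dtype=float)
    # column-sparse structure of W for the future-bin terms
    from scipy import sparse

    Wc = sparse.csc_matrix(W)
    rng = np.random.default_rng(seed)
    unif = rng.random(n_missing * sweeps)
    _gibbs_sweeps(
        S, O,
        Wc.indices.astype(np.int64), Wc.indptr.astype(np.int64), Wc.data,
        np.asarray(b, dtype=float), sweeps, unif,
    )
    return SpikeMatrix(S=S, bin_width=spikes.bin_width)


def em_step(
    spikes: SpikeMatrix,
    mask: ObservationMask,
    result: _ell.InferenceResult,
    prior: _ell.Prior = None,
    sweeps: int = 31,
    seed: int = 0,
    grad_mode: str = "adjusted",
    match_sparsity: float = None,
    **fit_kwargs,
) -> _ell.InferenceResult:
    """One Monte-Carlo EM step around the ELL fit.

    E-step: Gibbs-impute the missing spikes at the current (W_hat, b_hat).
    M-step: recompute moments on the completed raster (full observation) and
    refit with the ELL MAP — at the same prior, or with λ re-matched to
    ``match_sparsity`` when given (re-matching avoids the shrinkage feedback
    of imputing from an L1-shrunk estimate and then penalizing again).
    """
    if prior is None:
        prior = _ell.Prior(lam=result.lambda_used)
    b = result.b_hat.copy()
    b[~np.isfinite(b)] = -20.0  # silent neurons: effectively never spike
    completed = gibbs_impute(spikes, mask, result.W_hat, b, sweeps=sweeps, seed=seed)
    mom = exact_moments(completed)
    T = completed.T
    if match_sparsity is not None:
        _, new = _ell.select_lambda(
            mom, T, match_sparsity, grad_mode=grad_mode, **fit_kwargs
        )
    else:
        new = _ell.fit_map(
            mom, T, prior, grad_mode=grad_mode, W0=result.W_hat, **fit_kwargs
        )
    new.flags["em_parent_objective"] = (
        float(result.objective_trace[-1]) if len(result.objective_trace) else None
    )
    return new
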