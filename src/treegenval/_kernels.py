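"""Numba kernels for the threshold-linear Gibbs sampler.

One call to :func:`iterate_once` performs a full sweep: (i) data augmentation
(liabilities of categorical records from truncated conditional normals,
missing trait values from plain conditional normals), (ii) single-site draws
of all location effects (fixed block means, plot effects, additive values)
from their multivariate-normal full conditionals. Covariance-matrix updates
stay in the Python layer.

All multivariate draws use a small-matrix Cholesky written out long-hand, so
the kernels never allocate inside the hot loops.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def seed_rng(seed):  # pragma: no cover - numba
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _draw_mvn_prec(P, rhs, L, y, out):  # pragma: no cover - numba
    """Draw from N(P^{-1} rhs, P^{-1}); returns False on a non-SPD P."""
    T = P.shape[0]
    for i in range(T):
        for j in range(i + 1):
            s = P[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    for i in range(T):
        s = rhs[i]
        for k in range(i):
            s -= L[i, k] * y[k]
        y[i] = s / L[i, i]
    for i in range(T - 1, -1, -1):
        s = y[i]
        for k in range(i + 1, T):
            s -= L[k, i] * out[k]
        out[i] = s / L[i, i]
    # add noise: x = L^{-T} z has covariance P^{-1}
    for i in range(T - 1, -1, -1):
        s = np.random.standard_normal()
        for k in range(i + 1, T):
            s -= L[k, i] * y[k]
        y[i] = s / L[i, i]
    for i in range(T):
        out[i] += y[i]
    return True


@njit(cache=True)
def _rtnorm_tail(a):  # pragma: no cover - numba
    """Standard normal truncated to [a, inf), a finite (Robert's method)."""
    if a < 0.3:
        while True:
            x = np.random.standard_normal()
            if x >= a:
                return x
    lam = 0.5 * (a + np.sqrt(a * a + 4.0))
    while True:
        x = a - np.log(np.random.random()) / lam
        if np.log(np.random.random()) <= -0.5 * (x - lam) ** 2:
            return x


@njit(cache=True)
def _rtnorm_std(a, b):  # pragma: no cover - numba
    """Standard normal truncated to (a, b); either bound may be +-inf."""
    if a == -np.inf and b == np.inf:
        return np.random.standard_normal()
    if b == np.inf:
        return _rtnorm_tail(a)
    if a == -np.inf:
        return -_rtnorm_tail(-b)
    # bounded interval
    if a <= 0.0 <= b and b - a > 1.0:
        for _ in range(128):
            x = np.random.standard_normal()
            if a < x <= b:
                return x
    # uniform rejection with the interval's density maximum as envelope
    if a > 0.0:
        peak = a * a
    elif b < 0.0:
        peak = b * b
    else:
        peak = 0.0
    while True:
        x = a + (b - a) * np.random.random()
        if np.log(np.random.random()) <= -0.5 * (x * x - peak):
            return x


@njit(cache=True)
def iterate_once(
    obs, cat, ttype, w,
    block_idx, plot_idx, ind_idx,
    block_ptr, block_recs, plot_ptr, plot_recs, rec_of_ind,
    kp, ki, kx,
    b, pl, u,
    R0inv, L_R0, Sinv, P0inv,
    beta, cond_sd, t1, t2,
):  # pragma: no cover - numba
    """One full Gibbs sweep over augmented data and location effects."""
    n_rec, T = w.shape
    n_blocks = b.shape[0]
    n_plots = pl.shape[0]
    n_ind = u.shape[0]

    f = np.empty(T)
    P = np.empty((T, T))
    rhs = np.empty(T)
    L = np.empty((T, T))
    scratch = np.empty(T)
    draw = np.empty(T)

    # --- augmentation: liabilities and missing traits ---
    for i in range(n_rec):
        bi = block_idx[i]
        pi = plot_idx[i]
        ui = ind_idx[i]
        for t in range(T):
            f[t] = b[bi, t] + u[ui, t]
            if pi >= 0:
                f[t] += pl[pi, t]
        for t in range(T):
            if ttype[t] == 0 and obs[i, t] == 1:
                continue  # observed linear record stays fixed
            m = f[t]
            for s in range(T):
                if s != t:
                    m += beta[t, s] * (w[i, s] - f[s])
            sd = cond_sd[t]
            if ttype[t] == 1 and obs[i, t] == 1:
                c = cat[i, t]
                if c == 1:
                    lo, hi = -np.inf, (t1 - m) / sd
                elif c == 2:
                    lo, hi = (t1 - m) / sd, (t2 - m) / sd
                else:
                    lo, hi = (t2 - m) / sd, np.inf
                w[i, t] = m + sd * _rtnorm_std(lo, hi)
            else:
                w[i, t] = m + sd * np.random.standard_normal()

    # --- fixed block means (flat prior) ---
    for lev in range(n_blocks):
        for t in range(T):
            rhs[t] = 0.0
        cnt = 0.0
        for k in range(block_ptr[lev], block_ptr[lev + 1]):
            i = block_recs[k]
            pi = plot_idx[i]
            ui = ind_idx[i]
            for t in range(T):
                r = w[i, t] - u[ui, t]
                if pi >= 0:
                    r -= pl[pi, t]
                rhs[t] += r
            cnt += 1.0
        if cnt == 0.0:
            continue
        inv_sqrt = 1.0 / np.sqrt(cnt)
        for t in range(T):
            scratch[t] = np.random.standard_normal()
        for t in range(T):
            m = rhs[t] / cnt
            for s in range(t + 1):
                m += L_R0[t, s] * scratch[s] * inv_sqrt
            b[lev, t] = m

    # --- plot effects ---
    for lev in range(n_plots):
        for t in range(T):
            f[t] = 0.0
        cnt = 0.0
        for k in range(plot_ptr[lev], plot_ptr[lev + 1]):
            i = plot_recs[k]
            bi = block_idx[i]
            ui = ind_idx[i]
            for t in range(T):
                f[t] += w[i, t] - b[bi, t] - u[ui, t]
            cnt += 1.0
        for t in range(T):
            rhs[t] = 0.0
            for s in range(T):
                rhs[t] += R0inv[t, s] * f[s]
                P[t, s] = cnt * R0inv[t, s] + P0inv[t, s]
        if not _draw_mvn_prec(P, rhs, L, scratch, draw):
            return -(lev + 1)
        for t in range(T):
            pl[lev, t] = draw[t]

    # --- additive genetic values (single-site over Kinv rows) ---
    for j in range(n_ind):
        kjj = 0.0
        for t in range(T):
            f[t] = 0.0  # f = sum_{k != j} Kinv_jk u_k
        for ptr in range(kp[j], kp[j + 1]):
            k = ki[ptr]
            v = kx[ptr]
            if k == j:
                kjj += v
            else:
                for t in range(T):
                    f[t] += v * u[k, t]
        rec = rec_of_ind[j]
        for t in range(T):
            rhs[t] = 0.0
            for s in range(T):
                rhs[t] -= Sinv[t, s] * f[s]
                P[t, s] = kjj * Sinv[t, s]
        if rec >= 0:
            bi = block_idx[rec]
            pi = plot_idx[rec]
            for t in range(T):
                scratch[t] = w[rec, t] - b[bi, t]
                if pi >= 0:
                    scratch[t] -= pl[pi, t]
            for t in range(T):
                for s in range(T):
                    rhs[t] += R0inv[t, s] * scratch[s]
                    P[t, s] += R0inv[t, s]
        if not _draw_mvn_prec(P, rhs, L, scratch, draw):
            return -(n_plots + j + 1)
        for t in range(T):
            u[j, t] = draw[t]
    return 0
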