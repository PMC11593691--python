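"""Fast SIMPLS submodel scoring used by the iterative-shrinkage selector.

SIMPLS computes the same PLS1 model as NIPALS for a single response and a
direct multi-response generalization (dominant eigenvector of S'S per
component).  The selector must score thousands of random channel-subset
submodels by K-fold cross-validated RMSE per iteration, so the scorer is
written as tight loops and JIT-compiled with numba when available; a
pure-numpy implementation of the identical algorithm is the fallback and the
reference in tests.
"""

from __future__ import annotations

import numpy as np

try:  # optional speedup
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally installed
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


def simpls_coefficients(Xc: np.ndarray, Yc: np.ndarray, n_lv: int) -> np.ndarray:
    """SIMPLS regression coefficients for centered Xc (n x k), Yc (n x m).

    Returns B (k x m) with ``Yc_hat = Xc @ B``.  Components stop early if the
    score norm collapses (rank exhausted).
    """
    k = Xc.shape[1]
    m = Yc.shape[1]
    S = Xc.T @ Yc
    R = np.zeros((k, n_lv))
    V = np.zeros((k, n_lv))
    Q = np.zeros((m, n_lv))
    a_eff = 0
    for a in range(n_lv):
        if m == 1:
            r = S[:, 0].copy()
        else:
            M = S.T @ S
            q = np.ones(m)
            for _ in range(30):
                q_new = M @ q
                nq = np.linalg.norm(q_new)
                if nq == 0:
                    break
                q = q_new / nq
            r = S @ q
        t = Xc @ r
        nt = np.linalg.norm(t)
        if nt < 1e-12:
            break
        t = t / nt
        r = r / nt
        p = Xc.T @ t
        qload = Yc.T @ t
        v = p.copy()
        for i in range(a_eff):
            v -= V[:, i] * (V[:, i] @ p)
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            break
        v /= nv
        S = S - np.outer(v, v @ S)
        R[:, a] = r
        V[:, a] = v
        Q[:, a] = qload
        a_eff = a + 1
    if a_eff == 0:
        return np.zeros((k, m))
    return R[:, :a_eff] @ Q[:, :a_eff].T


def _score_submodels_numpy(
    X: np.ndarray,
    Y: np.ndarray,
    masks: np.ndarray,
    fold_ids: np.ndarray,
    n_folds: int,
    max_lv: int,
) -> np.ndarray:
    """Cross-validated RMSE of one PLS submodel per mask row (reference path)."""
    n, _ = X.shape
    m = Y.shape[1]
    out = np.empty(masks.shape[0])
    for s in range(masks.shape[0]):
        cols = np.flatnonzero(masks[s])
        Xs = X[:, cols]
        sse = 0.0
        for f in range(n_folds):
            test = fold_ids == f
            train = ~test
            Xt = Xs[train]
            Yt = Y[train]
            xm = Xt.mean(axis=0)
            ym = Yt.mean(axis=0)
            a = min(max_lv, len(cols), int(train.sum()) - 1)
            B = simpls_coefficients(Xt - xm, Yt - ym, a)
            pred = (Xs[test] - xm) @ B + ym
            sse += float(np.sum((pred - Y[test]) ** 2))
        out[s] = np.sqrt(sse / (n * m))
    return out


@njit(cache=True)
def _score_submodels_numba(X, Y, masks, fold_ids, n_folds, max_lv):  # pragma: no cover
    n, p = X.shape
    m = Y.shape[1]
    n_sub = masks.shape[0]
    out = np.empty(n_sub)
    for s in range(n_sub):
        k = 0
        for j in range(p):
            if masks[s, j]:
                k += 1
        cols = np.empty(k, dtype=np.int64)
        c = 0
        for j in range(p):
            if masks[s, j]:
                cols[c] = j
                c += 1
        sse = 0.0
        for f in range(n_folds):
            nt = 0
            for i in range(n):
                if fold_ids[i] != f:
                    nt += 1
            Xt = np.empty((nt, k))
            Yt = np.empty((nt, m))
            r = 0
            for i in range(n):
                if fold_ids[i] != f:
                    for c in range(k):
                        Xt[r, c] = X[i, cols[c]]
                    for c in range(m):
                        Yt[r, c] = Y[i, c]
                    r += 1
            xm = np.zeros(k)
            ym = np.zeros(m)
            for i in range(nt):
                for c in range(k):
                    xm[c] += Xt[i, c]
                for c in range(m):
                    ym[c] += Yt[i, c]
            for c in range(k):
                xm[c] /= nt
            for c in range(m):
                ym[c] /= nt
            for i in range(nt):
                for c in range(k):
                    Xt[i, c] -= xm[c]
                for c in range(m):
                    Yt[i, c] -= ym[c]
            a_max = min(max_lv, k, nt - 1)
            # ---- SIMPLS ----
            S = Xt.T @ Yt
            R = np.zeros((k, a_max))
            V = np.zeros((k, a_max))
            Q = np.zeros((m, a_max))
            a_eff = 0
            for a in range(a_max):
                if m == 1:
                    rvec = S[:, 0].copy()
                else:
                    M = S.T @ S
                    q = np.ones(m)
                    for _ in range(30):
                        q_new = M @ q
                        nq = np.sqrt(np.sum(q_new * q_new))
                        if nq == 0:
                            break
                        q = q_new / nq
                    rvec = S @ q
                t = Xt @ rvec
                ntn = np.sqrt(np.sum(t * t))
                if ntn < 1e-12:
                    break
                t = t / ntn
                rvec = rvec / ntn
                pv = Xt.T @ t
                qload = Yt.T @ t
                v = pv.copy()
                for i in range(a_eff):
                    dot = 0.0
                    for c in range(k):
                        dot += V[c, i] * pv[c]
                    for c in range(k):
                        v[c] -= V[c, i] * dot
                nv = np.sqrt(np.sum(v * v))
                if nv < 1e-12:
                    break
                v = v / nv
                vS = v @ S
                for c in range(k):
                    for d in range(m):
                        S[c, d] -= v[c] * vS[d]
                for c in range(k):
                    R[c, a] = rvec[c]
                    V[c, a] = v[c]
                for d in range(m):
                    Q[d, a] = qload[d]
                a_eff = a + 1
            B = np.zeros((k, m))
            for a in range(a_eff):
                for c in range(k):
                    for d in range(m):
                        B[c, d] += R[c, a] * Q[d, a]
            # ---- test fold ----
            for i in range(n):
                if fold_ids[i] == f:
                    for d in range(m):
                        pred = ym[d]
                        for c in range(k):
                            pred += (X[i, cols[c]] - xm[c]) * B[c, d]
                        diff = pred - Y[i, d]
                        sse += diff * diff
        out[s] = np.sqrt(sse / (n * m))
    return out


def score_submodels(
    X: np.ndarray,
    Y: np.ndarray,
    masks: np.ndarray,
    fold_ids: np.ndarray,
    n_folds: int,
    max_lv: int,
    force_numpy: bool = False,
) -> np.ndarray:
    """K-fold CV RMSE (pooled over responses) per channel-subset mask row."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    Y = np.ascontiguousarray(Y if Y.ndim == 2 else Y[:, None], dtype=np.float64)
    masks = np.ascontiguousarray(masks, dtype=bool)
    fold_ids = np.ascontiguousarray(fold_ids, dtype=np.int64)
    if HAVE_NUMBA and not force_numpy:
        return _score_submodels_numba(X, Y, masks, fold_ids, n_folds, max_lv)
    return _score_submodels_numpy(X, Y, masks, fold_ids, n_folds, max_lv)
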