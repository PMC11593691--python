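"""Chemometric learners: NIPALS partial least squares (regression and
discriminant analysis) plus contracts over standard learners (BPNN, SVM, RF).

The PLS machinery is implemented from scratch with the NIPALS algorithm --
mean-centering of X and Y, no variance scaling, which is the chemometrics
convention for reflectance spectra.  Latent variables are extracted by
deflation, so a single fit with ``A`` components yields every nested model
with ``k <= A`` components for free (used heavily by cross-validated
latent-variable selection).

The back-propagation network, support vector machine and random forest are
thin, seeded wrappers over scikit-learn estimators with the standardization
each method expects handled internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVC

from .errors import (
    DataError,
    DegenerateTargetError,
    InvalidLabelsError,
    InvalidParameterError,
)

DEFAULT_PLSDA_LV_RANGE = range(4, 16)


# --------------------------------------------------------------------------
# NIPALS PLS core
# --------------------------------------------------------------------------


@dataclass
class PLSModel:
    """A fitted NIPALS PLS model (PLS1 or PLS2).

    ``B``/``intercept`` give predictions for *uncentered* inputs:
    ``y_hat = X @ B + intercept``; by construction ``predict(x_mean) ==
    y_mean``.  ``weights`` (W), ``x_loadings`` (P) and ``y_loadings`` (Q) are
    channels-by-LV / targets-by-LV matrices; successive score vectors are
    mutually orthogonal.
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray  # (p, A)
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (m, A)
    coefficients: np.ndarray  # (p, m)
    intercept: np.ndarray  # (m,)
    x_scores: np.ndarray | None = None  # (n, A), training scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = X @ self.coefficients + self.intercept
        return out[:, 0] if out.shape[1] == 1 else out

    def coefficients_for(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Coefficients/intercept of the nested model with the first *k* LVs."""
        if not 1 <= k <= self.n_lv:
            raise InvalidParameterError(f"k must be in [1, {self.n_lv}]")
        W, P, Q = self.weights[:, :k], self.x_loadings[:, :k], self.y_loadings[:, :k]
        B = W @ np.linalg.solve(P.T @ W, Q.T)
        return B, self.y_mean - self.x_mean @ B

    def to_json(self, path) -> None:
        payload = {
            "kind": "PLS",
            "n_lv": int(self.n_lv),
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean.tolist(),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "PLSModel":
        d = json.loads(Path(path).read_text())
        return cls(
            n_lv=d["n_lv"],
            x_mean=np.array(d["x_mean"]),
            y_mean=np.array(d["y_mean"]),
            weights=np.array(d["weights"]),
            x_loadings=np.array(d["x_loadings"]),
            y_loadings=np.array(d["y_loadings"]),
            coefficients=np.array(d["coefficients"]),
            intercept=np.array(d["intercept"]),
        )


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    max_iter: int = 500,
    tol: float = 1e-12,
) -> PLSModel:
    """Fit PLS by NIPALS with *n_lv* latent variables.

    For a single response the inner loop is non-iterative; for multi-response
    Y it alternates until the score vector stabilizes.  X and Y are
    mean-centered internally (no scaling); returned coefficients apply to the
    original inputs.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise DataError("X and y have different sample counts")
    if not 1 <= n_lv <= min(n - 1, p):
        raise InvalidParameterError(
            f"n_lv={n_lv} outside [1, min(n_samples-1, n_channels)={min(n - 1, p)}]"
        )
    if np.allclose(Y.std(axis=0), 0):
        raise DegenerateTargetError("response has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    m = Y.shape[1]

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((m, n_lv))
    T = np.zeros((n, n_lv))
    total_var = float(np.sum(Xc**2))
    a_eff = 0
    for a in range(n_lv):
        u = Yc[:, int(np.argmax(Yc.var(axis=0)))]
        if np.allclose(u, 0):
            break  # Y fully deflated
        t = q = None
        t_old = None
        for _ in range(max_iter if m > 1 else 1):
            w = Xc.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                t = None
                break
            w /= nw
            t = Xc @ w
            tt = t @ t
            if tt == 0:
                t = None
                break
            q = Yc.T @ t / tt
            if m == 1:
                break
            u = Yc @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        if t is None:
            break  # covariance exhausted
        tt = t @ t
        if tt <= 1e-14 * max(total_var, 1.0):
            break  # rank exhausted
        p_load = Xc.T @ t / tt
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_load, q, t
        Xc = Xc - np.outer(t, p_load)
        Yc = Yc - np.outer(t, q)
        a_eff = a + 1
    if a_eff == 0:
        raise DegenerateTargetError("no usable covariance between X and y")
    W, P, Q, T = W[:, :a_eff], P[:, :a_eff], Q[:, :a_eff], T[:, :a_eff]
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    return PLSModel(
        n_lv=a_eff,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        coefficients=B,
        intercept=y_mean - x_mean @ B,
        x_scores=T,
    )


def select_plsr_lv(
    X: np.ndarray,
    y: np.ndarray,
    lv_range=range(1, 16),
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Choose a PLSR latent-variable count by K-fold CV RMSE (ties: fewer LVs)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, cv_folds)
    ks = sorted(lv_range)
    sse = dict.fromkeys(ks, 0.0)
    usable = dict.fromkeys(ks, True)
    for test_idx in folds:
        train_idx = np.setdiff1d(order, test_idx)
        k_cap = min(max(ks), len(train_idx) - 1, X.shape[1])
        model = fit_plsr(X[train_idx], y[train_idx], k_cap)
        for k in ks:
            if k > model.n_lv:
                usable[k] = False
                kk = model.n_lv
            else:
                kk = k
            B, b0 = model.coefficients_for(kk)
            pred = X[test_idx] @ B[:, 0] + b0[0]
            sse[k] += float(np.sum((pred - y[test_idx]) ** 2))
    rmse = {k: float(np.sqrt(sse[k] / n)) for k in ks}
    best = min(ks, key=lambda k: (rmse[k], k))
    return best, rmse


# --------------------------------------------------------------------------
# PLS-DA
# --------------------------------------------------------------------------


@dataclass
class PLSDAModel:
    """PLS2 on one-hot class indicators with an argmax decision rule.

    ``classes`` fixes the indicator column order; argmax ties resolve to the
    earlier class.  Only labels seen in training can be predicted.
    """

    classes: list
    pls: PLSModel
    n_lv: int
    cv_accuracy: dict = field(default_factory=dict)

    def predict_indicator(self, X: np.ndarray) -> np.ndarray:
        out = self.pls.predict(X)
        return out if out.ndim == 2 else out[:, None]

    def predict(self, X: np.ndarray) -> np.ndarray:
        ind = self.predict_indicator(X)
        return np.asarray(self.classes, dtype=object)[np.argmax(ind, axis=1)]


def fit_plsda(
    X: np.ndarray,
    labels,
    lv_range=DEFAULT_PLSDA_LV_RANGE,
    cv_folds: int = 5,
    seed: int = 0,
) -> PLSDAModel:
    """Fit PLS-DA, choosing the LV count by stratified-CV accuracy.

    The LV grid (default 4-15) is scored by stratified K-fold classification
    accuracy; ties go to the smallest LV count.  The final model is refit on
    the full data with the chosen count.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = list(pd.unique(labels))
    if len(classes) < 2:
        raise InvalidLabelsError("PLS-DA requires at least two classes")
    counts = pd.Series(labels).value_counts()
    if (counts < cv_folds).any():
        raise InvalidLabelsError(
            f"every class needs >= cv_folds={cv_folds} members "
            f"(smallest has {int(counts.min())})"
        )
    Y = (labels[:, None] == np.asarray(classes, dtype=object)[None, :]).astype(float)
    ks = sorted(lv_range)
    k_max_req = max(ks)

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    correct = dict.fromkeys(ks, 0)
    for train_idx, test_idx in skf.split(X, labels):
        k_cap = min(k_max_req, len(train_idx) - 1, X.shape[1])
        model = fit_plsr(X[train_idx], Y[train_idx], k_cap)
        for k in ks:
            kk = min(k, model.n_lv)
            B, b0 = model.coefficients_for(kk)
            pred_ind = X[test_idx] @ B + b0
            pred = np.asarray(classes, dtype=object)[np.argmax(pred_ind, axis=1)]
            correct[k] += int(np.sum(pred == labels[test_idx]))
    acc = {k: correct[k] / len(labels) for k in ks}
    best = min(ks, key=lambda k: (-acc[k], k))
    k_fit = min(best, len(labels) - 1, X.shape[1])
    final = fit_plsr(X, Y, k_fit)
    return PLSDAModel(classes=classes, pls=final, n_lv=final.n_lv, cv_accuracy=acc)


# --------------------------------------------------------------------------
# Standard-learner contracts
# --------------------------------------------------------------------------


class BPNNRegressor:
    """Single-hidden-layer feedforward network (logistic hidden units, linear
    output) trained by gradient-based back-propagation; deterministic under a
    fixed seed.  Inputs and the response are standardized internally."""

    def __init__(self, hidden_nodes: int = 10, epochs: int = 500, seed: int = 0):
        if hidden_nodes < 1:
            raise InvalidParameterError("hidden_nodes must be >= 1")
        self.hidden_nodes = hidden_nodes
        self.epochs = epochs
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BPNNRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise DataError("BPNN inputs must be finite")
        self._x_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self._x_sd = np.where(sd == 0, 1.0, sd)
        self._y_mean = y.mean()
        ysd = y.std()
        if ysd == 0:  # constant response: nothing to learn
            self._net = None
            self._y_sd = 1.0
            return self
        self._y_sd = ysd
        self._net = MLPRegressor(
            hidden_layer_sizes=(self.hidden_nodes,),
            activation="logistic",
            solver="lbfgs",
            max_iter=self.epochs,
            random_state=self.seed,
        )
        self._net.fit((X - self._x_mean) / self._x_sd, (y - self._y_mean) / self._y_sd)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._net is None:
            return np.full(X.shape[0], self._y_mean)
        z = self._net.predict((X - self._x_mean) / self._x_sd)
        return z * self._y_sd + self._y_mean


class SVMClassifier:
    """RBF-kernel margin classifier over internally standardized features."""

    def __init__(self, kernel: str = "rbf", C: float = 1.0, gamma: float | None = None):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma

    def fit(self, X: np.ndarray, labels) -> "SVMClassifier":
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels)
        if len(pd.unique(labels)) < 2:
            raise InvalidLabelsError("SVM requires at least two classes")
        self._x_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self._x_sd = np.where(sd == 0, 1.0, sd)
        gamma = self.gamma if self.gamma is not None else 1.0 / X.shape[1]
        self._svc = SVC(kernel=self.kernel, C=self.C, gamma=gamma)
        self._svc.fit((X - self._x_mean) / self._x_sd, labels)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._svc.predict((X - self._x_mean) / self._x_sd)


class RFRegressor:
    """Mean-of-trees random forest regressor, seeded."""

    def __init__(self, n_trees: int = 500, seed: int = 0):
        if n_trees < 1:
            raise InvalidParameterError("n_trees must be >= 1")
        self.n_trees = n_trees
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RFRegressor":
        self._rf = RandomForestRegressor(
            n_estimators=self.n_trees, random_state=self.seed, n_jobs=1
        )
        self._rf.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float).ravel())
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._rf.predict(np.asarray(X, dtype=float))


def fit_bpnn(X, y, hidden_nodes: int = 10, epochs: int = 500, seed: int = 0) -> BPNNRegressor:
    return BPNNRegressor(hidden_nodes, epochs, seed).fit(X, y)


def fit_svm(X, labels, kernel: str = "rbf", C: float = 1.0, gamma: float | None = None) -> SVMClassifier:
    return SVMClassifier(kernel, C, gamma).fit(X, labels)


def fit_rf(X, y, n_trees: int = 500, seed: int = 0) -> RFRegressor:
    return RFRegressor(n_trees, seed).fit(X, y)
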