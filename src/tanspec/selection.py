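"""Effective-wavelength screening: successive projections algorithm (SPA)
and variable iterative space shrinkage approach (VISSA).

SPA is deterministic forward selection in column space: starting from each
candidate channel, the chain repeatedly adds the unselected channel whose
column has the largest norm after projection onto the orthogonal complement
of the span of the already-selected columns (maximally non-collinear
information).  Every (start, chain length) combination is then scored by
multiple linear regression RMSE on a held-out validation split, and the
global minimizer wins (ties: shorter chain, then smaller starting channel).

VISSA is model-population analysis with weighted binary matrix sampling:
every channel carries an inclusion probability (weight, starting at 0.5); a
population of random channel subsets is drawn from those weights, each subset
is scored by cross-validated PLS RMSE, and the weights are updated to the
inclusion frequencies within the best-scoring fraction of the population.
Weights therefore shrink the search space iteration by iteration; a channel
whose weight hits 0 can never return.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import solve_triangular

from ._simpls import score_submodels
from .errors import (
    DegenerateTargetError,
    InvalidParameterError,
)


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs for both selectors.

    SPA: chain lengths ``spa_k_min..spa_k_max``.  VISSA: population size
    ``n_submodels``, surviving fraction ``top_fraction``, iteration cap,
    final inclusion ``weight_threshold``, submodel scorer settings
    (``cv_folds``-fold CV of a PLS model capped at ``max_lv`` components).
    """

    spa_k_min: int = 5
    spa_k_max: int = 60
    n_submodels: int = 1000
    top_fraction: float = 0.05
    max_iter: int = 50
    weight_threshold: float = 0.5
    cv_folds: int = 5
    max_lv: int = 10

    def __post_init__(self) -> None:
        if not 1 <= self.spa_k_min <= self.spa_k_max:
            raise InvalidParameterError("require 1 <= spa_k_min <= spa_k_max")
        if not 0 < self.top_fraction < 1:
            raise InvalidParameterError("top_fraction must be in (0, 1)")
        if self.n_submodels < 1 or self.max_iter < 1:
            raise InvalidParameterError("n_submodels and max_iter must be >= 1")


@dataclass
class SelectionResult:
    """Outcome of one selector run."""

    method: str  # "SPA" | "VISSA"
    selected: np.ndarray  # sorted unique channel indices
    score_trace: list = field(default_factory=list)
    weights: np.ndarray | None = None  # VISSA only, in [0, 1]
    details: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return int(len(self.selected))

    def to_json(self, path, wavelengths_nm=None) -> None:
        payload = {
            "method": self.method,
            "selected": [int(i) for i in self.selected],
            "score_trace": self.score_trace,
            "weights": None if self.weights is None else [float(w) for w in self.weights],
            "details": {k: v for k, v in self.details.items() if _jsonable(v)},
        }
        if wavelengths_nm is not None:
            wl = np.asarray(wavelengths_nm, dtype=float)
            payload["wavelengths_nm"] = [float(wl[i]) for i in self.selected]
        Path(path).write_text(json.dumps(payload, indent=1))


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def reduction_percent(n_selected: int, n_total: int) -> float:
    """Percentage of channels removed, to 2 decimals: 100*(1 - sel/total)."""
    if n_total <= 0:
        raise InvalidParameterError("n_total must be positive")
    if not 0 <= n_selected <= n_total:
        raise InvalidParameterError("require 0 <= n_selected <= n_total")
    return round(100.0 * (1.0 - n_selected / n_total), 2)


def spa_chain(X: np.ndarray, start: int, k_max: int) -> np.ndarray:
    """The SPA projection chain of length <= k_max starting at column *start*.

    At each step every remaining column is projected onto the orthogonal
    complement of the most recently selected column's direction (successive
    projections), and the column with the largest residual norm is appended.
    Exactly collinear columns project to zero and can never co-occur.
    """
    Xp = np.array(X, dtype=float)
    n, p = Xp.shape
    chain = [int(start)]
    tol = 1e-10 * max(float(np.max(np.sum(X**2, axis=0))), 1.0)
    for _ in range(min(k_max, p) - 1):
        v = Xp[:, chain[-1]]
        nv = v @ v
        if nv <= tol:
            break
        Xp -= np.outer(v, v @ Xp) / nv
        norms = np.sum(Xp**2, axis=0)
        norms[chain] = -1.0
        j = int(np.argmax(norms))
        if norms[j] <= tol:
            break
        chain.append(j)
    return np.array(chain, dtype=int)


def spa_select(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    k_min: int = 5,
    k_max: int = 60,
) -> SelectionResult:
    """Successive projections algorithm with MLR validation scoring.

    For every starting channel, the projection chain is grown to ``k_max``;
    each prefix of length ``k_min..k_max`` is scored by the RMSE of an
    ordinary least-squares model (with intercept) on the validation split.
    Multi-column y is supported (RMSE pooled over responses).
    """
    X_cal = np.asarray(X_cal, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    Y_cal = np.asarray(y_cal, dtype=float)
    Y_val = np.asarray(y_val, dtype=float)
    if Y_cal.ndim == 1:
        Y_cal = Y_cal[:, None]
        Y_val = Y_val[:, None]
    n, p = X_cal.shape
    if not 1 <= k_min <= k_max:
        raise InvalidParameterError("require 1 <= k_min <= k_max")
    if k_max >= n:
        raise InvalidParameterError(
            f"k_max={k_max} must be < n_calibration_samples={n} for a well-posed MLR"
        )
    k_max = min(k_max, p)
    k_min = min(k_min, k_max)
    norms0 = np.sum(X_cal**2, axis=0)
    if np.any(norms0 == 0):
        raise InvalidParameterError("X_cal contains an all-zero column")

    best = None  # (rmse, k, start, chain)
    trace = np.full((p, k_max + 1), np.nan)
    ones_cal = np.ones((n, 1))
    ones_val = np.ones((X_val.shape[0], 1))
    m = Y_cal.shape[1]
    n_val = X_val.shape[0]
    for start in range(p):
        chain = spa_chain(X_cal, start, k_max)
        D = np.hstack([ones_cal, X_cal[:, chain]])
        Qm, Rm = np.linalg.qr(D)
        Qty = Qm.T @ Y_cal
        Dval = np.hstack([ones_val, X_val[:, chain]])
        rdiag = np.abs(np.diag(Rm))
        for k in range(k_min, len(chain) + 1):
            cols = k + 1  # + intercept
            if np.any(rdiag[:cols] < 1e-10 * max(rdiag[0], 1.0)):
                break
            beta = solve_triangular(Rm[:cols, :cols], Qty[:cols])
            resid = Dval[:, :cols] @ beta - Y_val
            rmse = float(np.sqrt(np.mean(resid**2)))
            trace[start, k] = rmse
            cand = (rmse, k, start)
            if best is None or cand < best[:3]:
                best = (rmse, k, start, chain[:k])
    if best is None:
        raise InvalidParameterError("no admissible SPA chain; widen k range")
    rmse, k, start, sel = best
    return SelectionResult(
        method="SPA",
        selected=np.sort(sel),
        score_trace=[
            {"start": int(s), "k": int(kk), "rmse": float(trace[s, kk])}
            for s in range(p)
            for kk in range(k_min, k_max + 1)
            if np.isfinite(trace[s, kk])
        ],
        details={
            "best_rmse": rmse,
            "best_k": int(k),
            "best_start": int(start),
            "n_val": int(n_val),
            "n_responses": int(m),
        },
    )


def vissa_select(
    X: np.ndarray,
    y: np.ndarray,
    config: SelectionConfig | None = None,
    seed: int | None = None,
) -> SelectionResult:
    """VISSA: weighted binary matrix sampling with survivor reweighting.

    Weights start at 0.5 for every channel.  Each iteration draws
    ``n_submodels`` binary inclusion rows (entry j included with probability
    w_j; rows with fewer than 2 channels are redrawn), scores each row's PLS
    submodel by K-fold CV RMSE, keeps the best ``top_fraction``, and replaces
    the weights with the survivors' inclusion frequencies.  Iteration stops
    when all weights are 0 or 1 or at ``max_iter``.  Channels whose final
    weight reaches ``weight_threshold`` are selected.
    """
    cfg = config or SelectionConfig()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if np.allclose(Y.std(axis=0), 0):
        raise DegenerateTargetError("response has zero variance")
    if cfg.n_submodels < 100:
        raise InvalidParameterError("n_submodels must be >= 100 for stable frequencies")
    rng = np.random.default_rng(seed)
    # fixed fold assignment across iterations -> paired submodel comparisons
    fold_ids = rng.permutation(n) % cfg.cv_folds

    w = np.full(p, 0.5)
    n_keep = max(1, int(round(cfg.top_fraction * cfg.n_submodels)))
    trace: list[dict] = []
    for it in range(cfg.max_iter):
        active = np.flatnonzero(w > 0)
        if active.size < 2:
            break
        masks = rng.random((cfg.n_submodels, p)) < w
        for _ in range(100):
            bad = np.flatnonzero(masks.sum(axis=1) < 2)
            if bad.size == 0:
                break
            masks[bad] = rng.random((bad.size, p)) < w
        bad = np.flatnonzero(masks.sum(axis=1) < 2)
        if bad.size:  # weights too sparse to sample 2 channels; force the top two
            top2 = np.argsort(w)[-2:]
            masks[bad[:, None], top2[None, :]] = True
        scores = score_submodels(X, Y, masks, fold_ids, cfg.cv_folds, cfg.max_lv)
        keep = np.argsort(scores, kind="stable")[:n_keep]
        w = masks[keep].mean(axis=0)
        trace.append(
            {
                "iteration": it,
                "best_rmse": float(scores[keep[0]]),
                "mean_kept_rmse": float(scores[keep].mean()),
                "n_active": int(np.sum(w > 0)),
            }
        )
        if np.all((w == 0.0) | (w == 1.0)):
            break
    selected = np.flatnonzero(w >= cfg.weight_threshold)
    return SelectionResult(
        method="VISSA",
        selected=selected,
        score_trace=trace,
        weights=w,
        details={"n_iterations": len(trace), "n_keep": n_keep},
    )
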