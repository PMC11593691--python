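"""Row-wise spectral pretreatments: SNV, MSC, Savitzky-Golay, derivatives.

Every transform operates sample-by-sample (row-wise) on a samples-by-channels
matrix, so permuting samples commutes with each method and no information
leaks between samples.  The one deliberate exception to statelessness is the
multiplicative scatter correction reference: in a calibration/prediction
workflow the reference must come from the calibration set only, which is what
:class:`Preprocessor` implements.

Derivatives are Savitzky-Golay derivatives (local polynomial least squares),
not simple differences, and are expressed per channel *index*.  On a
two-sensor axis the segments are differentiated independently and
concatenated so the sensor seam does not produce a spurious spike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    DegenerateFitError,
    DegenerateSpectrumError,
    InvalidParameterError,
)

METHODS = ("ORI", "D1", "D2", "SG", "MSC", "SNV")

DEFAULT_WINDOW = 11
DEFAULT_POLYORDER = 2


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: each row to zero mean, unit SD (ddof=1)."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise DegenerateSpectrumError(
            f"constant spectrum at row {int(bad[0])}: SNV undefined"
        )
    return (X - mu) / sd


def msc(X: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative scatter correction against *reference*.

    Each row is regressed on the reference, ``x ~ a*ref + b``, and returned as
    ``(x - b)/a``.  The reference defaults to the column-mean spectrum of *X*;
    for calibration/prediction workflows pass the calibration-set reference
    explicitly (or use :class:`Preprocessor`).
    """
    X = np.asarray(X, dtype=float)
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.shape != (X.shape[1],):
        raise InvalidParameterError("reference length must equal the channel count")
    refc = ref - ref.mean()
    denom = refc @ refc
    if denom == 0:
        raise DegenerateFitError("MSC reference is constant")
    xm = X.mean(axis=1)
    a = (X - xm[:, None]) @ refc / denom
    bad = np.flatnonzero(np.abs(a) < 1e-12)
    if bad.size:
        raise DegenerateFitError(
            f"MSC slope ~ 0 at row {int(bad[0])}: spectrum orthogonal to reference"
        )
    b = xm - a * ref.mean()
    return (X - b[:, None]) / a[:, None]


def _check_window(window: int, polyorder: int, deriv: int, n_channels: int) -> None:
    if window % 2 != 1:
        raise InvalidParameterError("window must be odd")
    if not (window > polyorder >= deriv >= 0):
        raise InvalidParameterError("require window > polyorder >= deriv >= 0")
    if window > n_channels:
        raise InvalidParameterError(
            f"window {window} exceeds channel count {n_channels}"
        )


def savgol(
    X: np.ndarray,
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
    deriv: int = 0,
    segments: list[slice] | None = None,
) -> np.ndarray:
    """Savitzky-Golay smoothing / differentiation, per segment.

    Edge channels are handled by evaluating the edge-window polynomial fit
    (``mode='interp'``), so the channel count is preserved.  Derivative units
    are per channel index within each segment.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        return savgol(X[None, :], window, polyorder, deriv, segments)[0]
    if segments is None:
        segments = [slice(0, X.shape[1])]
    out = np.empty_like(X)
    for sl in segments:
        n = sl.stop - sl.start
        _check_window(window, polyorder, deriv, n)
        out[:, sl] = savgol_filter(
            X[:, sl], window, polyorder, deriv=deriv, axis=1, mode="interp"
        )
    return out


def derivative(
    X: np.ndarray,
    order: int,
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
    segments: list[slice] | None = None,
) -> np.ndarray:
    """Savitzky-Golay derivative of *order* 1 (D1) or 2 (D2)."""
    if order not in (1, 2):
        raise InvalidParameterError("derivative order must be 1 or 2")
    return savgol(X, window, polyorder, deriv=order, segments=segments)


@dataclass
class PreprocessSpec:
    """Serializable description of one pretreatment."""

    method: str = "ORI"
    window: int = DEFAULT_WINDOW
    polyorder: int = DEFAULT_POLYORDER

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise InvalidParameterError(
                f"unknown method {self.method!r}; expected one of {METHODS}"
            )
        if self.method in ("D1", "D2", "SG"):
            _check_window(self.window, self.polyorder, 0, self.window)

    def to_dict(self) -> dict:
        return {"method": self.method, "window": self.window, "polyorder": self.polyorder}

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        return cls(
            method=d.get("method", "ORI"),
            window=int(d.get("window", DEFAULT_WINDOW)),
            polyorder=int(d.get("polyorder", DEFAULT_POLYORDER)),
        )


class Preprocessor:
    """Fit-on-calibration / transform-anywhere wrapper around the transforms.

    Only MSC is stateful (its reference spectrum is the calibration-set column
    mean); all other methods ignore :meth:`fit`.
    """

    def __init__(self, spec: PreprocessSpec | str, segments: list[slice] | None = None):
        self.spec = PreprocessSpec(method=spec) if isinstance(spec, str) else spec
        self.segments = segments
        self.msc_reference_: np.ndarray | None = None

    def fit(self, X_cal: np.ndarray) -> "Preprocessor":
        if self.spec.method == "MSC":
            self.msc_reference_ = np.asarray(X_cal, dtype=float).mean(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        m = self.spec.method
        if m == "ORI":
            return np.asarray(X, dtype=float)
        if m == "SNV":
            return snv(X)
        if m == "MSC":
            if self.msc_reference_ is None:
                raise InvalidParameterError("MSC preprocessor must be fit before transform")
            return msc(X, reference=self.msc_reference_)
        if m == "SG":
            return savgol(X, self.spec.window, self.spec.polyorder, 0, self.segments)
        if m == "D1":
            return derivative(X, 1, self.spec.window, self.spec.polyorder, self.segments)
        if m == "D2":
            return derivative(X, 2, self.spec.window, self.spec.polyorder, self.segments)
        raise InvalidParameterError(f"unknown method {m!r}")

    def fit_transform(self, X_cal: np.ndarray) -> np.ndarray:
        return self.fit(X_cal).transform(X_cal)
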