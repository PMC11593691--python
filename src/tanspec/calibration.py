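"""Black/white reference calibration and region-of-interest extraction.

Raw hyperspectral frames mix the sample signal with dark current and the
spatial/spectral profile of the illumination.  The standard correction uses a
dark frame (shutter closed) and a white frame (near-perfect diffuse
reflector):

    R = (R_raw - R_dark) / (R_white - R_dark)

applied elementwise over pixels and channels.  Values slightly outside
[0, 1] are legitimate (detector noise, specular glints) and are deliberately
*not* clipped -- clipping would bias downstream scatter-correction tests --
but their frequency is reported through the module logger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateReferenceError, DimensionError, InvalidMaskError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrameTriple:
    """Raw, dark and white intensity frames of identical shape.

    Shapes may be ``(pixels, channels)`` or ``(rows, cols, channels)``; the
    dark/white frames may also be broadcastable to the raw shape (a single
    reference spectrum per channel is common).
    """

    raw: np.ndarray
    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw, dtype=float)
        dark = np.asarray(self.dark, dtype=float)
        white = np.asarray(self.white, dtype=float)
        try:
            dark_b = np.broadcast_to(dark, raw.shape)
            white_b = np.broadcast_to(white, raw.shape)
        except ValueError as exc:
            raise DimensionError(
                f"frame shapes incompatible: raw {raw.shape}, dark {dark.shape}, "
                f"white {white.shape}"
            ) from exc
        object.__setattr__(self, "raw", raw)
        object.__setattr__(self, "dark", np.array(dark_b))
        object.__setattr__(self, "white", np.array(white_b))


def calibrate(frames: FrameTriple) -> np.ndarray:
    """Reflectance ``(raw - dark) / (white - dark)``, elementwise.

    Raises
    ------
    DegenerateReferenceError
        If white and dark coincide anywhere; the message names the first
        offending channel (last axis index).
    """
    denom = frames.white - frames.dark
    bad = denom == 0
    if np.any(bad):
        channel = int(np.argwhere(bad)[0][-1])
        raise DegenerateReferenceError(
            f"white == dark at channel {channel}: reference frames give a zero "
            "denominator"
        )
    refl = (frames.raw - frames.dark) / denom
    n_out = int(np.sum((refl < 0) | (refl > 1)))
    if n_out:
        logger.info(
            "calibrate: %d of %d values outside [0, 1] (kept, not clipped)",
            n_out,
            refl.size,
        )
    return refl


def extract_roi_mean(reflectance_cube: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-channel arithmetic mean over the pixels included by *mask*.

    ``reflectance_cube`` is ``(rows, cols, channels)`` or ``(pixels,
    channels)``; ``mask`` is a boolean (or 0/1) map over the spatial shape.
    Returns one spectrum of length ``channels``.
    """
    cube = np.asarray(reflectance_cube, dtype=float)
    m = np.asarray(mask)
    if cube.ndim < 2:
        raise DimensionError("reflectance cube must have a trailing channel axis")
    if m.shape != cube.shape[:-1]:
        raise InvalidMaskError(
            f"mask shape {m.shape} does not match cube spatial shape {cube.shape[:-1]}"
        )
    m = m.astype(bool)
    if not m.any():
        raise InvalidMaskError("ROI mask selects no pixels")
    pixels = cube.reshape(-1, cube.shape[-1])[m.reshape(-1)]
    return pixels.mean(axis=0)
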