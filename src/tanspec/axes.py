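"""Wavelength axes for dual-sensor (VNIR + SWIR) hyperspectral instruments.

A push-broom imager of the kind used for powdered-herb work carries two
cameras: a visible/near-infrared sensor (~410-990 nm) and a short-wave
infrared sensor (~950-2500 nm).  Their channel grids are concatenated into a
single axis, and every per-channel provenance question ("which sensor saw
this band?") is answered by the ``segment`` tags kept alongside the
wavelengths.  Segment boundaries also matter downstream: derivative
pretreatments must not difference across the sensor seam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

VNIR = "VNIR"
SWIR = "SWIR"

#: Default instrument geometry: 108 VNIR channels at a 5.4 nm pitch starting
#: at 410 nm, and 288 SWIR channels spanning 950-2500 nm.
DEFAULT_VNIR_START = 410.0
DEFAULT_VNIR_STEP = 5.4
DEFAULT_VNIR_STOP = 990.0
DEFAULT_SWIR_START = 950.0
DEFAULT_SWIR_COUNT = 288
DEFAULT_SWIR_STEP = (2500.0 - DEFAULT_SWIR_START) / (DEFAULT_SWIR_COUNT - 1)


@dataclass(frozen=True)
class WavelengthAxis:
    """Ordered channel-center wavelengths with per-channel sensor tags.

    Parameters
    ----------
    wavelengths_nm : ndarray of float
        Channel centers in nanometres.
    segment : ndarray of str
        Per-channel sensor tag, ``"VNIR"`` or ``"SWIR"``.  Wavelengths must be
        strictly increasing within each contiguous segment (the SWIR grid may
        start below the last VNIR channel, as the two sensors overlap).
    """

    wavelengths_nm: np.ndarray
    segment: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        seg = np.asarray(self.segment, dtype=object)
        if wl.ndim != 1 or seg.shape != wl.shape:
            raise InvalidParameterError(
                "wavelengths_nm and segment must be 1-D arrays of equal length"
            )
        if wl.size == 0:
            raise InvalidParameterError("axis must contain at least one channel")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "segment", seg)
        for sl in self.segments():
            w = wl[sl]
            if w.size > 1 and not np.all(np.diff(w) > 0):
                raise InvalidParameterError(
                    f"wavelengths not strictly increasing within segment {seg[sl.start]!r}"
                )

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    @property
    def n_channels(self) -> int:
        return self.wavelengths_nm.size

    def segments(self) -> list[slice]:
        """Contiguous runs of equal segment tag, as slices into the axis."""
        seg = self.segment
        bounds = [0]
        for i in range(1, len(seg)):
            if seg[i] != seg[i - 1]:
                bounds.append(i)
        bounds.append(len(seg))
        return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]

    def segment_slice(self, name: str) -> slice:
        """Slice covering the first contiguous run tagged *name*."""
        for sl in self.segments():
            if self.segment[sl.start] == name:
                return sl
        raise InvalidParameterError(f"no segment named {name!r}")

    def count(self, name: str) -> int:
        return int(np.sum(self.segment == name))


def make_wavelength_axis(
    vnir_start_nm: float,
    vnir_step_nm: float,
    vnir_stop_nm: float,
    swir_start_nm: float = DEFAULT_SWIR_START,
    swir_step_nm: float = DEFAULT_SWIR_STEP,
    swir_count: int = DEFAULT_SWIR_COUNT,
) -> WavelengthAxis:
    """Build a two-segment axis from instrument grid parameters.

    VNIR channels are ``start + k*step`` for every ``k >= 0`` whose value does
    not exceed ``vnir_stop_nm`` (a half-step tolerance absorbs floating-point
    representation of the pitch).  SWIR channels are counted explicitly
    (``swir_count`` values from ``swir_start_nm`` at ``swir_step_nm``) because
    manufacturer-quoted range/step/count triples are frequently not mutually
    consistent and the channel count is the authoritative figure.
    """
    if vnir_step_nm <= 0 or swir_step_nm <= 0:
        raise InvalidParameterError("wavelength steps must be positive")
    if vnir_stop_nm < vnir_start_nm:
        raise InvalidParameterError("vnir_stop_nm must be >= vnir_start_nm")
    if swir_count < 1:
        raise InvalidParameterError("swir_count must be >= 1")
    n_vnir = int(np.floor((vnir_stop_nm - vnir_start_nm) / vnir_step_nm + 0.5 * 1e-9)) + 1
    # guard against the stop falling a hair under start + k*step
    while vnir_start_nm + n_vnir * vnir_step_nm <= vnir_stop_nm + 1e-9:
        n_vnir += 1
    vnir = vnir_start_nm + vnir_step_nm * np.arange(n_vnir)
    swir = swir_start_nm + swir_step_nm * np.arange(swir_count)
    wl = np.concatenate([vnir, swir])
    seg = np.array([VNIR] * n_vnir + [SWIR] * swir_count, dtype=object)
    return WavelengthAxis(wl, seg)


def default_axis() -> WavelengthAxis:
    """The default 108-channel VNIR + 288-channel SWIR axis (396 channels)."""
    return make_wavelength_axis(
        DEFAULT_VNIR_START,
        DEFAULT_VNIR_STEP,
        DEFAULT_VNIR_STOP,
        DEFAULT_SWIR_START,
        DEFAULT_SWIR_STEP,
        DEFAULT_SWIR_COUNT,
    )
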