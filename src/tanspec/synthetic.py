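"""Seeded generator of synthetic powdered-herb reflectance spectra.

The generator emulates the statistical structure a diffuse-reflectance
chemometrics study of *Salvia miltiorrhiza* powder relies on:

* five geographic origin classes (Shandong SD, Hebei HB, Shanxi SX, Sichuan
  SC, Anhui AH) with per-origin tanshinone concentration distributions
  (tanshinone I, tanshinone IIA, cryptotanshinone; mg/g dry weight, totals
  derived as the component sum);
* a Beer-Lambert-style absorbance model: each analyte contributes
  concentration-linear Gaussian absorption bands in the short-wave infrared,
  on top of a fixed baseline carrying water/C-H bands (910/960/1120 nm) and a
  steep visible-region pigment edge;
* an origin-specific visible-region colour band (powders from different
  provinces differ visibly in colour), which is what makes origins separable
  beyond their analyte contents;
* sample-wise affine scatter ``x = a*r + b + eps`` -- exactly the distortion
  multiplicative scatter correction and the standard normal variate are
  designed to remove -- plus iid channel noise;
* raw/dark/white frame triples consistent with the reflectance, so the
  black/white calibration step is testable end to end.

Everything is driven by a single integer seed; identical seeds reproduce
bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .axes import WavelengthAxis, default_axis
from .calibration import FrameTriple
from .errors import DimensionError, InvalidParameterError

#: Analyte column order used throughout the package.
ANALYTES = ("tan_i", "tan_iia", "cts")
ORIGINS = ("SD", "HB", "SX", "SC", "AH")


@dataclass(frozen=True)
class OriginProfile:
    """Per-origin analyte concentration distribution (mean/SD, mg/g)."""

    origin: str
    mean_mgg: tuple[float, float, float]  # (tan_i, tan_iia, cts)
    sd_mgg: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.mean_mgg) or any(s < 0 for s in self.sd_mgg):
            raise InvalidParameterError("concentration means and SDs must be nonnegative")


#: Reference per-origin concentration statistics (mg/g) for the five
#: provinces; totals are always derived, never parameterized.
DEFAULT_ORIGIN_PROFILES: tuple[OriginProfile, ...] = (
    OriginProfile("SD", (1.090, 2.807, 3.616), (0.373, 0.983, 2.070)),
    OriginProfile("HB", (0.316, 0.826, 0.451), (0.268, 0.633, 0.379)),
    OriginProfile("SX", (0.132, 1.142, 0.640), (0.058, 0.608, 0.420)),
    OriginProfile("SC", (0.271, 1.663, 0.678), (0.186, 1.317, 0.687)),
    OriginProfile("AH", (0.376, 1.940, 1.928), (0.257, 1.113, 1.831)),
)


@dataclass(frozen=True)
class PureSpectrum:
    """Gaussian absorption-band model of one analyte's unit-concentration
    absorbance contribution (absorbance units per mg/g)."""

    analyte: str
    band_centers_nm: tuple[float, ...]
    band_widths_nm: tuple[float, ...]
    band_amplitudes: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.band_centers_nm)
        if not (len(self.band_widths_nm) == n == len(self.band_amplitudes)):
            raise InvalidParameterError("band parameter tuples must share one length")
        if any(a < 0 for a in self.band_amplitudes):
            raise InvalidParameterError("band amplitudes must be nonnegative")
        if any(w <= 0 for w in self.band_widths_nm):
            raise InvalidParameterError("band widths must be positive")

    def absorbance(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Unit-concentration absorbance profile over *wavelengths_nm*."""
        wl = np.asarray(wavelengths_nm, dtype=float)
        out = np.zeros_like(wl)
        for c, w, a in zip(self.band_centers_nm, self.band_widths_nm, self.band_amplitudes):
            out += a * np.exp(-0.5 * ((wl - c) / w) ** 2)
        return out


def default_pure_spectra() -> tuple[PureSpectrum, ...]:
    """One distinct SWIR band per analyte (C-H / carbonyl overtone region).

    Amplitudes of 0.1 AU per mg/g put peak analyte absorbances in the
    0.01-0.4 range for realistic contents.
    """
    return (
        PureSpectrum("tan_i", (2220.0,), (45.0,), (0.10,)),
        PureSpectrum("tan_iia", (1740.0,), (45.0,), (0.10,)),
        PureSpectrum("cts", (1300.0,), (40.0,), (0.10,)),
    )


@dataclass(frozen=True)
class BaselineSpec:
    """Concentration-independent absorbance background.

    ``vis_edge_amp/vis_edge_decay_nm`` model the steep pigment absorption that
    makes reflectance rise sharply across 400-900 nm.  ``shared_bands`` are
    water / C-H features common to all samples.  ``origin_bands`` maps each
    origin to one visible-region Gaussian (center, width, amplitude) -- the
    colour difference between provenances.  ``offset_sd`` is the SD of the
    per-sample additive reflectance offset ``b``.
    """

    vis_edge_amp: float = 1.2
    vis_edge_decay_nm: float = 150.0
    shared_bands: tuple[tuple[float, float, float], ...] = (
        (910.0, 35.0, 0.25),
        (960.0, 35.0, 0.30),
        (1120.0, 40.0, 0.15),
    )
    origin_bands: dict = field(
        default_factory=lambda: {
            "SD": (520.0, 60.0, 0.35),
            "HB": (560.0, 60.0, 0.12),
            "SX": (480.0, 55.0, 0.25),
            "SC": (610.0, 60.0, 0.18),
            "AH": (660.0, 65.0, 0.28),
        }
    )
    offset_sd: float = 0.005

    def shared_absorbance(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=float)
        out = self.vis_edge_amp * np.exp(-(wl - wl.min()) / self.vis_edge_decay_nm)
        for c, w, a in self.shared_bands:
            out += a * np.exp(-0.5 * ((wl - c) / w) ** 2)
        return out

    def origin_absorbance(self, origin: str, wavelengths_nm: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=float)
        if origin not in self.origin_bands:
            return np.zeros_like(wl)
        c, w, a = self.origin_bands[origin]
        return a * np.exp(-0.5 * ((wl - c) / w) ** 2)

    def without_origin_bands(self) -> "BaselineSpec":
        return replace(self, origin_bands={})


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated dataset: axis, sample table, reflectance and scatter truth.

    ``truth`` records the per-sample multiplicative slope ``a``, additive
    offset ``b`` and the channel noise SD actually applied, so tests can
    verify scatter-correction behaviour against known ground truth.
    """

    axis: WavelengthAxis
    samples: pd.DataFrame
    reflectance: np.ndarray
    truth: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.reflectance.shape[1]


def simulate_concentrations(
    profiles=DEFAULT_ORIGIN_PROFILES,
    n_per_origin: int = 84,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw per-sample analyte contents from zero-truncated normals.

    Returns a table with columns ``sample_id, origin, tan_i, tan_iia, cts,
    total``; the total is the exact component sum.  SD = 0 degenerates to the
    profile mean.
    """
    profiles = tuple(profiles)
    if not profiles:
        raise InvalidParameterError("at least one origin profile is required")
    if n_per_origin < 1:
        raise InvalidParameterError("n_per_origin must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for prof in profiles:
        vals = np.empty((n_per_origin, len(ANALYTES)))
        for k, (m, s) in enumerate(zip(prof.mean_mgg, prof.sd_mgg)):
            if s == 0:
                vals[:, k] = m
            else:
                a = (0.0 - m) / s  # truncate at zero: contents are physical
                vals[:, k] = stats.truncnorm.rvs(
                    a, np.inf, loc=m, scale=s, size=n_per_origin, random_state=rng
                )
        for i in range(n_per_origin):
            rows.append(
                {
                    "sample_id": f"{prof.origin}-{i + 1:03d}",
                    "origin": prof.origin,
                    **{name: vals[i, k] for k, name in enumerate(ANALYTES)},
                }
            )
    df = pd.DataFrame(rows)
    df["total"] = df[list(ANALYTES)].sum(axis=1)
    return df


def simulate_reflectance(
    samples: pd.DataFrame,
    pures=None,
    axis: WavelengthAxis | None = None,
    scatter_sd: float = 0.05,
    baseline: BaselineSpec | None = None,
    noise_sd: float = 0.003,
    seed: int | None = None,
) -> SyntheticDataset:
    """Turn a sample table into observed reflectance spectra.

    Absorbance ``A(lam) = baseline(lam, origin) + sum_k conc_k * pure_k(lam)``,
    ideal reflectance ``r = exp(-A)``, observed
    ``x = a*r + b + eps`` with ``a ~ N(1, scatter_sd)``,
    ``b ~ N(0, baseline.offset_sd)`` and ``eps ~ N(0, noise_sd)`` iid.
    """
    if pures is None:
        pures = default_pure_spectra()
    if axis is None:
        axis = default_axis()
    if baseline is None:
        baseline = BaselineSpec()
    if scatter_sd < 0 or noise_sd < 0:
        raise InvalidParameterError("scatter_sd and noise_sd must be nonnegative")
    by_analyte = {p.analyte: p for p in pures}
    missing = [a for a in ANALYTES if a in samples.columns and a not in by_analyte]
    if missing:
        raise InvalidParameterError(f"no pure spectrum supplied for analyte(s) {missing}")

    wl = axis.wavelengths_nm
    pure_mat = np.stack([by_analyte[a].absorbance(wl) for a in ANALYTES])  # (3, p)
    if pure_mat.shape[1] != axis.n_channels:
        raise DimensionError("pure-spectrum length does not match axis")
    conc = samples[list(ANALYTES)].to_numpy(dtype=float)  # (n, 3)
    shared = baseline.shared_absorbance(wl)

    absorb = shared[None, :] + conc @ pure_mat
    for origin in pd.unique(samples["origin"]):
        sel = (samples["origin"] == origin).to_numpy()
        absorb[sel] += baseline.origin_absorbance(str(origin), wl)[None, :]

    r = np.exp(-absorb)
    n = r.shape[0]
    rng = np.random.default_rng(seed)
    a_slope = rng.normal(1.0, scatter_sd, size=n) if scatter_sd > 0 else np.ones(n)
    b_off = (
        rng.normal(0.0, baseline.offset_sd, size=n)
        if baseline.offset_sd > 0
        else np.zeros(n)
    )
    eps = rng.normal(0.0, noise_sd, size=r.shape) if noise_sd > 0 else 0.0
    x = a_slope[:, None] * r + b_off[:, None] + eps

    truth = pd.DataFrame(
        {
            "sample_id": samples["sample_id"].to_numpy(),
            "scatter_slope": a_slope,
            "scatter_offset": b_off,
            "noise_sd": noise_sd,
        }
    )
    return SyntheticDataset(axis=axis, samples=samples.reset_index(drop=True), reflectance=x, truth=truth)


def simulate_raw_frames(
    dataset: SyntheticDataset,
    white_level: float = 1000.0,
    dark_level: float = 100.0,
    seed: int | None = None,
    frame_noise_sd: float = 0.0,
) -> FrameTriple:
    """Raw/dark/white frames whose black-white calibration reproduces
    ``dataset.reflectance`` exactly (when ``frame_noise_sd`` is 0, the
    default)."""
    if white_level <= dark_level or dark_level < 0:
        raise InvalidParameterError("require white_level > dark_level >= 0")
    refl = dataset.reflectance
    dark = np.full_like(refl, dark_level)
    white = np.full_like(refl, white_level)
    raw = dark + refl * (white - dark)
    if frame_noise_sd > 0:
        rng = np.random.default_rng(seed)
        raw = raw + rng.normal(0.0, frame_noise_sd, size=raw.shape)
    return FrameTriple(raw=raw, dark=dark, white=white)


def make_dataset(
    seed: int | None = 0,
    n_per_origin: int = 84,
    profiles=DEFAULT_ORIGIN_PROFILES,
    pures=None,
    axis: WavelengthAxis | None = None,
    scatter_sd: float = 0.05,
    baseline: BaselineSpec | None = None,
    noise_sd: float = 0.003,
) -> SyntheticDataset:
    """Default study-sized dataset: 5 origins x *n_per_origin* samples.

    A single seed drives both the concentration draw and the spectral noise
    (two independent substreams derived from it).
    """
    ss = np.random.SeedSequence(seed)
    s_conc, s_spec = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    samples = simulate_concentrations(profiles, n_per_origin=n_per_origin, seed=s_conc)
    return simulate_reflectance(
        samples,
        pures=pures,
        axis=axis,
        scatter_sd=scatter_sd,
        baseline=baseline,
        noise_sd=noise_sd,
        seed=s_spec,
    )
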