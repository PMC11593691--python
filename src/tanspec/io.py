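"""Readers and writers for spectra tables and ENVI-style cubes.

Spectra CSV layout: first row is the wavelength header (first cell ``sample_id``),
each subsequent row is one sample.  Sample metadata CSV carries
``sample_id, origin, tan_i, tan_iia, cts, total``.

The ENVI format is a plain-ASCII ``.hdr`` file describing a headerless binary
cube; only the subset needed here is supported (BSQ/BIL interleave, IEEE
float32/float64/uint16, little/big endian, an optional ``wavelength`` block).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .axes import SWIR, VNIR, WavelengthAxis
from .errors import DataError, InvalidParameterError

# ENVI "data type" codes -> numpy dtypes (subset)
_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def write_spectra_csv(path, axis: WavelengthAxis, sample_ids, X) -> None:
    """Write a samples-by-channels matrix with a wavelength header row."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != axis.n_channels:
        raise DataError("spectra width does not match axis length")
    df = pd.DataFrame(X, columns=[f"{w:.4f}" for w in axis.wavelengths_nm])
    df.insert(0, "sample_id", list(sample_ids))
    df.to_csv(path, index=False)


def read_spectra_csv(path) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Read a spectra CSV; returns ``(wavelengths_nm, sample_ids, X)``.

    The header is parsed directly (not via DataFrame column names) because
    overlapping VNIR/SWIR sensors can legitimately produce duplicate
    wavelength labels.
    """
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    if not header or header[0] != "sample_id":
        raise DataError("spectra CSV must start with a sample_id column")
    try:
        wl = np.array([float(c) for c in header[1:]])
    except ValueError as exc:
        raise DataError(f"non-numeric wavelength in header: {exc}") from exc
    df = pd.read_csv(path, header=None, skiprows=1)
    ids = df.iloc[:, 0].astype(str).tolist()
    X = df.iloc[:, 1:].to_numpy(dtype=float)
    return wl, ids, X


def axis_from_wavelengths(wl: np.ndarray, vnir_max_nm: float = 990.0) -> WavelengthAxis:
    """Reconstruct segment tags from a bare wavelength vector.

    Channels are tagged VNIR until the sequence first decreases (the sensor
    seam) or exceeds *vnir_max_nm*; the remainder is SWIR.
    """
    wl = np.asarray(wl, dtype=float)
    split = len(wl)
    for i in range(1, len(wl)):
        if wl[i] <= wl[i - 1] or wl[i] > vnir_max_nm:
            split = i
            break
    seg = np.array([VNIR] * split + [SWIR] * (len(wl) - split), dtype=object)
    return WavelengthAxis(wl, seg)


def write_samples_csv(path, samples: pd.DataFrame) -> None:
    samples.to_csv(path, index=False)


def read_samples_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise DataError("sample metadata CSV must contain a sample_id column")
    return df


def write_envi(path_base, cube: np.ndarray, wavelengths_nm=None, interleave: str = "bsq") -> None:
    """Write ``(lines, samples, bands)`` *cube* as ``<base>.img`` + ``<base>.hdr``."""
    cube = np.asarray(cube)
    if cube.ndim != 3:
        raise InvalidParameterError("ENVI cube must be 3-D (lines, samples, bands)")
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil"):
        raise InvalidParameterError(f"unsupported interleave {interleave!r}")
    if cube.dtype not in _ENVI_CODES:
        cube = cube.astype(np.float32)
    lines, samples, bands = cube.shape
    if interleave == "bsq":
        ordered = np.transpose(cube, (2, 0, 1))  # (bands, lines, samples)
    else:  # bil
        ordered = np.transpose(cube, (0, 2, 1))  # (lines, bands, samples)
    base = Path(path_base)
    ordered.tofile(base.with_suffix(".img"))
    lines_hdr = [
        "ENVI",
        f"samples = {samples}",
        f"lines = {lines}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_ENVI_CODES[np.dtype(cube.dtype)]}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if wavelengths_nm is not None:
        wl = ", ".join(f"{w:.4f}" for w in np.asarray(wavelengths_nm, dtype=float))
        lines_hdr.append("wavelength units = Nanometers")
        lines_hdr.append("wavelength = { " + wl + " }")
    base.with_suffix(".hdr").write_text("\n".join(lines_hdr) + "\n")


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    # fold {...} blocks onto one line
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(hdr_path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read an ENVI cube; returns ``(cube (lines, samples, bands), wavelengths or None)``."""
    hdr_path = Path(hdr_path)
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields.get("interleave", "bsq").lower()
    except KeyError as exc:
        raise DataError(f"ENVI header missing field: {exc}") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise DataError(f"unsupported ENVI data type {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    offset = int(fields.get("header offset", "0"))

    img_path = hdr_path.with_suffix(".img")
    if not img_path.exists():
        candidates = [p for p in (hdr_path.with_suffix(ext) for ext in (".dat", ".bsq", ".bil", "")) if p.exists() and p != hdr_path]
        if not candidates:
            raise DataError(f"no binary cube found next to {hdr_path}")
        img_path = candidates[0]
    data = np.fromfile(img_path, dtype=dtype, offset=offset)
    if data.size != samples * lines * bands:
        raise DataError("ENVI cube size does not match header dimensions")
    if interleave == "bsq":
        cube = data.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = data.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:
        raise DataError(f"unsupported interleave {interleave!r}")
    wl = None
    if "wavelength" in fields:
        inner = fields["wavelength"].strip().lstrip("{").rstrip("}")
        wl = np.array([float(t) for t in inner.replace(",", " ").split()])
    return cube.astype(float), wl


def read_mask(path) -> np.ndarray:
    """Read a 0/1 ROI mask from CSV or a PNG/image file."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return np.loadtxt(path, delimiter=",") > 0
    from matplotlib import image as mpimg

    img = mpimg.imread(path)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    return img > (img.max() / 2 if img.max() > 0 else 0)
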