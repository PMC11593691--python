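"""Small report plots (selected-channel maps, prediction scatter)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .axes import WavelengthAxis
from .selection import SelectionResult


def plot_selection(
    axis: WavelengthAxis,
    mean_spectrum: np.ndarray,
    result: SelectionResult,
    path,
    title: str | None = None,
) -> None:
    """Mark selected channels on the mean spectrum and save a PNG."""
    wl = axis.wavelengths_nm
    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.plot(wl, mean_spectrum, lw=0.8, color="0.3", label="mean spectrum")
    sel = np.asarray(result.selected, dtype=int)
    ax.plot(wl[sel], np.asarray(mean_spectrum)[sel], "r.", ms=5,
            label=f"{result.method} ({len(sel)} channels)")
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("reflectance (a.u.)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_prediction(y_true, y_pred, path, target: str = "") -> None:
    """Reference-vs-predicted scatter with the 1:1 line."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    fig, ax = plt.subplots(figsize=(4, 4))
    lo = min(y_true.min(), y_pred.min())
    hi = max(y_true.max(), y_pred.max())
    ax.plot([lo, hi], [lo, hi], "k--", lw=0.8)
    ax.plot(y_true, y_pred, "o", ms=4, alpha=0.6)
    ax.set_xlabel(f"reference {target} (mg/g)")
    ax.set_ylabel(f"predicted {target} (mg/g)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
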