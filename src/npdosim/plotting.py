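"""Minimal plotting helpers for proximity curves and nucleus-energy spectra."""

from __future__ import annotations

import numpy as np

from .proximity import ProximityCurve
from .tracks import EnergySpectrum

__all__ = ["plot_proximity", "plot_spectrum"]


def plot_proximity(curve: ProximityCurve, ax=None, label: str | None = None, **kwargs):
    """Log-log step plot of t(x); returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mask = curve.t_values > 0
    ax.loglog(curve.bin_centers[mask], curve.t_values[mask],
              drawstyle="steps-mid", label=label, **kwargs)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("t(x) (keV/um)")
    if label:
        ax.legend()
    return ax


def plot_spectrum(spectrum: EnergySpectrum, ax=None, bins: int = 50, **kwargs):
    """Histogram of the nonzero nucleus-energy spectrum; annotates the
    zero-event point mass in the title. Returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    nz = spectrum.energies_kev[spectrum.energies_kev > 0]
    if nz.size:
        ax.hist(nz, bins=bins, **kwargs)
    ax.set_xlabel("E in nucleus (keV)")
    ax.set_ylabel("events")
    ax.set_title(
        f"zero fraction {spectrum.zero_fraction:.3f}, "
        f"z-bar {spectrum.z_bar_gy:.2e} Gy"
    )
    return ax
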