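"""Proximity functions of energy-deposit point clouds.

The (differential) proximity function t(x) describes the geometry of a
track's energy-deposition pattern: t(x) dx is the expected energy found in
a spherical shell [x, x + dx] around a randomly chosen transfer point,
weighted by transfer energy. For a track with transfers of energy eps_i at
pairwise distances x_ij and total energy T = sum(eps_i), each ordered pair
(i, j), i != j, contributes eps_i * eps_j / T to the shell containing
x_ij; consequently the total mass integral(t dx) equals T - sum(eps^2)/T
exactly, an identity the binned estimator preserves (overflow included).

Under uniform irradiation at dose D the dose-dependent proximity function
gains an inter-track term that grows like the shell volume:
t_D(x) = t(x) + 4 pi x^2 rho D.

Internal units are keV and um throughout; this module owns the single
keV <-> J conversion constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "ProximityCurve",
    "default_bin_edges",
    "estimate_proximity",
    "weighted_proximity",
    "add_dose_term",
    "event_proximity_integral",
    "KEV_TO_J",
    "GY_GCC_TO_KEV_PER_UM3",
]

#: 1 keV in joules.
KEV_TO_J = 1.602176634e-16

#: rho * D = 1 (g/cm^3) * 1 Gy expressed as energy density in keV/um^3:
#: 1e-15 kg/um^3 * 1 J/kg / KEV_TO_J.
GY_GCC_TO_KEV_PER_UM3 = 1.0e-15 / KEV_TO_J


def default_bin_edges(n_per_decade: int = 20) -> np.ndarray:
    """Log-spaced bin edges from 1e-4 to 1e3 um (pair distances span ~7 decades)."""
    return np.geomspace(1e-4, 1e3, 7 * n_per_decade + 1)


@dataclass(frozen=True)
class ProximityCurve:
    """Binned proximity function t(x).

    ``t_values`` are in keV/um per track (per-track expectation over the
    ``n_tracks`` contributing tracks). ``overflow_mass`` collects, per
    track, the pair mass at distances outside the binned range — reported,
    never silently dropped. ``n_pairs`` counts ordered pairs per bin.
    """

    bin_edges: np.ndarray = field(repr=False)
    t_values: np.ndarray = field(repr=False)
    n_tracks: int = 1
    overflow_mass: float = 0.0
    n_pairs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        t = np.asarray(self.t_values, dtype=float)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0) or edges[0] < 0:
            raise ValueError("bin_edges must be 1-D, strictly increasing, first edge >= 0")
        if t.shape != (edges.size - 1,):
            raise ValueError("t_values length must equal number of bins")
        if np.any(t < 0):
            raise ValueError("t_values must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "t_values", t)

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin representatives: geometric means of the edges (arithmetic
        mean where the lower edge is zero)."""
        lo, hi = self.bin_edges[:-1], self.bin_edges[1:]
        centers = np.where(lo > 0, np.sqrt(lo * hi), 0.5 * (lo + hi))
        return centers

    @property
    def mass(self) -> float:
        """integral(t dx) over the binned range, keV per track."""
        return float(np.sum(self.t_values * self.bin_widths))

    @property
    def total_mass(self) -> float:
        """Binned mass plus overflow, keV per track."""
        return self.mass + self.overflow_mass


def _track_pair_data(positions: np.ndarray, energies: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Ordered-pair distances and weights eps_i*eps_j/T for one track."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    energies = np.asarray(energies, dtype=float)
    if energies.size == 0:
        raise ValueError("track has no deposits")
    if np.any(energies <= 0):
        raise ValueError("deposit energies must be positive")
    t_total = float(energies.sum())
    if energies.size < 2:
        return np.empty(0), np.empty(0), t_total
    d = pdist(positions)
    # pdist yields each unordered pair once, in upper-triangle order; the
    # double sum of the estimator counts both orders, hence the factor 2.
    i, j = np.triu_indices(energies.size, k=1)
    w = 2.0 * energies[i] * energies[j] / t_total
    return d, w, t_total


def estimate_proximity(
    tracks: list[tuple[np.ndarray, np.ndarray]],
    bin_edges: np.ndarray | None = None,
) -> ProximityCurve:
    """Estimate t(x) from a list of tracks (Eq. form: ordered-pair sum / T).

    Each track is a ``(positions, energies)`` pair; the per-bin pair mass is
    averaged over tracks and divided by the bin width. Pair distances that
    fall outside the binned range are accumulated in ``overflow_mass``.
    """
    if not tracks:
        raise ValueError("need at least one track")
    edges = default_bin_edges() if bin_edges is None else np.asarray(bin_edges, dtype=float)
    mass = np.zeros(edges.size - 1)
    pairs = np.zeros(edges.size - 1, dtype=np.int64)
    overflow = 0.0
    for positions, energies in tracks:
        d, w, _ = _track_pair_data(positions, energies)
        if d.size == 0:
            continue
        inside = (d >= edges[0]) & (d < edges[-1])
        overflow += float(w[~inside].sum())
        idx = np.searchsorted(edges, d[inside], side="right") - 1
        np.add.at(mass, idx, w[inside])
        np.add.at(pairs, idx, 1)
    n_tracks = len(tracks)
    t_values = mass / np.diff(edges) / n_tracks
    return ProximityCurve(
        bin_edges=edges,
        t_values=t_values,
        n_tracks=n_tracks,
        overflow_mass=overflow / n_tracks,
        n_pairs=pairs,
    )


def weighted_proximity(
    curves: list[tuple[ProximityCurve, float]],
) -> ProximityCurve:
    """Convex combination of proximity curves over an energy-fluence spectrum.

    Weights (>= 0, e.g. w_k proportional to E_k * f_k for a spectrum of
    monoenergetic-electron curves) are normalized internally by their sum.
    All curves must share identical bin edges.
    """
    if not curves:
        raise ValueError("need at least one curve")
    weights = np.array([w for _, w in curves], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    weights = weights / weights.sum()
    edges = curves[0][0].bin_edges
    for c, _ in curves[1:]:
        if c.bin_edges.shape != edges.shape or not np.array_equal(c.bin_edges, edges):
            raise ValueError("all curves must share identical bin edges")
    t = sum(w * c.t_values for (c, _), w in zip(curves, weights))
    overflow = sum(w * c.overflow_mass for (c, _), w in zip(curves, weights))
    n_tracks = int(sum(c.n_tracks for c, _ in curves))
    return ProximityCurve(bin_edges=edges, t_values=t, n_tracks=n_tracks, overflow_mass=float(overflow))


def add_dose_term(curve: ProximityCurve, rho: float, dose_gy: float) -> ProximityCurve:
    """Add the inter-track dose term 4 pi x^2 rho D to t(x), giving t_D(x).

    ``rho`` is in g/cm^3 and ``dose_gy`` in Gy; the term is evaluated at
    each bin representative and converted to keV/um.
    """
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    x = curve.bin_centers
    term = 4.0 * np.pi * x**2 * rho * dose_gy * GY_GCC_TO_KEV_PER_UM3
    return replace(curve, t_values=curve.t_values + term)


def event_proximity_integral(event, a: float) -> float:
    """E * integral(t_ev(x) e^(-x/a) dx) for one event, in keV^2.

    ``t_ev`` is the proximity function of the event's nucleus deposits,
    normalized by the nucleus energy E; the integral is evaluated as the
    exact ordered-pair sum sum_{i!=j} eps_i eps_j e^(-x_ij/a) / T with
    T = E, then multiplied by E (no binning, no discretization error).
    Events with fewer than two nucleus deposits contribute 0.
    """
    if a <= 0:
        raise ValueError(f"distance-model parameter a must be positive, got {a}")
    energies = np.asarray(event.nucleus_energies, dtype=float)
    if energies.size < 2:
        return 0.0
    positions = np.asarray(event.nucleus_positions, dtype=float)
    d = pdist(positions)
    i, j = np.triu_indices(energies.size, k=1)
    w = 2.0 * energies[i] * energies[j]
    t_total = float(energies.sum())
    pair_sum = float(np.sum(w * np.exp(-d / a))) / t_total
    return float(event.energy_kev) * pair_sum
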