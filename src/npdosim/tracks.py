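"""Synthetic track-structure generator.

Emulates the Monte-Carlo outputs the analysis pipeline consumes, without
doing particle transport: per-ionization Auger-cascade deposit clouds
around a nanoparticle, single secondary-electron tracks in water for the
reference proximity function, and the per-event spectrum of energy
imparted to the nucleus (which carries a point mass at E = 0 when all
electrons miss the nucleus).

The physics is deliberately a toy: each emitted electron travels on a
straight, isotropically oriented segment of length R = b * E^p (a
power-law range-energy relation), laying down a fixed number of energy
transfers whose spatial density increases toward the track end (track-end
clustering) and whose energies sum exactly to the electron energy. This
preserves the spatial-statistical features the microdosimetric estimators
respond to — short-range clustering, isotropy, energy conservation — while
making every run cheap and bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import CellModel, NPPlacement, deposits_in_nucleus, sample_np_positions

__all__ = [
    "CascadeModel",
    "EventRecord",
    "EnergySpectrum",
    "generate_cascade_event",
    "generate_water_track",
    "simulate_exposure",
]


@dataclass(frozen=True)
class CascadeModel:
    """Parameters of the toy Auger-cascade / electron-track generator.

    Attributes
    ----------
    n_auger : float
        Mean number of Auger electrons per NP ionization (Poisson).
    auger_energy : float
        Exponential scale of the Auger electron energies, keV.
    photoelectron_energy : float
        Exponential scale of the fast (photo/Compton) electron energy, keV.
    photoelectron_emission_prob : float
        Fraction of ionization events that emit a fast electron.
    range_coeff, range_exp : float
        Range-energy law R = range_coeff * E**range_exp (R in um, E keV).
    deposits_per_electron : int
        Number of discrete energy transfers along each electron track.
    self_absorption_prob : float
        Probability that an electron is absorbed inside the NP and
        contributes nothing (Bernoulli thinning standing in for in-NP
        transport; larger for bigger NPs).
    """

    n_auger: float = 4.0
    auger_energy: float = 1.0
    photoelectron_energy: float = 30.0
    photoelectron_emission_prob: float = 0.9
    range_coeff: float = 0.04
    range_exp: float = 1.7
    deposits_per_electron: int = 20
    self_absorption_prob: float = 0.1

    def __post_init__(self) -> None:
        if min(self.n_auger, self.auger_energy, self.photoelectron_energy,
               self.range_coeff, self.range_exp) <= 0:
            raise ValueError("scales and range-law parameters must be positive")
        for p in (self.photoelectron_emission_prob, self.self_absorption_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if self.deposits_per_electron < 1:
            raise ValueError("deposits_per_electron must be >= 1")

    def electron_range(self, energy_kev: float) -> float:
        """Track length in um for an electron of the given energy."""
        return self.range_coeff * energy_kev**self.range_exp


def _electron_track(
    energy_kev: float, model: CascadeModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Straight toy track from the origin: (k, 3) positions, (k,) energies.

    Deposit j sits at fractional arc length sqrt((j - 1/2)/k), so the
    linear density of transfer points grows toward the track end while the
    per-transfer energies are equal shares E/k (sum exact).
    """
    k = model.deposits_per_electron
    cos_t = rng.uniform(-1.0, 1.0)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    sin_t = np.sqrt(1.0 - cos_t**2)
    direction = np.array([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    r = model.electron_range(energy_kev)
    frac = np.sqrt((np.arange(k) + 0.5) / k)
    positions = np.outer(r * frac, direction)
    energies = np.full(k, energy_kev / k)
    return positions, energies


def generate_cascade_event(
    model: CascadeModel, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Deposits from one NP ionization, in the NP-local frame.

    Draws 0 or 1 fast electron plus a Poisson number of Auger electrons,
    thins each by the self-absorption probability, and lays down a toy
    track per surviving electron. Returns ``(positions, energies)``;
    the energies sum exactly to the summed emitted-electron energies.
    """
    rng = np.random.default_rng(rng)
    electron_energies: list[float] = []
    if rng.random() < model.photoelectron_emission_prob:
        electron_energies.append(rng.exponential(model.photoelectron_energy))
    n_aug = rng.poisson(model.n_auger)
    electron_energies.extend(rng.exponential(model.auger_energy, n_aug))

    positions, energies = [], []
    for e in electron_energies:
        if rng.random() < model.self_absorption_prob:
            continue
        p, w = _electron_track(e, model, rng)
        positions.append(p)
        energies.append(w)
    if not positions:
        return np.empty((0, 3)), np.empty(0)
    return np.concatenate(positions), np.concatenate(energies)


def generate_water_track(
    e0_kev: float, model: CascadeModel, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """A single secondary-electron track in water (track-local frame)."""
    if e0_kev <= 0:
        raise ValueError(f"electron energy must be positive, got {e0_kev}")
    rng = np.random.default_rng(rng)
    return _electron_track(e0_kev, model, rng)


@dataclass(frozen=True)
class EventRecord:
    """One NP-ionization event scored against the nucleus.

    ``positions`` / ``energies`` are all deposits in the NP-local frame;
    ``nucleus_positions`` / ``nucleus_energies`` the subset inside the
    nucleus, re-expressed in the nucleus frame. ``energy_kev`` is the total
    energy imparted to the nucleus (E) and ``z_gy`` the specific energy
    E / m_nucleus.
    """

    event_id: int
    np_position: np.ndarray = field(repr=False)
    positions: np.ndarray = field(repr=False)
    energies: np.ndarray = field(repr=False)
    nucleus_positions: np.ndarray = field(repr=False)
    nucleus_energies: np.ndarray = field(repr=False)
    energy_kev: float
    z_gy: float


# 1 keV in joules (CODATA); the only energy-unit bridge used for z.
KEV_TO_J = 1.602176634e-16


@dataclass(frozen=True)
class EnergySpectrum:
    """Per-event nucleus energies E (keV), zeros included.

    The point mass at E = 0 collects the events whose electrons all miss
    the nucleus; it shrinks as NPs sit closer to the nucleus.
    """

    energies_kev: np.ndarray = field(repr=False)
    m_nucleus_kg: float

    @property
    def n_events(self) -> int:
        return self.energies_kev.size

    @property
    def zero_fraction(self) -> float:
        return float(np.mean(self.energies_kev == 0.0))

    @property
    def e_bar_kev(self) -> float:
        """Mean energy to the nucleus per ionization, zeros included."""
        return float(np.mean(self.energies_kev))

    @property
    def z_bar_gy(self) -> float:
        """Mean specific energy per ionization, Gy."""
        return self.e_bar_kev * KEV_TO_J / self.m_nucleus_kg

    def histogram(self, bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
        """Histogram of the nonzero part of the spectrum."""
        nz = self.energies_kev[self.energies_kev > 0]
        return np.histogram(nz, bins=bins)


def simulate_exposure(
    scenario: str,
    cell: CellModel,
    n_events: int,
    model: CascadeModel | None = None,
    rng: np.random.Generator | int | None = None,
    np_radius: float = 0.025,
) -> tuple[list[EventRecord], EnergySpectrum]:
    """Simulate ``n_events`` NP-ionization events for one uptake scenario.

    For each event an NP position is sampled per the scenario, a cascade is
    generated in the NP-local frame, and the deposits are translated into
    the nucleus frame and scored (the NP stays fixed relative to the
    nucleus). Events that miss the nucleus are kept with E = 0, so the
    returned spectrum includes the zero point mass.
    """
    if n_events < 1:
        raise ValueError(f"n_events must be >= 1, got {n_events}")
    model = model or CascadeModel()
    rng = np.random.default_rng(rng)
    placement: NPPlacement = sample_np_positions(
        scenario, cell, n_events, rng=rng, np_radius=np_radius
    )
    events: list[EventRecord] = []
    e_values = np.empty(n_events)
    for i in range(n_events):
        pos, en = generate_cascade_event(model, rng)
        np_pos = placement.positions[i]
        nuc_pos, nuc_en = deposits_in_nucleus(pos, en, np_pos, cell)
        e_tot = float(nuc_en.sum())
        e_values[i] = e_tot
        events.append(
            EventRecord(
                event_id=i,
                np_position=np_pos,
                positions=pos,
                energies=en,
                nucleus_positions=nuc_pos,
                nucleus_energies=nuc_en,
                energy_kev=e_tot,
                z_gy=e_tot * KEV_TO_J / cell.m_nucleus,
            )
        )
    spectrum = EnergySpectrum(energies_kev=e_values, m_nucleus_kg=cell.m_nucleus)
    return events, spectrum


def model_metadata(model: CascadeModel) -> dict:
    """JSON-serializable dump of the generator parameters."""
    return asdict(model)
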