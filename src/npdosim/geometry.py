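"""Spherical cell/nucleus geometry and nanoparticle placement.

Cells are modeled as two concentric spheres (cell membrane and nucleus)
centered at the origin. Nanoparticles (NPs) are placed according to one of
three uptake scenarios: uniformly in the whole cell, uniformly in the
cytoplasmic shell, or on the outside of the nuclear membrane. Energy
deposits produced in an NP-local frame are scored against the nucleus by
translating them (never rotating) into the nucleus frame, with the NP kept
at its sampled position relative to the nucleus center.

All lengths are micrometres; coordinates are right-handed Cartesian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellModel",
    "NPPlacement",
    "SCENARIOS",
    "sample_np_positions",
    "deposits_in_nucleus",
]

#: Valid NP-distribution scenario labels.
SCENARIOS = ("whole_cell", "cytoplasm", "nuclear_membrane")

# 1 um^3 of unit-density (1 g/cm^3) material weighs 1e-15 kg.
KG_PER_UM3_PER_GCC = 1.0e-15


@dataclass(frozen=True)
class CellModel:
    """Concentric-sphere cell model.

    Parameters
    ----------
    r_cell : float
        Cell radius in um.
    r_nucleus : float
        Nucleus radius in um; must satisfy 0 < r_nucleus < r_cell.
    rho : float
        Density of the nucleus material in g/cm^3 (water default 1.0).
    eta : float
        Effective DNA volume fraction of the nucleus. Carried for
        completeness; it cancels in every exported ratio and is never
        needed numerically.
    """

    r_cell: float
    r_nucleus: float
    rho: float = 1.0
    eta: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.r_nucleus < self.r_cell):
            raise ValueError(
                f"need 0 < r_nucleus < r_cell, got {self.r_nucleus}, {self.r_cell}"
            )
        if self.rho <= 0.0:
            raise ValueError(f"density must be positive, got {self.rho}")
        if not (0.0 < self.eta <= 1.0):
            raise ValueError(f"eta must be in (0, 1], got {self.eta}")

    @property
    def v_nucleus(self) -> float:
        """Nucleus volume in um^3."""
        return (4.0 / 3.0) * np.pi * self.r_nucleus**3

    @property
    def m_nucleus(self) -> float:
        """Nucleus mass in kg."""
        return self.rho * KG_PER_UM3_PER_GCC * self.v_nucleus


@dataclass(frozen=True)
class NPPlacement:
    """A batch of NP center positions for one uptake scenario.

    ``positions`` is an (n, 3) array of NP centers in um relative to the
    cell (= nucleus) center.
    """

    scenario: str
    np_radius: float
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return self.positions.shape[0]


def _uniform_in_shell(rng: np.random.Generator, n: int, r_lo: float, r_hi: float) -> np.ndarray:
    """Sample uniformly in volume between radii r_lo and r_hi (radial CDF)."""
    u = rng.random(n)
    r = (r_lo**3 + u * (r_hi**3 - r_lo**3)) ** (1.0 / 3.0)
    return r[:, None] * _isotropic_directions(rng, n)


def _isotropic_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    cos_t = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    return np.column_stack((sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t))


def sample_np_positions(
    scenario: str,
    cell: CellModel,
    count: int,
    rng: np.random.Generator | int | None = None,
    np_radius: float = 0.025,
) -> NPPlacement:
    """Sample NP center positions for an uptake scenario.

    Scenarios: ``whole_cell`` and ``cytoplasm`` sample uniformly in volume
    (by the radial CDF); ``nuclear_membrane`` places NP centers on the
    sphere of radius ``r_nucleus + np_radius`` (NPs touching the membrane
    from outside), isotropically.

    Parameters
    ----------
    scenario : {"whole_cell", "cytoplasm", "nuclear_membrane"}
    cell : CellModel
    count : int
        Number of NP positions (>= 1).
    rng : numpy Generator, int seed, or None
    np_radius : float
        NP radius in um (default 0.025 = 25 nm, a 50 nm AuNP).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    rng = np.random.default_rng(rng)
    if scenario == "whole_cell":
        pos = _uniform_in_shell(rng, count, 0.0, cell.r_cell)
    elif scenario == "cytoplasm":
        pos = _uniform_in_shell(rng, count, cell.r_nucleus, cell.r_cell)
    else:
        r = cell.r_nucleus + np_radius
        pos = r * _isotropic_directions(rng, count)
    return NPPlacement(scenario=scenario, np_radius=np_radius, positions=pos)


def deposits_in_nucleus(
    positions: np.ndarray,
    energies: np.ndarray,
    np_position: np.ndarray,
    cell: CellModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Select the energy deposits that fall inside the nucleus.

    ``positions`` are NP-local deposit coordinates (um, the ionized NP at
    the origin); ``np_position`` is the NP center relative to the nucleus
    center. Deposits are translated into the nucleus frame and kept when
    ``|d + np_position| <= r_nucleus``. Energies are untouched and order
    is preserved, so the operation is idempotent.

    Returns ``(nucleus_positions, nucleus_energies)`` with the positions
    expressed in the nucleus frame.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    energies = np.asarray(energies, dtype=float)
    if positions.shape[0] == 0:
        return positions.reshape(0, 3), energies[:0]
    nucleus_frame = positions + np.asarray(np_position, dtype=float)
    keep = np.einsum("ij,ij->i", nucleus_frame, nucleus_frame) <= cell.r_nucleus**2
    return nucleus_frame[keep], energies[keep]
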