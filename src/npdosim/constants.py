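"""Packaged reference constants and fixture tables.

Cell and nanoparticle presets, per-ionization exposure coefficients
(lambda, mu, and their product p1Gy, the expected number of NP ionizations
per NP per Gy of dose to the surrounding water), published linear-quadratic
survival parameters with and without NPs, per-scenario mean specific
energies to the nucleus, and the printed table values used by the
``reproduce-tables`` check.

The single energy-unit conversion owned by the package lives in
:mod:`npdosim.proximity` (keV <-> J); this module only carries data.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .geometry import CellModel

__all__ = [
    "load_data",
    "cell_preset",
    "np_preset",
    "exposure_coefficients",
    "survival_fixture",
    "specific_energy",
    "printed_tables",
    "list_fixtures",
]


@lru_cache(maxsize=None)
def load_data(name: str) -> dict:
    """Load a packaged JSON data file by stem name (e.g. ``"cells"``)."""
    ref = resources.files("npdosim.data").joinpath(f"{name}.json")
    return json.loads(ref.read_text(encoding="utf-8"))


def cell_preset(name: str) -> CellModel:
    """Cell model preset: one of SQ20B, Hela, A549."""
    cells = load_data("cells")
    try:
        d = cells[name]
    except KeyError:
        raise KeyError(f"unknown cell preset {name!r}; available: {sorted(cells)}") from None
    return CellModel(r_cell=d["r_cell"], r_nucleus=d["r_nucleus"], rho=d["rho"], name=name)


def np_preset(name: str) -> dict:
    """Nanoparticle preset (diameter in nm, density in g/cm^3)."""
    nps = load_data("nanoparticles")
    try:
        return dict(nps[name])
    except KeyError:
        raise KeyError(f"unknown NP preset {name!r}; available: {sorted(nps)}") from None


def exposure_coefficients(np_name: str, beam: str) -> dict:
    """lambda, mu, p1Gy (with uncertainties) for an NP/beam combination."""
    table = load_data("exposures")
    try:
        return dict(table[np_name][beam])
    except KeyError:
        beams = {k: sorted(v) for k, v in table.items()}
        raise KeyError(
            f"no exposure coefficients for ({np_name!r}, {beam!r}); available: {beams}"
        ) from None


def survival_fixture(fixture_id: str) -> dict:
    """One published LQ parameter set (alpha/beta with and without NPs)."""
    table = load_data("survival_fixtures")
    try:
        return dict(table[fixture_id])
    except KeyError:
        raise KeyError(
            f"unknown survival fixture {fixture_id!r}; available: {sorted(table)}"
        ) from None


def list_fixtures() -> list[str]:
    return sorted(load_data("survival_fixtures"))


def specific_energy(np_name: str, scenario: str) -> float:
    """Mean specific energy to the nucleus (Gy) per NP ionization."""
    table = load_data("specific_energy")
    return table[np_name]["z_bar_Gy"][scenario]


def printed_tables() -> dict:
    """Printed reference values used by the reproduce-tables check."""
    return load_data("printed_tables")
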