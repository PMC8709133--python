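"""File formats: deposit CSV, spectrum CSV, proximity CSV, results JSON.

Deposit files are plain CSV with one row per energy transfer
(``event_id,frame,x_um,y_um,z_um,edep_keV``) plus a JSON sidecar holding
the run metadata (seed, scenario, generator parameters, nucleus mass), so
a simulation output is self-describing and round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .proximity import ProximityCurve

__all__ = [
    "write_deposits_csv",
    "read_deposits_csv",
    "write_sidecar",
    "read_sidecar",
    "write_spectrum_csv",
    "write_proximity_csv",
    "read_proximity_csv",
    "write_results_json",
]

DEPOSIT_COLUMNS = ["event_id", "frame", "x_um", "y_um", "z_um", "edep_keV"]


def write_deposits_csv(events: list, path: str | Path, frame: str = "np_local") -> None:
    """Write per-event deposits to CSV (all deposits, NP-local frame by default).

    ``frame="nucleus"`` writes the nucleus-scored subset in the nucleus
    frame instead. Events without deposits in the chosen frame simply
    contribute no rows (their E = 0 lives in the sidecar/spectrum).
    """
    rows = []
    for ev in events:
        if frame == "np_local":
            pos, en = ev.positions, ev.energies
        elif frame == "nucleus":
            pos, en = ev.nucleus_positions, ev.nucleus_energies
        else:
            raise ValueError(f"unknown frame {frame!r}")
        for p, e in zip(pos, en):
            rows.append((ev.event_id, frame, p[0], p[1], p[2], e))
    df = pd.DataFrame(rows, columns=DEPOSIT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_deposits_csv(path: str | Path) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Read a deposit CSV into ``{event_id: (positions, energies)}``."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(DEPOSIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"deposit CSV missing columns: {sorted(missing)}")
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for ev_id, grp in df.groupby("event_id", sort=True):
        out[int(ev_id)] = (
            grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
            grp["edep_keV"].to_numpy(dtype=float),
        )
    return out


def write_sidecar(path: str | Path, metadata: dict) -> None:
    Path(path).write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")


def read_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_spectrum_csv(spectrum, path: str | Path, bins: int = 50) -> None:
    """Histogram of the nonzero nucleus-energy spectrum plus summary row.

    Columns: ``E_lo_keV,E_hi_keV,count``; the zero fraction and means are
    stored as commented header lines so the CSV stays a single table.
    """
    counts, edges = spectrum.histogram(bins=bins)
    header = (
        f"# n_events = {spectrum.n_events}\n"
        f"# zero_fraction = {spectrum.zero_fraction:.17g}\n"
        f"# E_bar_keV = {spectrum.e_bar_kev:.17g}\n"
        f"# z_bar_Gy = {spectrum.z_bar_gy:.17g}\n"
    )
    df = pd.DataFrame({"E_lo_keV": edges[:-1], "E_hi_keV": edges[1:], "count": counts})
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.17g")


def write_proximity_csv(curve: ProximityCurve, path: str | Path) -> None:
    """Columns: ``x_lo_um,x_hi_um,t_keV_per_um,n_pairs``."""
    n_pairs = curve.n_pairs if curve.n_pairs is not None else np.zeros(curve.t_values.size, int)
    df = pd.DataFrame(
        {
            "x_lo_um": curve.bin_edges[:-1],
            "x_hi_um": curve.bin_edges[1:],
            "t_keV_per_um": curve.t_values,
            "n_pairs": n_pairs,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# n_tracks = {curve.n_tracks}\n")
        fh.write(f"# overflow_mass_keV = {curve.overflow_mass:.17g}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_proximity_csv(path: str | Path) -> ProximityCurve:
    n_tracks, overflow = 1, 0.0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition("=")
            key = key.strip()
            if key == "n_tracks":
                n_tracks = int(value)
            elif key == "overflow_mass_keV":
                overflow = float(value)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    edges = np.append(df["x_lo_um"].to_numpy(), df["x_hi_um"].iloc[-1])
    return ProximityCurve(
        bin_edges=edges,
        t_values=df["t_keV_per_um"].to_numpy(),
        n_tracks=n_tracks,
        overflow_mass=overflow,
        n_pairs=df["n_pairs"].to_numpy(),
    )


def write_results_json(path: str | Path, results: dict) -> None:
    Path(path).write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")
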