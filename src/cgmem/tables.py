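"""TSV/CSV serialization for profiles, spectra, series, surfaces and windows.

All tables carry unit-suffixed column names in the header row and round-trip
floats at full precision.  Column order is free (parsing is by header name);
a missing or unit-mismatched column is refused with a clear error.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TableFormatError
from .membrane import FluctuationSpectrum, InsertionSeries, UndulationSurface
from .pmf import PMFProfile, UmbrellaWindow

__all__ = [
    "write_pmf_profile",
    "read_pmf_profile",
    "write_spectrum",
    "read_spectrum",
    "write_insertion_series",
    "read_insertion_series",
    "write_surface",
    "read_surface",
    "write_window",
    "read_window",
    "write_windows_manifest",
    "read_windows_manifest",
]

_FMT = "%.17g"


def _read_table(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing/unit-mismatched columns {missing}; found {list(df.columns)}"
        )
    return df


def _write_table(path, columns: dict):
    df = pd.DataFrame(columns)
    df.to_csv(path, sep="\t", index=False, float_format=_FMT)


# -- PMF profiles -----------------------------------------------------------

def write_pmf_profile(path, profile: PMFProfile):
    cols = {
        "z_nm": profile.z_grid,
        "free_energy_kJ_per_mol": profile.free_energy,
    }
    if profile.error is not None:
        cols["error_kJ_per_mol"] = profile.error
    _write_table(path, cols)


def read_pmf_profile(path) -> PMFProfile:
    df = _read_table(path, ["z_nm", "free_energy_kJ_per_mol"])
    err = df["error_kJ_per_mol"].to_numpy() if "error_kJ_per_mol" in df.columns else None
    return PMFProfile(df["z_nm"].to_numpy(), df["free_energy_kJ_per_mol"].to_numpy(), error=err)


# -- spectra ----------------------------------------------------------------

def write_spectrum(path, spec: FluctuationSpectrum):
    _write_table(
        path,
        {
            "q_per_nm": spec.q_values,
            "intensity_nm4": spec.intensity,
            "stderr_nm4": spec.stderr,
            "n_frames": np.full(len(spec.q_values), spec.n_frames, int),
            "box_edge_nm": np.full(len(spec.q_values), spec.box_edge),
            "grid": np.full(len(spec.q_values), spec.grid, int),
        },
    )


def read_spectrum(path) -> FluctuationSpectrum:
    df = _read_table(path, ["q_per_nm", "intensity_nm4", "stderr_nm4"])
    n_frames = int(df["n_frames"].iloc[0]) if "n_frames" in df.columns else 1
    box_edge = float(df["box_edge_nm"].iloc[0]) if "box_edge_nm" in df.columns else float("nan")
    grid = int(df["grid"].iloc[0]) if "grid" in df.columns else 0
    return FluctuationSpectrum(
        q_values=df["q_per_nm"].to_numpy(),
        intensity=df["intensity_nm4"].to_numpy(),
        stderr=df["stderr_nm4"].to_numpy(),
        n_frames=n_frames,
        box_edge=box_edge,
        grid=grid,
    )


# -- insertion series -------------------------------------------------------

def write_insertion_series(path, s: InsertionSeries):
    _write_table(
        path,
        {
            "time_ps": s.time,
            "inserted_upper": s.inserted_upper,
            "inserted_lower": s.inserted_lower,
            "lipids_upper": s.lipids_upper,
            "lipids_lower": s.lipids_lower,
            "ratio_upper": s.ratio_upper,
            "ratio_lower": s.ratio_lower,
        },
    )


def read_insertion_series(path) -> InsertionSeries:
    df = _read_table(
        path,
        ["time_ps", "inserted_upper", "inserted_lower", "lipids_upper", "lipids_lower"],
    )
    return InsertionSeries(
        time=df["time_ps"].to_numpy(float),
        inserted_upper=df["inserted_upper"].to_numpy(int),
        inserted_lower=df["inserted_lower"].to_numpy(int),
        lipids_upper=df["lipids_upper"].to_numpy(int),
        lipids_lower=df["lipids_lower"].to_numpy(int),
    )


# -- surfaces ---------------------------------------------------------------

def write_surface(path, surface: UndulationSurface):
    """N x N CSV grid plus a JSON sidecar header (<path>.json)."""
    np.savetxt(path, surface.heights, delimiter=",", fmt=_FMT)
    meta = {"box_edge_nm": surface.box_edge, "time_ps": surface.time, "grid": surface.heights.shape[0]}
    Path(str(path) + ".json").write_text(json.dumps(meta))


def read_surface(path) -> UndulationSurface:
    heights = np.loadtxt(path, delimiter=",")
    meta = json.loads(Path(str(path) + ".json").read_text())
    return UndulationSurface(heights=heights, box_edge=meta["box_edge_nm"], time=meta.get("time_ps", 0.0))


# -- umbrella windows -------------------------------------------------------

def write_window(path, w: UmbrellaWindow):
    _write_table(path, {"time_ps": np.arange(len(w.samples), dtype=float), "z_nm": w.samples})


def read_window(path, center: float, spring_k: float, temperature: float) -> UmbrellaWindow:
    df = _read_table(path, ["z_nm"])
    return UmbrellaWindow(center=center, spring_k=spring_k, samples=df["z_nm"].to_numpy(), temperature=temperature)


def write_windows_manifest(path, windows: list[UmbrellaWindow], paths: list[str]):
    _write_table(
        path,
        {
            "path": paths,
            "center_nm": [w.center for w in windows],
            "spring_k_kJ_per_mol_nm2": [w.spring_k for w in windows],
            "temperature_K": [w.temperature for w in windows],
        },
    )


def read_windows_manifest(path) -> list[UmbrellaWindow]:
    df = _read_table(path, ["path", "center_nm", "spring_k_kJ_per_mol_nm2", "temperature_K"])
    base = Path(path).parent
    out = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        out.append(
            read_window(p, float(row["center_nm"]), float(row["spring_k_kJ_per_mol_nm2"]), float(row["temperature_K"]))
        )
    return out
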