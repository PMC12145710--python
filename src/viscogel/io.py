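"""File I/O and run configuration shared by all modules.

Dialects (see FORMATS.md): mechanical curves as CSV with header
``time_s,strain,stress_Pa``; calibration tables as CSV with lumped-parameter
or descriptor columns; structured reports as JSON; configuration as YAML with
sections ``asls``, ``transport``, ``grid``, ``fit``, ``design``, ``noise``.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from viscogel.design import CalibrationRow, CalibrationTable
from viscogel.errors import ConfigError, ParseError
from viscogel.mechanics import ASLSParams, MechanicalCurve, ViscoelasticDescriptors
from viscogel.transport import GridSpec, SimulationResult, TransportParams

__all__ = [
    "read_mechanical_curve",
    "write_mechanical_curve",
    "read_calibration_table",
    "write_calibration_table",
    "write_simulation_traces",
    "load_config",
]

CURVE_COLUMNS = ("time_s", "strain", "stress_Pa")

_CONFIG_SECTIONS = {"asls", "transport", "grid", "fit", "design", "noise"}
_SECTION_KEYS: dict[str, set[str]] = {
    "asls": {"E0", "E1", "eta1", "eta2", "phi"},
    "transport": {"r_h", "kappa", "mu", "T", "p", "alpha", "k_r", "c0"},
    "grid": {"extents", "n", "boundary", "bc_value"},
    "fit": {"initial_guess", "bounds", "tol", "max_iter", "n_starts", "seed"},
    "design": {"tau_b", "tau_L_min", "tau_L_max", "E_low", "E_high", "label", "regime"},
    "noise": {"kind", "level", "seed"},
}

_PARAM_COLUMNS = ["agarose_mg_ml", "dextran_mg_ml", "E0_Pa", "E1_Pa", "eta1_Pa_s", "eta2_Pa_s", "phi"]
_DESCRIPTOR_COLUMNS = ["agarose_mg_ml", "dextran_mg_ml", "E_eq_Pa", "E_inst_Pa", "tau_rel_s"]


def read_mechanical_curve(path: str | Path, strain_rate: float | None = None) -> MechanicalCurve:
    """Read one curve from CSV (``time_s,strain,stress_Pa``).

    When the strain column is absent it is reconstructed as ``strain_rate*t``
    (requires ``strain_rate``) and flagged in the curve metadata.  When
    ``strain_rate`` is not given it is estimated from the strain column slope.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    if "time_s" not in df.columns or "stress_Pa" not in df.columns:
        raise ParseError(
            f"{path}: header must contain time_s and stress_Pa, got {list(df.columns)}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)):
        bad = int(np.flatnonzero(~np.isfinite(t))[0]) + 2  # +2: header + 1-based
        raise ParseError(f"{path}: non-finite time at line {bad}")
    if np.any(np.diff(t) <= 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 3
        raise ParseError(f"{path}: time not strictly increasing at line {bad}")
    stress = df["stress_Pa"].to_numpy(dtype=float)
    meta: dict[str, Any] = {"source": str(path)}
    if "strain" in df.columns:
        strain = df["strain"].to_numpy(dtype=float)
        if strain_rate is None:
            pos = t > 0
            strain_rate = float(np.median(strain[pos] / t[pos])) if pos.any() else 0.0
    else:
        if strain_rate is None:
            raise ParseError(f"{path}: no strain column and no strain_rate provided")
        strain = strain_rate * t
        meta["strain_reconstructed"] = True
    try:
        return MechanicalCurve(
            time=t, strain=strain, stress=stress, strain_rate=float(strain_rate), metadata=meta
        )
    except Exception as exc:
        raise ParseError(f"{path}: invalid curve ({exc})") from exc


def write_mechanical_curve(curve: MechanicalCurve, path: str | Path) -> None:
    """Write a curve as ``time_s,strain,stress_Pa`` CSV with full precision."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CURVE_COLUMNS)
        for t, e, s in zip(curve.time, curve.strain, curve.stress):
            w.writerow([repr(float(t)), repr(float(e)), repr(float(s))])


def read_calibration_table(path: str | Path) -> CalibrationTable:
    """Read a calibration CSV with lumped-parameter or descriptor columns."""
    path = Path(path)
    df = pd.read_csv(path)
    cols = set(df.columns)
    rows: list[CalibrationRow] = []
    if set(_PARAM_COLUMNS) <= cols:
        for r in df.itertuples(index=False):
            params = ASLSParams(
                E0=float(r.E0_Pa), E1=float(r.E1_Pa),
                eta1=float(r.eta1_Pa_s), eta2=float(r.eta2_Pa_s), phi=float(r.phi),
            )
            rows.append(CalibrationRow(
                agarose_conc=float(r.agarose_mg_ml), dextran_conc=float(r.dextran_mg_ml),
                params=params,
            ))
    elif set(_DESCRIPTOR_COLUMNS) <= cols:
        has_eapp = "E_app_Pa" in cols
        for r in df.itertuples(index=False):
            desc = ViscoelasticDescriptors(
                E_eq=float(r.E_eq_Pa), E_inst=float(r.E_inst_Pa), tau_rel=float(r.tau_rel_s),
                E_app=float(r.E_app_Pa) if has_eapp and np.isfinite(r.E_app_Pa) else None,
            )
            rows.append(CalibrationRow(
                agarose_conc=float(r.agarose_mg_ml), dextran_conc=float(r.dextran_mg_ml),
                descriptors=desc,
            ))
    else:
        raise ParseError(
            f"{path}: need columns {_PARAM_COLUMNS} or {_DESCRIPTOR_COLUMNS}, got {sorted(cols)}"
        )
    return CalibrationTable(rows=tuple(rows))


def write_calibration_table(table: CalibrationTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        if all(r.params is not None for r in table.rows):
            w.writerow(_PARAM_COLUMNS)
            for r in table.rows:
                p = r.params
                w.writerow([r.agarose_conc, r.dextran_conc, p.E0, p.E1, p.eta1, p.eta2, p.phi])
        else:
            w.writerow(_DESCRIPTOR_COLUMNS + ["E_app_Pa"])
            for r in table.rows:
                d = r.resolved_descriptors()
                w.writerow([
                    r.agarose_conc, r.dextran_conc, d.E_eq, d.E_inst, d.tau_rel,
                    "" if d.E_app is None else d.E_app,
                ])


def write_simulation_traces(result: SimulationResult, path: str | Path) -> None:
    """Write the scalar traces as ``time_s,total_mass_mg,D_app_m2s,xi_m`` CSV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "total_mass_mg", "D_app_m2s", "xi_m"])
        for t, m, d, xi in zip(result.times, result.total_mass, result.D_app_trace, result.xi_trace):
            w.writerow([repr(float(t)), repr(float(m)), repr(float(d)), repr(float(xi))])


def _check_section(name: str, block: Any) -> dict:
    if not isinstance(block, dict):
        raise ConfigError(f"config section {name!r} must be a mapping")
    unknown = set(block) - _SECTION_KEYS[name]
    if unknown:
        raise ConfigError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    return block


def load_config(path: str | Path) -> dict:
    """Load and schema-validate a YAML run configuration.

    Unknown top-level sections or keys are rejected before any computation.
    Returns a dict with instantiated objects under ``asls`` (:class:`ASLSParams`),
    ``transport`` (:class:`TransportParams`) and ``grid`` (:class:`GridSpec`)
    when those sections are present; other sections stay as plain dicts.
    """
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _CONFIG_SECTIONS
    if unknown:
        raise ConfigError(f"{path}: unknown sections {sorted(unknown)}")

    out: dict[str, Any] = {}
    if "asls" in raw:
        out["asls"] = ASLSParams(**_check_section("asls", raw["asls"]))
    if "transport" in raw:
        out["transport"] = TransportParams(**_check_section("transport", raw["transport"]))
    if "grid" in raw:
        g = _check_section("grid", raw["grid"])
        out["grid"] = GridSpec(
            extents=tuple(g["extents"]), n=tuple(g["n"]),
            boundary=g.get("boundary", "no-flux"), bc_value=g.get("bc_value", 0.0),
        )
    for name in ("fit", "design", "noise"):
        if name in raw:
            out[name] = _check_section(name, raw[name])
    return out
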