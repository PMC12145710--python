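"""Deborah-number substrate design: regime classification and formulation selection.

The cell-perceived Deborah number is ``De = tau_rel / tau_L``: the ratio of the
substrate relaxation time to the focal-adhesion lifetime.  A formulation is
classified structurally against the cell sensing window (tau_b, tau_L_max]:
gels relaxing before adhesions form (tau_rel <= tau_b) read as static
equilibrium substrates (De < 1); gels relaxing inside the window read as
time-varying (De ~ 1); slower gels read as static instantaneous substrates
(De > 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from typing import Literal

from viscogel.errors import DomainError, InsufficientDataError
from viscogel.mechanics import ASLSParams, ViscoelasticDescriptors, descriptors_from_params

__all__ = [
    "Regime",
    "CellSensingWindow",
    "DeborahAssessment",
    "CalibrationRow",
    "CalibrationTable",
    "TissueTarget",
    "deborah_number",
    "classify_regime",
    "classify_regime_by_band",
    "assess",
    "select_agarose_concentration",
    "select_dextran_concentration",
    "design_report",
]


class Regime(str, Enum):
    BELOW_ONE = "below_one"
    NEAR_ONE = "near_one"
    ABOVE_ONE = "above_one"


@dataclass(frozen=True)
class CellSensingWindow:
    """Focal-adhesion timescales bounding the cell's mechanical sensing window.

    ``tau_b`` is the adhesion binding time; ``tau_L_min``/``tau_L_max`` bound
    the adhesion lifetime.
    """

    tau_b: float = 1.0
    tau_L_min: float = 10.0
    tau_L_max: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.tau_b <= self.tau_L_min <= self.tau_L_max:
            raise DomainError(
                f"need 0 < tau_b <= tau_L_min <= tau_L_max, got "
                f"({self.tau_b!r}, {self.tau_L_min!r}, {self.tau_L_max!r})"
            )


@dataclass(frozen=True)
class DeborahAssessment:
    """De evaluated over the sensing window plus the regime label."""

    De_point: float
    De_range: tuple[float, float]
    regime: Regime

    def __post_init__(self) -> None:
        if self.De_range[0] > self.De_range[1]:
            raise DomainError("De_range must be ascending")

    def as_dict(self) -> dict:
        return {
            "De_point": self.De_point,
            "De_range": list(self.De_range),
            "regime": self.regime.value,
        }


@dataclass(frozen=True)
class CalibrationRow:
    """One calibrated formulation: composition plus its mechanical description."""

    agarose_conc: float  # mg/mL
    dextran_conc: float  # mg/mL
    params: ASLSParams | None = None
    descriptors: ViscoelasticDescriptors | None = None

    def __post_init__(self) -> None:
        if self.agarose_conc < 0 or self.dextran_conc < 0:
            raise DomainError("concentrations must be >= 0")
        if self.params is None and self.descriptors is None:
            raise DomainError("row needs ASLSParams or ViscoelasticDescriptors")

    def resolved_descriptors(self) -> ViscoelasticDescriptors:
        if self.descriptors is not None:
            return self.descriptors
        return descriptors_from_params(self.params)


@dataclass(frozen=True)
class CalibrationTable:
    """Calibrated formulations keyed by (agarose, dextran) concentration."""

    rows: tuple[CalibrationRow, ...]

    def __post_init__(self) -> None:
        keys = [(r.agarose_conc, r.dextran_conc) for r in self.rows]
        if len(set(keys)) != len(keys):
            raise DomainError("duplicate (agarose, dextran) keys in calibration table")

    def __len__(self) -> int:
        return len(self.rows)

    def at_agarose(self, agarose_conc: float, rel_tol: float = 1e-9) -> list[CalibrationRow]:
        return [
            r
            for r in self.rows
            if math.isclose(r.agarose_conc, agarose_conc, rel_tol=rel_tol, abs_tol=1e-12)
        ]


@dataclass(frozen=True)
class TissueTarget:
    """Stiffness band [Pa] of the tissue the substrate should mimic."""

    E_low: float
    E_high: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.E_low <= self.E_high:
            raise DomainError(f"need 0 < E_low <= E_high, got ({self.E_low!r}, {self.E_high!r})")


def deborah_number(tau_rel: float, tau_L: float) -> float:
    """Cell-perceived Deborah number ``De = tau_rel / tau_L``."""
    if not tau_L > 0:
        raise DomainError(f"tau_L must be > 0, got {tau_L!r}")
    if tau_rel < 0:
        raise DomainError(f"tau_rel must be >= 0, got {tau_rel!r}")
    return tau_rel / tau_L


def classify_regime(tau_rel: float, window: CellSensingWindow) -> Regime:
    """Structural regime classification against the sensing window.

    ``below_one`` if tau_rel <= tau_b (relaxation over before adhesions form),
    ``near_one`` if tau_b < tau_rel <= tau_L_max (relaxation inside the
    sensing window), ``above_one`` otherwise (including infinite tau_rel).
    Boundary ties go to the lower regime.
    """
    if tau_rel < 0 or math.isnan(tau_rel):
        raise DomainError(f"tau_rel must be >= 0, got {tau_rel!r}")
    if tau_rel <= window.tau_b:
        return Regime.BELOW_ONE
    if tau_rel <= window.tau_L_max:
        return Regime.NEAR_ONE
    return Regime.ABOVE_ONE


def classify_regime_by_band(
    tau_rel: float,
    window: CellSensingWindow,
    band: tuple[float, float] = (0.1, 10.0),
    tau_L: float | None = None,
) -> Regime:
    """Alternative numeric-band classifier on De = tau_rel/tau_L.

    ``De < band[0]`` is below_one, ``band[0] <= De < band[1]`` near_one,
    larger above_one.  ``tau_L`` defaults to the window midpoint lifetime
    sqrt(tau_L_min * tau_L_max).
    """
    if tau_L is None:
        tau_L = math.sqrt(window.tau_L_min * window.tau_L_max)
    De = deborah_number(tau_rel, tau_L)
    if De < band[0]:
        return Regime.BELOW_ONE
    if De < band[1]:
        return Regime.NEAR_ONE
    return Regime.ABOVE_ONE


def assess(tau_rel: float, window: CellSensingWindow) -> DeborahAssessment:
    """Full Deborah assessment: point value at tau_L_max, range over the lifetime span."""
    de_max = deborah_number(tau_rel, window.tau_L_max)  # smallest De
    de_min_lifetime = deborah_number(tau_rel, window.tau_L_min)  # largest De
    return DeborahAssessment(
        De_point=de_max,
        De_range=(de_max, de_min_lifetime),
        regime=classify_regime(tau_rel, window),
    )


def select_agarose_concentration(
    table: CalibrationTable,
    target: TissueTarget,
    *,
    modulus: Literal["E_app", "E_eq"] = "E_app",
    dextran_conc: float = 0.0,
) -> dict:
    """Step 1: agarose concentrations whose modulus falls inside the tissue band.

    Uses ``E_app`` when present on the row's descriptors (falling back to
    ``E_eq``), or ``E_eq`` when requested.  When no row qualifies, a
    monotone-interpolated concentration suggestion is returned with
    ``interpolated=True``.
    """
    if len(table) == 0:
        raise InsufficientDataError("empty calibration table")
    candidates = [r for r in table.rows if math.isclose(r.dextran_conc, dextran_conc, abs_tol=1e-12)]
    if not candidates:
        candidates = list(table.rows)

    def row_modulus(r: CalibrationRow) -> float:
        d = r.resolved_descriptors()
        if modulus == "E_app" and d.E_app is not None:
            return d.E_app
        return d.E_eq

    scored = sorted(((row_modulus(r), r.agarose_conc) for r in candidates))
    selected = [conc for E, conc in scored if target.E_low <= E <= target.E_high]
    out = {"selected": selected, "interpolated": False, "suggestion": None}
    if not selected and len(scored) >= 2:
        Es = [E for E, _ in scored]
        concs = [c for _, c in scored]
        mid = 0.5 * (target.E_low + target.E_high)
        if Es[0] < mid < Es[-1]:
            # piecewise-linear inverse interpolation on the sorted (E, conc) pairs
            for (E_a, c_a), (E_b, c_b) in zip(scored[:-1], scored[1:]):
                if E_a <= mid <= E_b and E_b > E_a:
                    frac = (mid - E_a) / (E_b - E_a)
                    out["suggestion"] = c_a + frac * (c_b - c_a)
                    out["interpolated"] = True
                    break
    return out


def select_dextran_concentration(
    table: CalibrationTable,
    agarose_conc: float,
    window: CellSensingWindow,
    target_regime: Regime | str,
) -> list[float]:
    """Step 2: dextran concentrations whose tau_rel classifies to the target regime."""
    target_regime = Regime(target_regime)
    rows = table.at_agarose(agarose_conc)
    if not rows:
        raise InsufficientDataError(f"no calibration rows at agarose {agarose_conc} mg/mL")
    return [
        r.dextran_conc
        for r in rows
        if classify_regime(r.resolved_descriptors().tau_rel, window) is target_regime
    ]


def design_report(
    table: CalibrationTable,
    target: TissueTarget,
    window: CellSensingWindow,
) -> dict:
    """Two-step design report: agarose selection, then per-formulation De assessment."""
    if len(table) == 0:
        raise InsufficientDataError("empty calibration table")
    agarose_step = select_agarose_concentration(table, target)

    formulations = []
    for r in table.rows:
        d = r.resolved_descriptors()
        a = assess(d.tau_rel, window)
        formulations.append(
            {
                "agarose_mg_ml": r.agarose_conc,
                "dextran_mg_ml": r.dextran_conc,
                "tau_rel_s": d.tau_rel,
                "E_eq_Pa": d.E_eq,
                "E_inst_Pa": d.E_inst,
                "E_app_Pa": d.E_app,
                **a.as_dict(),
            }
        )

    by_regime: dict[str, list[dict]] = {r.value: [] for r in Regime}
    for f in formulations:
        by_regime[f["regime"]].append(
            {"agarose_mg_ml": f["agarose_mg_ml"], "dextran_mg_ml": f["dextran_mg_ml"]}
        )

    return {
        "tissue_target": {"E_low_Pa": target.E_low, "E_high_Pa": target.E_high, "label": target.label},
        "sensing_window": {
            "tau_b_s": window.tau_b,
            "tau_L_min_s": window.tau_L_min,
            "tau_L_max_s": window.tau_L_max,
        },
        "agarose_selection": agarose_step,
        "formulations": formulations,
        "by_regime": by_regime,
    }


def report_to_text(report: dict) -> str:
    """Human-readable rendering of a design report."""
    lines = []
    tt = report["tissue_target"]
    lines.append(
        f"Tissue target: {tt['label'] or 'unnamed'} [{tt['E_low_Pa']:.0f}-{tt['E_high_Pa']:.0f} Pa]"
    )
    sel = report["agarose_selection"]
    if sel["selected"]:
        lines.append("Agarose concentrations in target band: "
                     + ", ".join(f"{c:g} mg/mL" for c in sel["selected"]))
    elif sel["suggestion"] is not None:
        lines.append(f"No row in band; interpolated suggestion: {sel['suggestion']:.2f} mg/mL")
    else:
        lines.append("No agarose concentration matches the target band.")
    lines.append("Formulations:")
    for f in report["formulations"]:
        lines.append(
            f"  agarose {f['agarose_mg_ml']:g} + dextran {f['dextran_mg_ml']:g} mg/mL: "
            f"tau_rel = {f['tau_rel_s']:.3g} s, De = {f['De_point']:.3g} "
            f"[{f['De_range'][0]:.3g}, {f['De_range'][1]:.3g}] -> {f['regime']}"
        )
    return "\n".join(lines)


def report_to_json(report: dict, indent: int = 2) -> str:
    return json.dumps(report, indent=indent, sort_keys=True)
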