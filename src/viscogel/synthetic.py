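"""Seeded generators for every input the pipeline consumes.

All generators are pure functions of their parameters and a seed, so the full
generate -> fit -> design loop can run with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from viscogel.errors import DomainError
from viscogel.mechanics import ASLSParams, LoadingProtocol, MechanicalCurve, stress_response
from viscogel.transport import ConcentrationField, GridSpec

__all__ = [
    "NoiseModel",
    "generate_epsdot_curves",
    "generate_cell_table",
    "generate_concentration_field",
]


@dataclass(frozen=True)
class NoiseModel:
    """Stress-noise description: multiplicative (relative) or additive (Pa) Gaussian."""

    kind: Literal["multiplicative-gaussian", "additive-gaussian"] = "multiplicative-gaussian"
    level: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level < 0:
            raise DomainError(f"noise level must be >= 0, got {self.level!r}")
        if self.kind not in ("multiplicative-gaussian", "additive-gaussian"):
            raise DomainError(f"unknown noise kind {self.kind!r}")


def generate_epsdot_curves(
    params: ASLSParams,
    protocols: Sequence[LoadingProtocol] | LoadingProtocol,
    noise: NoiseModel | None = None,
    n_replicates: int = 1,
) -> list[MechanicalCurve]:
    """Noisy constant-strain-rate stress curves from known aSLS parameters.

    Noise is applied to the stress column only; time and strain stay exact.
    Deterministic under a fixed ``noise.seed``; each curve's metadata records
    the generating parameters for recovery tests.
    """
    if isinstance(protocols, LoadingProtocol):
        protocols = [protocols]
    if n_replicates < 0:
        raise DomainError("n_replicates must be >= 0")
    if noise is None:
        noise = NoiseModel(level=0.0)
    rng = np.random.default_rng(noise.seed)
    curves: list[MechanicalCurve] = []
    for protocol in protocols:
        clean = stress_response(protocol, params)
        for rep in range(n_replicates):
            stress = clean.stress.copy()
            if noise.level > 0:
                g = rng.standard_normal(len(stress))
                if noise.kind == "multiplicative-gaussian":
                    stress = stress * (1.0 + noise.level * g)
                else:
                    stress = stress + noise.level * g
                stress[0] = 0.0  # curves start unloaded by construction
            curves.append(
                MechanicalCurve(
                    time=clean.time.copy(),
                    strain=clean.strain.copy(),
                    stress=stress,
                    strain_rate=protocol.strain_rate,
                    metadata={
                        "true_params": params.as_dict(),
                        "noise": {"kind": noise.kind, "level": noise.level, "seed": noise.seed},
                        "replicate": rep,
                    },
                )
            )
    return curves


def generate_cell_table(
    n_cells: int,
    shape_mix: dict[str, float] | None = None,
    intensity_params: dict[str, float] | None = None,
    seed: int = 0,
    condition: str = "synthetic",
) -> pd.DataFrame:
    """Synthetic segmented-cell measurement table (columns condition,A,P,A_N,GI_nuc,GI_cyt).

    Round cells are drawn with CSI near 1 (perimeter close to the circular
    minimum), spread cells with CSI well below 1.  ``intensity_params`` sets
    the target nuclear/cytosolic mean-intensity ratio (``nc_ratio``), base
    cytosolic level (``gi_cyt``), relative intensity noise (``cv``) and the
    nuclear-to-cell area fraction (``nuclear_fraction``).
    """
    if n_cells < 0:
        raise DomainError("n_cells must be >= 0")
    shape_mix = dict(shape_mix or {"round_fraction": 0.5, "spread_fraction": 0.5})
    rf = shape_mix.get("round_fraction", 0.0)
    sf = shape_mix.get("spread_fraction", 0.0)
    if rf < 0 or sf < 0 or abs(rf + sf - 1.0) > 1e-9:
        raise DomainError("round_fraction and spread_fraction must be >= 0 and sum to 1")
    ip = {"gi_cyt": 100.0, "nc_ratio": 1.0, "cv": 0.05, "nuclear_fraction": 0.2}
    ip.update(intensity_params or {})

    rng = np.random.default_rng(seed)
    cols = {"condition": [], "A": [], "P": [], "A_N": [], "GI_nuc": [], "GI_cyt": []}
    n_round = int(round(rf * n_cells))
    for i in range(n_cells):
        is_round = i < n_round
        A = float(rng.lognormal(mean=np.log(800.0), sigma=0.25))  # ~cell-sized, um^2
        p_circle = 2.0 * np.sqrt(np.pi * A)
        if is_round:
            # CSI in (0.8, 1]: perimeter within ~11 % of the circular minimum
            csi = rng.uniform(0.82, 0.995)
        else:
            csi = rng.uniform(0.2, 0.6)
        P = p_circle / np.sqrt(csi)
        A_N = float(np.clip(ip["nuclear_fraction"] * A * rng.uniform(0.8, 1.2), 0.0, A))
        gi_cyt = max(ip["gi_cyt"] * (1.0 + ip["cv"] * rng.standard_normal()), 1e-6)
        gi_nuc = max(
            ip["gi_cyt"] * ip["nc_ratio"] * (1.0 + ip["cv"] * rng.standard_normal()), 0.0
        )
        cols["condition"].append(condition)
        cols["A"].append(A)
        cols["P"].append(float(P))
        cols["A_N"].append(A_N)
        cols["GI_nuc"].append(gi_nuc)
        cols["GI_cyt"].append(gi_cyt)
    return pd.DataFrame(cols)


def generate_concentration_field(
    grid: GridSpec,
    profile: Literal["uniform", "cosine-mode", "gaussian-blob"],
    c0: float,
    amplitude: float = 0.0,
    seed: int = 0,
    width_fraction: float = 0.15,
) -> ConcentrationField:
    """Analytic initial conditions for the transport solver.

    ``uniform``: c = c0 everywhere.  ``cosine-mode``: c = c0 + A*cos(pi*x/Lx),
    the slowest decaying no-flux eigenmode along x.  ``gaussian-blob``:
    c = c0 + A*exp(-|r - centre|^2 / (2*s^2)) with s = width_fraction * min
    extent.  Requires c >= 0 everywhere.
    """
    if c0 < 0:
        raise DomainError("c0 must be >= 0")
    if amplitude < 0:
        raise DomainError("amplitude must be >= 0")
    x, y, z = np.meshgrid(*grid.axes(), indexing="ij")
    if profile == "uniform":
        c = np.full(grid.n, float(c0))
    elif profile == "cosine-mode":
        if amplitude > c0:
            raise DomainError("cosine amplitude > c0 would give negative concentrations")
        c = c0 + amplitude * np.cos(np.pi * x / grid.extents[0])
    elif profile == "gaussian-blob":
        s = width_fraction * min(grid.extents)
        centre = [0.5 * L for L in grid.extents]
        r2 = (x - centre[0]) ** 2 + (y - centre[1]) ** 2 + (z - centre[2]) ** 2
        c = c0 + amplitude * np.exp(-r2 / (2.0 * s * s))
    else:
        raise DomainError(f"unknown profile {profile!r}")
    return ConcentrationField(c=c, t=0.0)
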