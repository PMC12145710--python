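"""Cell morphometrics from region-measurement tables.

Two metrics: the cell shape index ``CSI = 4*pi*A/P**2`` (1 for a circle,
-> 0 for elongated shapes) and the YAP nuclear/cytosolic distribution ratio.
The YAP ratio's default reading is a total-signal distribution,
``(GI_nuc * A_N) / (GI_cyt * A)``; a per-area density reading,
``(GI_nuc / GI_cyt)``-style ``(GI_nuc * A) / (GI_cyt * A_N)``, is available
via ``mode="density"`` since the gray intensities are already per-pixel means.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from viscogel.errors import DomainError, InsufficientDataError, UndefinedRatioError

__all__ = [
    "CellMeasurement",
    "cell_shape_index",
    "yap_nc_ratio",
    "summarize_by_condition",
    "measurements_from_frame",
]


@dataclass(frozen=True)
class CellMeasurement:
    """Region measurements for one segmented cell.

    ``A``/``P`` are cytosolic area and perimeter, ``A_N`` the nuclear area
    (same length units), ``GI_nuc``/``GI_cyt`` mean gray intensities.
    """

    A: float
    P: float
    A_N: float
    GI_nuc: float
    GI_cyt: float
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.A > 0 or not self.P > 0:
            raise DomainError(f"A and P must be > 0, got A={self.A!r}, P={self.P!r}")
        if self.A_N < 0 or self.A_N > self.A:
            raise DomainError(f"need 0 <= A_N <= A, got A_N={self.A_N!r}, A={self.A!r}")
        if self.GI_nuc < 0 or self.GI_cyt < 0:
            raise DomainError("intensities must be >= 0")


def cell_shape_index(A: float, P: float) -> float:
    """Cell shape index 4*pi*A/P^2; equals 1 iff the region is a circle.

    Values above 1 are geometrically impossible for simple closed shapes but
    can arise from noisy perimeter measurements; they are reported with a
    warning rather than clamped.
    """
    if not A > 0 or not P > 0:
        raise DomainError(f"A and P must be > 0, got A={A!r}, P={P!r}")
    csi = 4.0 * math.pi * A / (P * P)
    if csi > 1.0 + 1e-9:
        warnings.warn(
            f"CSI = {csi:.4f} > 1 violates the isoperimetric bound; "
            "check the perimeter measurement",
            stacklevel=2,
        )
    return csi


def yap_nc_ratio(
    m: CellMeasurement, mode: Literal["distribution", "density"] = "distribution"
) -> float:
    """YAP nuclear/cytosolic ratio.

    ``distribution`` (default): (GI_nuc * A_N) / (GI_cyt * A), the fraction of
    total signal in the nucleus relative to the whole cell.  ``density``:
    (GI_nuc / GI_cyt) * (A / A_N), a per-area concentration ratio.
    """
    if m.GI_cyt == 0:
        raise UndefinedRatioError("cytosolic gray intensity is zero; ratio undefined")
    if mode == "distribution":
        return (m.GI_nuc * m.A_N) / (m.GI_cyt * m.A)
    if mode == "density":
        if m.A_N == 0:
            raise UndefinedRatioError("nuclear area is zero; density ratio undefined")
        return (m.GI_nuc / m.A_N) / (m.GI_cyt / m.A)
    raise DomainError(f"unknown mode {mode!r}")


def measurements_from_frame(df: pd.DataFrame) -> list[CellMeasurement]:
    """Build measurements from a table with columns condition,A,P,A_N,GI_nuc,GI_cyt."""
    required = {"condition", "A", "P", "A_N", "GI_nuc", "GI_cyt"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"missing columns: {sorted(missing)}")
    return [
        CellMeasurement(
            A=float(r.A), P=float(r.P), A_N=float(r.A_N),
            GI_nuc=float(r.GI_nuc), GI_cyt=float(r.GI_cyt),
            condition=str(r.condition),
        )
        for r in df.itertuples(index=False)
    ]


def summarize_by_condition(
    table: Sequence[CellMeasurement],
    mode: Literal["distribution", "density"] = "distribution",
) -> pd.DataFrame:
    """Per-condition means, SDs and n of area, CSI and YAP ratio.

    Rows ordered by condition label.  SD is NaN for single-cell groups
    (ddof=1), mirroring how spreadsheets flag undefined spread.
    """
    if not table:
        raise InsufficientDataError("empty measurement table")
    records = []
    for m in table:
        records.append(
            {
                "condition": m.condition,
                "A": m.A,
                "CSI": cell_shape_index(m.A, m.P),
                "YAP_NC": yap_nc_ratio(m, mode=mode),
            }
        )
    df = pd.DataFrame.from_records(records)
    agg = df.groupby("condition", sort=True).agg(
        n=("A", "size"),
        A_mean=("A", "mean"),
        A_sd=("A", lambda s: s.std(ddof=1)),
        CSI_mean=("CSI", "mean"),
        CSI_sd=("CSI", lambda s: s.std(ddof=1)),
        YAP_NC_mean=("YAP_NC", "mean"),
        YAP_NC_sd=("YAP_NC", lambda s: s.std(ddof=1)),
    )
    return agg.reset_index()
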