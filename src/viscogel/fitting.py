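"""Non-linear least-squares extraction of aSLS parameters from epsilon-dot curves.

Within a single formulation only the lumped viscosity ``eta_eff = eta1 +
phi*eta2`` is identifiable; the split into ``eta1`` and ``eta2`` requires
curves from at least two dextran fractions and is obtained by linear
regression of the fitted ``eta_eff`` values on ``phi``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import numpy.typing as npt
from scipy.optimize import least_squares

from viscogel.errors import (
    DomainError,
    FitError,
    IdentifiabilityError,
    InsufficientDataError,
)
from viscogel.mechanics import (
    ASLSParams,
    MechanicalCurve,
    ViscoelasticDescriptors,
    descriptors_from_params,
)

__all__ = ["FitConfig", "FitResult", "fit_single_formulation", "fit_across_formulations"]

# E1/E0 ratio below which the Maxwell arm is deemed absent and eta_eff unidentifiable
_PURE_SPRING_RTOL = 1e-4


@dataclass(frozen=True)
class FitConfig:
    """Settings for the bounded trust-region least-squares fit."""

    initial_guess: tuple[float, float, float] | None = None  # (E0, E1, eta_eff)
    bounds: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (0.0, 0.0, 0.0),
        (np.inf, np.inf, np.inf),
    )
    tol: float = 1e-12
    max_iter: int = 2000
    n_starts: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b < 0 for b in self.bounds[0]):
            raise DomainError("lower bounds must be >= 0")
        if not self.tol > 0:
            raise DomainError("tol must be > 0")
        if self.n_starts < 1:
            raise DomainError("n_starts must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters, descriptors and goodness-of-fit for one formulation."""

    params: ASLSParams
    eta_eff: float
    descriptors: ViscoelasticDescriptors | None
    rss: float
    r2: float
    per_curve_residuals: tuple[dict, ...] = field(default_factory=tuple)
    eta_unidentifiable: bool = False

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise DomainError("rss must be >= 0")
        if self.r2 > 1 + 1e-12:
            raise DomainError("r2 must be <= 1")

    def as_dict(self) -> dict:
        return {
            "params": self.params.as_dict(),
            "eta_eff": self.eta_eff,
            "descriptors": None if self.descriptors is None else self.descriptors.as_dict(),
            "rss": self.rss,
            "r2": self.r2,
            "eta_unidentifiable": self.eta_unidentifiable,
            "per_curve_residuals": list(self.per_curve_residuals),
        }


def _model_stress(t: npt.NDArray, rate: float, E0: float, E1: float, eta: float) -> npt.NDArray:
    if E1 == 0 or eta == 0:
        return rate * E0 * t
    return rate * (E0 * t + eta * (-np.expm1(-E1 * t / eta)))


def _moment_initial_guess(curves: Sequence[MechanicalCurve]) -> tuple[float, float, float]:
    """Moment-style seeds: tail slope -> E0, initial slope -> E0+E1, 63 % rise time -> tau."""
    E0s, E1s, etas = [], [], []
    for c in curves:
        t, sig, rate = c.time, c.stress, c.strain_rate
        pos = t > 0
        t_p, s_p = t[pos], sig[pos] / rate  # sigma / rate ~ E0*t + eta*(1-exp(...))
        n = len(t_p)
        if n < 3:
            continue
        k = max(2, n // 4)
        tail_t, tail_s = t_p[-k:], s_p[-k:]
        A = np.vstack([tail_t, np.ones_like(tail_t)]).T
        (e0, intercept), *_ = np.linalg.lstsq(A, tail_s, rcond=None)
        e0 = max(e0, 0.0)
        head = slice(0, max(2, n // 10))
        einst = np.median(s_p[head] / t_p[head])
        e1 = max(einst - e0, 0.0)
        eta = max(intercept, 0.0)  # asymptote intercept equals eta_eff
        if eta == 0 and e1 > 0:
            # fall back: time at 63 % of the relaxation transient
            eta = e1 * t_p[min(n - 1, n // 3)]
        E0s.append(e0)
        E1s.append(e1)
        etas.append(eta)
    if not E0s:
        raise InsufficientDataError("curves too short for initial-guess estimation")
    return float(np.median(E0s)), float(np.median(E1s)), float(np.median(etas))


def fit_single_formulation(
    curves: Sequence[MechanicalCurve],
    phi: float,
    config: FitConfig | None = None,
) -> FitResult:
    """Jointly fit (E0, E1, eta_eff) to one formulation's stress curves.

    All curves must come from the same formulation; different strain rates are
    pooled into one residual vector.  Multi-start from jittered seeds, best
    residual sum of squares wins; deterministic under a fixed ``config.seed``.
    The returned ``params`` carry ``eta_eff`` in ``eta1`` with ``eta2 = 0``
    because the split is not identifiable from a single ``phi``.
    """
    if config is None:
        config = FitConfig()
    if not curves:
        raise InsufficientDataError("need at least one curve")
    if not 0 <= phi <= 1:
        raise DomainError(f"phi must lie in [0, 1], got {phi!r}")
    n_points = sum(int(np.sum(c.time > 0)) for c in curves)
    if n_points < 3:
        raise InsufficientDataError(f"need >= 3 positive-time samples, got {n_points}")

    guess = config.initial_guess or _moment_initial_guess(curves)
    guess = tuple(max(g, 1e-12) for g in guess)

    t_all = np.concatenate([c.time for c in curves])
    s_all = np.concatenate([c.stress for c in curves])
    r_all = np.concatenate([np.full(len(c), c.strain_rate) for c in curves])

    def residuals(x: npt.NDArray) -> npt.NDArray:
        return _model_stress(t_all, r_all, x[0], x[1], x[2]) - s_all

    rng = np.random.default_rng(config.seed)
    lo = np.asarray(config.bounds[0], dtype=float)
    hi = np.asarray(config.bounds[1], dtype=float)
    best = None
    starts = [np.asarray(guess, dtype=float)]
    for _ in range(config.n_starts - 1):
        jitter = np.exp(rng.normal(0.0, 0.5, size=3))
        starts.append(np.clip(np.asarray(guess) * jitter, lo + 1e-12, None))
    for x0 in starts:
        x0 = np.minimum(np.maximum(x0, lo), np.where(np.isfinite(hi), hi, x0))
        try:
            sol = least_squares(
                residuals,
                x0,
                bounds=(lo, hi),
                method="trf",
                xtol=config.tol,
                ftol=config.tol,
                gtol=config.tol,
                max_nfev=config.max_iter,
            )
        except Exception:  # singular starts etc.
            continue
        rss = float(np.sum(sol.fun**2))
        key = (rss, sol.x[1])  # ties broken by lowest E1
        if best is None or key < best[0]:
            best = (key, sol)
    if best is None:
        raise FitError("all multi-start least-squares attempts failed")
    sol = best[1]
    E0, E1, eta = (float(v) for v in sol.x)
    rss = float(np.sum(sol.fun**2))

    ss_tot = float(np.sum((s_all - s_all.mean()) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else (1.0 if rss == 0 else -np.inf)

    pure_spring = E1 <= _PURE_SPRING_RTOL * max(E0, 1e-300)
    per_curve = []
    for i, c in enumerate(curves):
        res = _model_stress(c.time, c.strain_rate, E0, E1, eta) - c.stress
        per_curve.append(
            {"curve": i, "strain_rate": c.strain_rate, "rss": float(np.sum(res**2)),
             "max_abs": float(np.max(np.abs(res)))}
        )

    params = ASLSParams(E0=E0, E1=E1, eta1=eta, eta2=0.0, phi=phi)
    descriptors = None if pure_spring else descriptors_from_params(params)
    return FitResult(
        params=params,
        eta_eff=eta,
        descriptors=descriptors,
        rss=rss,
        r2=r2,
        per_curve_residuals=tuple(per_curve),
        eta_unidentifiable=pure_spring,
    )


def fit_across_formulations(
    curve_sets: Sequence[tuple[Sequence[MechanicalCurve], float]],
    config: FitConfig | None = None,
) -> tuple[list[FitResult], tuple[float, float]]:
    """Fit each formulation, then split eta_eff = eta1 + phi*eta2 across them.

    Requires at least two distinct ``phi`` values.  Returns the per-formulation
    fit results (with ``params`` rewritten to carry the shared eta1/eta2 split)
    and the ``(eta1, eta2)`` estimates from ordinary least squares.
    """
    if len(curve_sets) < 2:
        raise IdentifiabilityError("need curve sets from >= 2 formulations")
    phis = np.array([phi for _, phi in curve_sets], dtype=float)
    if np.ptp(phis) == 0:
        raise IdentifiabilityError("all phi values equal: eta1/eta2 not separable")

    results = [fit_single_formulation(curves, phi, config) for curves, phi in curve_sets]
    etas = np.array([r.eta_eff for r in results])

    A = np.vstack([np.ones_like(phis), phis]).T
    (eta1, eta2), *_ = np.linalg.lstsq(A, etas, rcond=None)
    eta1 = float(max(eta1, 0.0))
    eta2 = float(max(eta2, 0.0))

    split_results = []
    for r, phi in zip(results, phis):
        p = r.params
        new_params = ASLSParams(E0=p.E0, E1=p.E1, eta1=eta1, eta2=eta2, phi=float(phi))
        split_results.append(
            FitResult(
                params=new_params,
                eta_eff=r.eta_eff,
                descriptors=r.descriptors,
                rss=r.rss,
                r2=r.r2,
                per_curve_residuals=r.per_curve_residuals,
                eta_unidentifiable=r.eta_unidentifiable,
            )
        )
    return split_results, (eta1, eta2)
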