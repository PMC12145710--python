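"""Adapted standard-linear-solid (aSLS) mechanics under constant-strain-rate loading.

The model is a spring ``E0`` in parallel with a Maxwell arm (spring ``E1`` in
series with a dashpot).  The dashpot viscosity is ``eta_eff = eta1 + phi*eta2``,
where the second dashpot accounts for dextran in the liquid phase through its
volumetric fraction ``phi``.  Under a constant strain rate the time-dependent
modulus is

    E(t) = E0 + (eta_eff / t) * (1 - exp(-E1 * t / eta_eff))

with the removable singularity at t = 0 resolved to E0 + E1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

from viscogel.errors import (
    DegenerateModelError,
    DomainError,
    InsufficientDataError,
)

__all__ = [
    "ASLSParams",
    "ViscoelasticDescriptors",
    "LoadingProtocol",
    "MechanicalCurve",
    "asls_modulus",
    "stress_response",
    "descriptors_from_params",
    "apparent_modulus",
]


@dataclass(frozen=True)
class ASLSParams:
    """Lumped parameters of the aSLS model for one gel formulation.

    Parameters
    ----------
    E0 : float
        Equilibrium spring modulus [Pa].
    E1 : float
        Maxwell-arm spring modulus [Pa].
    eta1 : float
        Base dashpot viscosity [Pa s].
    eta2 : float
        Dextran-associated dashpot viscosity [Pa s].
    phi : float
        Dextran volumetric fraction in the liquid phase, in [0, 1].
    """

    E0: float
    E1: float
    eta1: float
    eta2: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        for name in ("E0", "E1", "eta1", "eta2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise DomainError(f"{name} must be finite and >= 0, got {v!r}")
        if not 0.0 <= self.phi <= 1.0:
            raise DomainError(f"phi must lie in [0, 1], got {self.phi!r}")
        if self.E1 > 0 and self.eta_eff == 0:
            raise DegenerateModelError(
                "eta_eff = eta1 + phi*eta2 must be > 0 when E1 > 0"
            )

    @property
    def eta_eff(self) -> float:
        """Effective dashpot viscosity ``eta1 + phi * eta2`` [Pa s]."""
        return self.eta1 + self.phi * self.eta2

    def as_dict(self) -> dict[str, float]:
        return {
            "E0": self.E0,
            "E1": self.E1,
            "eta1": self.eta1,
            "eta2": self.eta2,
            "phi": self.phi,
        }


@dataclass(frozen=True)
class ViscoelasticDescriptors:
    """Descriptors that experiments report and the design step consumes.

    ``E_eq`` and ``E_inst`` are the long-time and instantaneous elastic moduli,
    ``tau_rel`` the characteristic relaxation time; ``E_app`` is the
    small-strain stress-strain slope when available.
    """

    E_eq: float
    E_inst: float
    tau_rel: float
    E_app: float | None = None

    def __post_init__(self) -> None:
        if self.E_eq < 0 or self.E_inst < self.E_eq:
            raise DomainError(
                f"need E_inst >= E_eq >= 0, got E_inst={self.E_inst!r}, E_eq={self.E_eq!r}"
            )
        if not self.tau_rel > 0:
            raise DomainError(f"tau_rel must be > 0, got {self.tau_rel!r}")

    def as_dict(self) -> dict[str, float | None]:
        return {
            "E_eq": self.E_eq,
            "E_inst": self.E_inst,
            "tau_rel": self.tau_rel,
            "E_app": self.E_app,
        }


@dataclass(frozen=True)
class LoadingProtocol:
    """A constant-strain-rate compression protocol.

    ``strain_limit`` caps the linear region used for the apparent modulus
    (default 5 % strain).  ``strain_rate = 0`` is accepted only as the
    degenerate "no loading" protocol used by the coupled virtual test.
    """

    strain_rate: float
    t_end: float
    n_samples: int = 200
    strain_limit: float = 0.05

    def __post_init__(self) -> None:
        if self.strain_rate < 0:
            raise DomainError(f"strain_rate must be >= 0, got {self.strain_rate!r}")
        if not self.t_end > 0:
            raise DomainError(f"t_end must be > 0, got {self.t_end!r}")
        if self.n_samples < 2:
            raise DomainError(f"n_samples must be >= 2, got {self.n_samples!r}")
        if self.strain_rate > 0:
            if not 0 < self.strain_limit <= self.strain_rate * self.t_end:
                raise DomainError(
                    "strain_limit must lie in (0, strain_rate*t_end], got "
                    f"{self.strain_limit!r} with max strain {self.strain_rate * self.t_end!r}"
                )

    def time_grid(self) -> npt.NDArray[np.float64]:
        return np.linspace(0.0, self.t_end, self.n_samples)


@dataclass(frozen=True)
class MechanicalCurve:
    """Sampled (time, strain, stress) triplets from one constant-strain-rate test."""

    time: npt.NDArray[np.float64]
    strain: npt.NDArray[np.float64]
    stress: npt.NDArray[np.float64]
    strain_rate: float
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        eps = np.asarray(self.strain, dtype=float)
        sig = np.asarray(self.stress, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "strain", eps)
        object.__setattr__(self, "stress", sig)
        if not (t.ndim == eps.ndim == sig.ndim == 1):
            raise DomainError("time, strain and stress must be 1-D arrays")
        if not (len(t) == len(eps) == len(sig)):
            raise DomainError("time, strain and stress must have equal lengths")
        if len(t) < 2:
            raise DomainError("a curve needs at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise DomainError("time must be strictly increasing")
        scale = max(abs(sig).max(), 1.0)
        if abs(eps[0]) > 1e-9 or abs(sig[0]) > 1e-9 * scale:
            raise DomainError("curve must start at strain(0) = stress(0) = 0")

    def __len__(self) -> int:
        return len(self.time)


def _eta_eff_checked(params: ASLSParams) -> float:
    eta = params.eta_eff
    if params.E1 > 0 and eta <= 0:
        raise DegenerateModelError("eta_eff must be > 0 when E1 > 0")
    return eta


def asls_modulus(t: float | npt.ArrayLike, params: ASLSParams) -> float | npt.NDArray[np.float64]:
    """Time-dependent elastic modulus E(t) of the aSLS model under epsilon-dot loading.

    ``E(t) = E0 + (eta_eff/t) * (1 - exp(-E1*t/eta_eff))``; at ``t = 0`` the
    analytic limit ``E0 + E1`` is returned.  Output is bounded in
    ``[E0, E0 + E1]`` and monotone non-increasing in ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("t must be >= 0")
    if params.E1 == 0:
        out = np.full_like(t_arr, params.E0, dtype=float)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    eta = _eta_eff_checked(params)
    tau = eta / params.E1
    with np.errstate(divide="ignore", invalid="ignore"):
        x = t_arr / tau
        # E0 + E1 * (1 - exp(-x)) / x, with x -> 0 limit E0 + E1
        out = params.E0 + params.E1 * np.where(
            x > 0, -np.expm1(-np.where(x > 0, x, 1.0)) / np.where(x > 0, x, 1.0), 1.0
        )
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def stress_response(protocol: LoadingProtocol, params: ASLSParams) -> MechanicalCurve:
    """Stress curve sigma(t) = strain_rate * [E0*t + eta_eff*(1 - exp(-E1*t/eta_eff))].

    Returns a :class:`MechanicalCurve` on the protocol's uniform time grid with
    ``strain = strain_rate * t``.  Collapses to a pure spring when ``E1 = 0``.
    """
    t = protocol.time_grid()
    rate = protocol.strain_rate
    strain = rate * t
    if params.E1 == 0:
        stress = rate * params.E0 * t
    else:
        eta = _eta_eff_checked(params)
        stress = rate * (params.E0 * t + eta * (-np.expm1(-params.E1 * t / eta)))
    return MechanicalCurve(
        time=t,
        strain=strain,
        stress=stress,
        strain_rate=rate,
        metadata={"params": params.as_dict()},
    )


def descriptors_from_params(params: ASLSParams) -> ViscoelasticDescriptors:
    """Map lumped parameters to descriptors: E_eq = E0, E_inst = E0+E1, tau_rel = eta_eff/E1."""
    if params.E1 <= 0:
        raise DegenerateModelError("relaxation time undefined for E1 = 0 (pure spring)")
    return ViscoelasticDescriptors(
        E_eq=params.E0,
        E_inst=params.E0 + params.E1,
        tau_rel=params.eta_eff / params.E1,
    )


def apparent_modulus(
    curve: MechanicalCurve,
    strain_limit: float = 0.05,
    through_origin: bool = True,
) -> float:
    """Apparent elastic modulus: least-squares slope of stress vs strain up to ``strain_limit``.

    By default the regression is constrained through the origin because both
    columns start at zero by construction; set ``through_origin=False`` for
    noisy experimental data with a free intercept.
    """
    if not strain_limit > 0:
        raise DomainError(f"strain_limit must be > 0, got {strain_limit!r}")
    mask = (curve.strain <= strain_limit) & (curve.strain > 0)
    if mask.sum() < (2 if not through_origin else 1):
        raise InsufficientDataError(
            f"need at least {'2' if not through_origin else '1'} positive-strain "
            f"samples with strain <= {strain_limit}, found {int(mask.sum())}"
        )
    eps = curve.strain[mask]
    sig = curve.stress[mask]
    if through_origin:
        return float(np.dot(eps, sig) / np.dot(eps, eps))
    slope, _ = np.polyfit(eps, sig, 1)
    return float(slope)
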