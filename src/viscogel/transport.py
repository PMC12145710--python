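"""Mesh-size law, hindered diffusion, and the 3-D reaction-diffusion solver.

The average mesh size of the agarose network is tied to the current modulus,

    xi_avg = (18 * kB * T / (pi * alpha**(2/3) * E))**(1/3),

and sets the hindrance of dextran diffusion together with the Brinkman drag
correction for a permeable fibre network:

    D_app = D0 * exp(-r_h / (2 * xi_avg)) / (1 + r_h/sqrt(kappa) + r_h**2/(3*kappa)),

with D0 the Stokes-Einstein free diffusivity kB*T/(6*pi*mu*r_h).  Transport of
dextran is then the reaction-diffusion equation dc/dt = D_app * lap(c) - kr*c0
(zero-order sink, clamped at c = 0), discretised by the method of lines on a
uniform Cartesian grid with a 7-point Laplacian and integrated adaptively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import numpy.typing as npt
from scipy.integrate import solve_ivp

from viscogel.errors import ConfigError, DomainError, SolverError
from viscogel.mechanics import ASLSParams, LoadingProtocol, MechanicalCurve, asls_modulus, stress_response

__all__ = [
    "BOLTZMANN",
    "TransportParams",
    "GridSpec",
    "ConcentrationField",
    "SimulationResult",
    "mesh_size",
    "apparent_diffusion",
    "stokes_einstein_diffusivity",
    "diffusion_time",
    "carman_kozeny_permeability",
    "solve_reaction_diffusion",
    "coupled_virtual_test",
]

BOLTZMANN = 1.380649e-23  # J/K, exact SI value


@dataclass(frozen=True)
class TransportParams:
    """Physical parameters of dextran transport in the agarose liquid phase.

    Parameters
    ----------
    r_h : float
        Solute hydrodynamic radius [m].
    kappa : float
        Hydraulic permeability of the network [m^2].
    mu : float
        Liquid-phase viscosity [Pa s].
    T : float
        Absolute temperature [K]; default room temperature.
    p : float
        Gel porosity, in (0, 1].
    alpha : float
        Degree of agarose gelation, in (0, 1]; default 0.65.
    k_r : float
        Dextran-water binding rate of the zero-order sink [1/s].
    c0 : float
        Nominal dextran concentration [mg/mL].
    """

    r_h: float
    kappa: float
    mu: float
    T: float = 298.15
    p: float = 0.95
    alpha: float = 0.65
    k_r: float = 0.0
    c0: float = 0.0
    k_B: float = BOLTZMANN

    def __post_init__(self) -> None:
        for name in ("r_h", "kappa", "mu", "T"):
            v = getattr(self, name)
            if not v > 0 or not np.isfinite(v):
                raise DomainError(f"{name} must be finite and > 0, got {v!r}")
        for name in ("p", "alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise DomainError(f"{name} must lie in (0, 1], got {v!r}")
        if self.k_r < 0:
            raise DomainError(f"k_r must be >= 0, got {self.k_r!r}")
        if self.c0 < 0:
            raise DomainError(f"c0 must be >= 0, got {self.c0!r}")


@dataclass(frozen=True)
class GridSpec:
    """Uniform Cartesian grid over a box, node-centred including the faces."""

    extents: tuple[float, float, float]
    n: tuple[int, int, int]
    boundary: Literal["no-flux", "fixed-concentration"] = "no-flux"
    bc_value: float = 0.0

    def __post_init__(self) -> None:
        if len(self.extents) != 3 or len(self.n) != 3:
            raise ConfigError("extents and n must each have 3 entries")
        if any(not e > 0 for e in self.extents):
            raise ConfigError(f"extents must be > 0, got {self.extents!r}")
        if any(ni < 3 for ni in self.n):
            raise ConfigError(f"need >= 3 nodes per axis, got {self.n!r}")
        if self.boundary not in ("no-flux", "fixed-concentration"):
            raise ConfigError(f"unknown boundary condition {self.boundary!r}")
        if self.boundary == "fixed-concentration" and self.bc_value < 0:
            raise ConfigError("bc_value must be >= 0")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return tuple(L / (ni - 1) for L, ni in zip(self.extents, self.n))

    def axes(self) -> tuple[npt.NDArray[np.float64], ...]:
        return tuple(np.linspace(0.0, L, ni) for L, ni in zip(self.extents, self.n))

    def quadrature_weights(self) -> npt.NDArray[np.float64]:
        """Trapezoidal node volumes; summing c * w integrates c over the box."""
        ws = []
        for L, ni in zip(self.extents, self.n):
            w = np.full(ni, L / (ni - 1))
            w[0] *= 0.5
            w[-1] *= 0.5
            ws.append(w)
        return ws[0][:, None, None] * ws[1][None, :, None] * ws[2][None, None, :]


@dataclass(frozen=True)
class ConcentrationField:
    """Concentration values on a grid at one time stamp."""

    c: npt.NDArray[np.float64]
    t: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=float)
        object.__setattr__(self, "c", c)
        if c.ndim != 3:
            raise DomainError("concentration field must be a 3-D array")
        if np.any(c < 0):
            raise DomainError("concentrations must be >= 0")


@dataclass(frozen=True)
class SimulationResult:
    """Output of one transport simulation: fields plus scalar traces vs time."""

    times: npt.NDArray[np.float64]
    fields: tuple[ConcentrationField, ...]
    D_app_trace: npt.NDArray[np.float64]
    xi_trace: npt.NDArray[np.float64]
    total_mass: npt.NDArray[np.float64]
    grid: GridSpec = field(compare=False, default=None)

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.fields) == len(self.D_app_trace) == len(self.xi_trace) == len(self.total_mass) == n):
            raise DomainError("all traces must have the same length as times")


def mesh_size(E_t: float | npt.ArrayLike, params: TransportParams) -> float | npt.NDArray[np.float64]:
    """Average network mesh size at modulus ``E_t``.

    ``xi_avg = (18 kB T / (pi alpha^(2/3) E_t))^(1/3)``; scales as E^(-1/3).
    """
    E = np.asarray(E_t, dtype=float)
    if np.any(E <= 0) or not np.all(np.isfinite(E)):
        raise DomainError("E_t must be finite and > 0")
    xi = (18.0 * params.k_B * params.T / (math.pi * params.alpha ** (2.0 / 3.0) * E)) ** (1.0 / 3.0)
    return float(xi) if np.isscalar(E_t) or E.ndim == 0 else xi


def stokes_einstein_diffusivity(params: TransportParams) -> float:
    """Free-solution diffusivity D0 = kB*T / (6*pi*mu*r_h) [m^2/s]."""
    return params.k_B * params.T / (6.0 * math.pi * params.mu * params.r_h)


def hindrance_factor(xi: float | npt.ArrayLike, params: TransportParams) -> float | npt.NDArray[np.float64]:
    """Dimensionless hindrance D_app/D0 in (0, 1]: mesh-size screening times Brinkman drag."""
    xi_arr = np.asarray(xi, dtype=float)
    if np.any(xi_arr <= 0):
        raise DomainError("xi must be > 0")
    rh, kap = params.r_h, params.kappa
    brinkman = 1.0 + rh / math.sqrt(kap) + rh * rh / (3.0 * kap)
    h = np.exp(-rh / (2.0 * xi_arr)) / brinkman
    return float(h) if np.isscalar(xi) or xi_arr.ndim == 0 else h


def apparent_diffusion(xi: float | npt.ArrayLike, params: TransportParams) -> float | npt.NDArray[np.float64]:
    """Hindered apparent diffusion coefficient of the solute at mesh size ``xi``.

    Always satisfies ``0 < D_app <= D0`` with D0 the Stokes-Einstein value.
    """
    return stokes_einstein_diffusivity(params) * hindrance_factor(xi, params)


def diffusion_time(L: float, D_app: float) -> float:
    """Characteristic diffusion time ``tau_diff = L^2 / D_app`` over length L."""
    if not L > 0 or not D_app > 0:
        raise DomainError("L and D_app must be > 0")
    return L * L / D_app


def carman_kozeny_permeability(r_f: float, p: float, C: float = 20.0) -> float:
    """Approximate permeability ``kappa = r_f^2 * p^3 / (C * (1-p)^2)`` of a fibre network.

    A rough Carman-Kozeny helper for when kappa was not measured; ``r_f`` is
    the fibre radius and ``C`` the Kozeny constant.
    """
    if not r_f > 0 or not 0 < p < 1 or not C > 0:
        raise DomainError("need r_f > 0, 0 < p < 1, C > 0")
    return r_f * r_f * p ** 3 / (C * (1.0 - p) ** 2)


def _laplacian(c: npt.NDArray[np.float64], grid: GridSpec) -> npt.NDArray[np.float64]:
    """7-point Laplacian; no-flux via ghost-node mirror reflection at each face."""
    dx, dy, dz = grid.spacing
    lap = np.zeros_like(c)
    for axis, h in zip((0, 1, 2), (dx, dy, dz)):
        upper = np.roll(c, -1, axis=axis)
        lower = np.roll(c, 1, axis=axis)
        # mirror ghost nodes: c[-1] := c[1], c[n] := c[n-2]
        first = [slice(None)] * 3
        last = [slice(None)] * 3
        first[axis] = 0
        last[axis] = -1
        second = [slice(None)] * 3
        penult = [slice(None)] * 3
        second[axis] = 1
        penult[axis] = -2
        lower[tuple(first)] = c[tuple(second)]
        upper[tuple(last)] = c[tuple(penult)]
        lap += (upper - 2.0 * c + lower) / (h * h)
    return lap


def _boundary_mask(shape: tuple[int, int, int]) -> npt.NDArray[np.bool_]:
    m = np.zeros(shape, dtype=bool)
    m[0, :, :] = m[-1, :, :] = True
    m[:, 0, :] = m[:, -1, :] = True
    m[:, :, 0] = m[:, :, -1] = True
    return m


def solve_reaction_diffusion(
    grid: GridSpec,
    params: TransportParams,
    D_schedule: float | Callable[[float], float],
    t_span: tuple[float, float],
    initial: ConcentrationField,
    *,
    n_output: int = 25,
    t_eval: Sequence[float] | None = None,
    xi_schedule: Callable[[float], float] | None = None,
    method: str = "RK45",
    rtol: float = 1e-8,
    atol: float | None = None,
) -> SimulationResult:
    """Integrate dc/dt = D_app(t) * lap(c) - k_r*c0 by the method of lines.

    ``D_schedule`` is either a constant D_app [m^2/s] or a callable of time.
    The zero-order sink is active only where c > 0 so concentrations stay
    non-negative.  Returns concentration fields, the total-mass trace
    (trapezoidal quadrature) and the D_app / mesh-size traces at the output
    times.
    """
    c0_field = np.asarray(initial.c, dtype=float)
    if c0_field.shape != grid.n:
        raise ConfigError(f"initial field shape {c0_field.shape} != grid {grid.n}")

    D_fun: Callable[[float], float]
    if callable(D_schedule):
        D_fun = D_schedule
    else:
        D_val = float(D_schedule)
        if not D_val > 0:
            raise DomainError("D_app must be > 0")
        D_fun = lambda t: D_val  # noqa: E731

    sink = params.k_r * params.c0  # mg/mL/s, zero-order
    shape = grid.n
    bmask = _boundary_mask(shape) if grid.boundary == "fixed-concentration" else None

    def rhs(t: float, y: npt.NDArray[np.float64]) -> npt.NDArray[np.float64]:
        c = y.reshape(shape)
        if bmask is not None:
            c = c.copy()
            c[bmask] = grid.bc_value
        dc = D_fun(t) * _laplacian(c, grid)
        if sink > 0:
            dc = dc - sink * (c > 0)
        if bmask is not None:
            dc[bmask] = 0.0
        return dc.ravel()

    y0 = c0_field.copy()
    if bmask is not None:
        y0[bmask] = grid.bc_value

    t0, t1 = float(t_span[0]), float(t_span[1])
    if t_eval is None:
        t_eval = np.linspace(t0, t1, n_output)
    else:
        t_eval = np.asarray(t_eval, dtype=float)
    if atol is None:
        scale = max(float(np.max(np.abs(c0_field))), grid.bc_value, 1e-30)
        atol = 1e-10 * scale

    sol = solve_ivp(
        rhs,
        (t0, t1),
        y0.ravel(),
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(f"ODE integration failed: {sol.message} (nfev={sol.nfev})")

    w = grid.quadrature_weights() * 1e6  # m^3 -> mL so mass is in mg with c in mg/mL
    fields = []
    masses = np.empty(len(sol.t))
    for k, tk in enumerate(sol.t):
        ck = np.maximum(sol.y[:, k].reshape(shape), 0.0)
        fields.append(ConcentrationField(c=ck, t=float(tk)))
        masses[k] = float(np.sum(ck * w))

    D_trace = np.array([D_fun(tk) for tk in sol.t], dtype=float)
    if xi_schedule is not None:
        xi_trace = np.array([xi_schedule(tk) for tk in sol.t], dtype=float)
    else:
        xi_trace = np.full(len(sol.t), np.nan)
    return SimulationResult(
        times=np.asarray(sol.t, dtype=float),
        fields=tuple(fields),
        D_app_trace=D_trace,
        xi_trace=xi_trace,
        total_mass=masses,
        grid=grid,
    )


def coupled_virtual_test(
    protocol: LoadingProtocol,
    asls: ASLSParams,
    transport: TransportParams,
    grid: GridSpec,
    initial: ConcentrationField | None = None,
    **solver_kwargs,
) -> tuple[MechanicalCurve, SimulationResult]:
    """One-way coupled virtual compression test.

    At each time the aSLS modulus E(t) sets the mesh size, which sets D_app,
    which parameterises the transport PDE.  Mechanics is never fed back from
    transport.  With ``strain_rate = 0`` (no loading) the modulus is held at
    its instantaneous value E(0) = E0 + E1 and the run reduces to a
    constant-D reaction-diffusion solve.
    """
    if initial is None:
        initial = ConcentrationField(c=np.full(grid.n, transport.c0, dtype=float), t=0.0)

    if protocol.strain_rate == 0:
        E_of_t = lambda t: asls_modulus(0.0, asls)  # noqa: E731
    else:
        E_of_t = lambda t: asls_modulus(t, asls)  # noqa: E731

    def xi_of_t(t: float) -> float:
        return mesh_size(E_of_t(t), transport)

    def D_of_t(t: float) -> float:
        return apparent_diffusion(xi_of_t(t), transport)

    curve = stress_response(protocol, asls)
    result = solve_reaction_diffusion(
        grid,
        transport,
        D_of_t,
        (0.0, protocol.t_end),
        initial,
        xi_schedule=xi_of_t,
        **solver_kwargs,
    )
    return curve, result
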