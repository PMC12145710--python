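import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viscogel.errors import ConfigError, DomainError
from viscogel.mechanics import ASLSParams, LoadingProtocol
from viscogel.synthetic import generate_concentration_field
from viscogel.transport import (
    BOLTZMANN,
    ConcentrationField,
    GridSpec,
    TransportParams,
    apparent_diffusion,
    carman_kozeny_permeability,
    coupled_virtual_test,
    diffusion_time,
    hindrance_factor,
    mesh_size,
    solve_reaction_diffusion,
    stokes_einstein_diffusivity,
)


class TestMeshSize:
    def test_cube_root_scaling(self, transport_params):
        xi = mesh_size(700.0, transport_params)
        assert mesh_size(8 * 700.0, transport_params) == pytest.approx(xi / 2, rel=1e-12)

    def test_gelation_degree_ratio(self):
        base = dict(r_h=1e-9, kappa=1e-14, mu=1e-3, T=298.15)
        xi_full = mesh_size(5000.0, TransportParams(alpha=1.0, **base))
        xi_partial = mesh_size(5000.0, TransportParams(alpha=0.65, **base))
        assert xi_partial / xi_full == pytest.approx((1 / 0.65) ** (2 / 9), rel=1e-12)

    def test_arbitrary_precision_oracle(self, transport_params):
        # sympy with rational inputs at 20 significant digits
        assert mesh_size(5000.0, transport_params) == pytest.approx(1.8455750813460154e-08, rel=1e-12)

    def test_rejects_non_positive_modulus(self, transport_params):
        with pytest.raises(DomainError):
            mesh_size(0.0, transport_params)
        with pytest.raises(DomainError):
            mesh_size(-10.0, transport_params)


class TestApparentDiffusion:
    def test_free_solution_limit(self):
        p = TransportParams(r_h=1e-9, kappa=1e6, mu=1e-3, T=298.15)
        D0 = stokes_einstein_diffusivity(p)
        # exact arithmetic: kB*T/(6*pi*mu*r_h), checked against sympy at 20 digits
        assert D0 == pytest.approx(2.1838206749456210e-10, rel=1e-12)
        assert apparent_diffusion(1.0, p) == pytest.approx(D0, rel=1e-9)

    def test_monotone_in_xi_kappa_mu(self):
        base = dict(r_h=1e-9, mu=1e-3, T=298.15)
        p = TransportParams(kappa=1e-14, **base)
        assert apparent_diffusion(2e-8, p) > apparent_diffusion(1e-8, p)
        assert apparent_diffusion(1e-8, TransportParams(kappa=2e-14, **base)) > apparent_diffusion(1e-8, p)
        p_thick = TransportParams(r_h=1e-9, kappa=1e-14, mu=2e-3, T=298.15)
        assert apparent_diffusion(1e-8, p_thick) < apparent_diffusion(1e-8, p)

    @given(
        log_xi=st.floats(min_value=-9, max_value=-5),
        log_kappa=st.floats(min_value=-18, max_value=-10),
        log_rh=st.floats(min_value=-10, max_value=-8),
    )
    @settings(max_examples=200, deadline=None)
    def test_hindrance_in_unit_interval(self, log_xi, log_kappa, log_rh):
        p = TransportParams(r_h=10**log_rh, kappa=10**log_kappa, mu=1e-3)
        h = hindrance_factor(10**log_xi, p)
        assert 0 < h <= 1.0
        assert apparent_diffusion(10**log_xi, p) <= stokes_einstein_diffusivity(p)

    def test_rejects_bad_xi(self, transport_params):
        with pytest.raises(DomainError):
            apparent_diffusion(0.0, transport_params)


class TestDiffusionTime:
    def test_arithmetic(self):
        assert diffusion_time(1e-3, 1e-10) == pytest.approx(1e4, rel=1e-12)

    def test_quadratic_in_length(self):
        assert diffusion_time(2e-3, 1e-10) == pytest.approx(4 * diffusion_time(1e-3, 1e-10))

    def test_vanishes_at_large_D(self):
        assert diffusion_time(1e-3, 1e10) < 1e-15

    def test_rejects_non_positive(self):
        with pytest.raises(DomainError):
            diffusion_time(0.0, 1e-10)


def test_carman_kozeny_helper():
    kappa = carman_kozeny_permeability(r_f=5e-9, p=0.9, C=20.0)
    assert kappa == pytest.approx(25e-18 * 0.729 / (20 * 0.01), rel=1e-12)
    with pytest.raises(DomainError):
        carman_kozeny_permeability(r_f=5e-9, p=1.0)


class TestGridSpec:
    def test_rejects_tiny_grid(self):
        with pytest.raises(ConfigError):
            GridSpec(extents=(1e-3, 1e-3, 1e-3), n=(2, 3, 3))

    def test_quadrature_weights_integrate_box(self):
        g = GridSpec(extents=(1e-3, 2e-3, 3e-3), n=(5, 7, 9))
        assert g.quadrature_weights().sum() == pytest.approx(6e-9, rel=1e-12)


L_BOX = 1e-3
D_REF = 2e-10


def _cosine_setup(n_x: int):
    grid = GridSpec(extents=(L_BOX, L_BOX, L_BOX), n=(n_x, 3, 3))
    init = generate_concentration_field(grid, "cosine-mode", c0=10.0, amplitude=2.0)
    return grid, init


class TestSolveReactionDiffusion:
    def test_uniform_steady_state(self, transport_params, small_grid):
        init = generate_concentration_field(small_grid, "uniform", c0=10.0)
        res = solve_reaction_diffusion(small_grid, transport_params, D_REF, (0.0, 500.0), init)
        for f in res.fields:
            assert f.c == pytest.approx(10.0, rel=1e-9)

    def test_cosine_eigenmode_decay(self, transport_params):
        grid, init = _cosine_setup(21)
        tau = 1.0 / (D_REF * (math.pi / L_BOX) ** 2)
        res = solve_reaction_diffusion(grid, transport_params, D_REF, (0.0, 2 * tau), init,
                                       t_eval=[0.0, 0.5 * tau, tau, 2 * tau])
        x = grid.axes()[0]
        mode = np.cos(np.pi * x / L_BOX)
        for k in range(1, 4):
            t = res.times[k]
            amp = np.dot(res.fields[k].c[:, 1, 1] - 10.0, mode) / np.dot(mode, mode)
            expected = 2.0 * math.exp(-D_REF * (math.pi / L_BOX) ** 2 * t)
            assert amp == pytest.approx(expected, rel=1e-2)

    def test_grid_convergence_second_order(self, transport_params):
        tau = 1.0 / (D_REF * (math.pi / L_BOX) ** 2)
        errs = []
        for n_x in (11, 21):
            grid, init = _cosine_setup(n_x)
            res = solve_reaction_diffusion(grid, transport_params, D_REF, (0.0, tau), init,
                                           n_output=3, rtol=1e-10)
            x = grid.axes()[0]
            exact = 10.0 + 2.0 * np.exp(-D_REF * (math.pi / L_BOX) ** 2 * res.times[-1]) * np.cos(np.pi * x / L_BOX)
            errs.append(np.sqrt(np.mean((res.fields[-1].c[:, 1, 1] - exact) ** 2)))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.15)

    def test_mass_conservation_no_sink(self, transport_params):
        grid, init = _cosine_setup(21)
        tau = 1.0 / (D_REF * (math.pi / L_BOX) ** 2)
        res = solve_reaction_diffusion(grid, transport_params, D_REF, (0.0, tau), init)
        drift = np.abs(res.total_mass - res.total_mass[0]) / res.total_mass[0]
        assert drift.max() <= 1e-6

    def test_zero_order_sink_mass_trace(self, small_grid):
        p = TransportParams(r_h=1e-9, kappa=1e-14, mu=1e-3, k_r=1e-3, c0=10.0)
        init = generate_concentration_field(small_grid, "uniform", c0=10.0)
        res = solve_reaction_diffusion(small_grid, p, D_REF, (0.0, 100.0), init)
        V_mL = np.prod(small_grid.extents) * 1e6
        expected = res.total_mass[0] - p.k_r * p.c0 * V_mL * res.times
        assert res.total_mass == pytest.approx(expected, rel=1e-6)

    def test_non_negativity_with_strong_sink(self, small_grid):
        p = TransportParams(r_h=1e-9, kappa=1e-14, mu=1e-3, k_r=0.5, c0=1.0)
        init = generate_concentration_field(small_grid, "uniform", c0=1.0)
        res = solve_reaction_diffusion(small_grid, p, D_REF, (0.0, 10.0), init)
        for f in res.fields:
            assert np.all(f.c >= 0)

    def test_piecewise_constant_D_matches_chained_runs(self, transport_params):
        grid, init = _cosine_setup(11)
        tau = 1.0 / (D_REF * (math.pi / L_BOX) ** 2)
        t_mid, t_end = 0.4 * tau, 0.8 * tau
        D1, D2 = D_REF, 2.5 * D_REF

        def schedule(t):
            return D1 if t < t_mid else D2

        res = solve_reaction_diffusion(grid, transport_params, schedule, (0.0, t_end), init,
                                       t_eval=[0.0, t_mid, t_end], rtol=1e-10)
        first = solve_reaction_diffusion(grid, transport_params, D1, (0.0, t_mid), init,
                                         t_eval=[0.0, t_mid], rtol=1e-10)
        second = solve_reaction_diffusion(
            grid, transport_params, D2, (t_mid, t_end),
            ConcentrationField(c=first.fields[-1].c, t=t_mid),
            t_eval=[t_mid, t_end], rtol=1e-10,
        )
        assert res.fields[-1].c == pytest.approx(second.fields[-1].c, rel=1e-5)

    def test_fixed_concentration_boundary_relaxes_to_bc(self):
        grid = GridSpec(extents=(L_BOX, L_BOX, L_BOX), n=(9, 9, 9),
                        boundary="fixed-concentration", bc_value=5.0)
        p = TransportParams(r_h=1e-9, kappa=1e-14, mu=1e-3)
        init = generate_concentration_field(grid, "uniform", c0=10.0)
        tau = diffusion_time(L_BOX, D_REF)
        res = solve_reaction_diffusion(grid, p, D_REF, (0.0, 3 * tau), init)
        assert res.fields[-1].c == pytest.approx(5.0, rel=1e-3)

    def test_shape_mismatch_rejected(self, transport_params, small_grid):
        init = ConcentrationField(c=np.zeros((5, 5, 5)))
        with pytest.raises(ConfigError):
            solve_reaction_diffusion(small_grid, transport_params, D_REF, (0.0, 1.0), init)


class TestCoupledVirtualTest:
    asls = ASLSParams(E0=1000.0, E1=1000.0, eta1=10000.0, eta2=0.0, phi=0.0)

    def test_no_loading_reduces_to_constant_D(self, transport_params, small_grid):
        protocol = LoadingProtocol(strain_rate=0.0, t_end=50.0, n_samples=11)
        curve, res = coupled_virtual_test(protocol, self.asls, transport_params, small_grid)
        assert np.all(curve.stress == 0)
        E_inst = 2000.0
        D_const = apparent_diffusion(mesh_size(E_inst, transport_params), transport_params)
        assert res.D_app_trace == pytest.approx(D_const, rel=1e-12)

    def test_D_trace_monotone_non_decreasing(self, transport_params, small_grid):
        protocol = LoadingProtocol(strain_rate=0.001, t_end=50.0, n_samples=11)
        curve, res = coupled_virtual_test(protocol, self.asls, transport_params, small_grid)
        assert np.all(np.diff(res.D_app_trace) >= -1e-25)
        assert np.all(np.diff(res.xi_trace) >= -1e-20)

    def test_traces_follow_modulus(self, transport_params, small_grid):
        from viscogel.mechanics import asls_modulus

        protocol = LoadingProtocol(strain_rate=0.001, t_end=50.0, n_samples=11)
        _, res = coupled_virtual_test(protocol, self.asls, transport_params, small_grid)
        for t, xi in zip(res.times, res.xi_trace):
            assert xi == pytest.approx(mesh_size(asls_modulus(t, self.asls), transport_params), rel=1e-12)
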