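"""Model assembly: parameters, tumor factor, reactions, advection, full RHS."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from angiosim import (
    Grid1D,
    ModelParameters,
    SystemState,
    advective_flux_divergence,
    build_laplacian_matrix,
    michaelis_menten,
    reaction_terms,
    semi_discrete_rhs,
    tumor_factor,
)
from angiosim.model import make_rhs
from angiosim.operators import apply_laplacian


class TestParameters:
    def test_defaults_satisfy_sign_conventions(self, params):
        assert params.alpha2 < 0
        assert params.d_max == pytest.approx(0.1)  # oxygen diffuses fastest
        assert params.alpha_max == pytest.approx(0.1)

    @pytest.mark.parametrize(
        "override", [{"d_C": 0.0}, {"k3": -1.0}, {"alpha2": 0.1}, {"K_O": 0.0}, {"eps": -0.01}]
    )
    def test_bad_signs_rejected(self, override):
        with pytest.raises(ValueError):
            ModelParameters(**override)


class TestMichaelisMenten:
    def test_anchor_values(self):
        assert michaelis_menten(0.0, 0.2) == 0.0
        assert michaelis_menten(0.2, 0.2) == pytest.approx(0.5)  # half-saturation
        assert michaelis_menten(0.8, 0.2) == pytest.approx(0.8)

    def test_monotone_and_bounded(self):
        O = np.linspace(0, 50, 200)
        H = michaelis_menten(O, 0.2)
        assert np.all(np.diff(H) > 0)
        assert np.all(H < 1.0)

    def test_nonpositive_half_saturation_rejected(self):
        with pytest.raises(ValueError):
            michaelis_menten(0.5, 0.0)


class TestTumorFactor:
    def test_profile_shape(self):
        g = Grid1D(L_f=1.0, M=50)
        prof = tumor_factor(g, eps=0.01, alpha4=1.0)
        assert prof.T[-1] == pytest.approx(1.0)  # peak at the tumor edge
        assert np.all(prof.T >= 0) and np.all(prof.T <= 1)
        assert np.all(np.diff(prof.T) >= 0)
        assert np.all(prof.phi >= 0) and np.all(prof.phi <= prof.T + 1e-15)

    def test_pointwise_values(self):
        g = Grid1D(L_f=1.0, M=10)
        prof = tumor_factor(g, eps=0.01, alpha4=1.0)
        assert prof.T[9] == pytest.approx(np.exp(-1.0))  # x = 0.9
        assert prof.phi[-1] == pytest.approx(np.log(2.0))  # T = 1 there

    @pytest.mark.parametrize("eps,alpha4", [(0.0, 1.0), (0.01, 0.0), (-1.0, 1.0)])
    def test_invalid_arguments_rejected(self, eps, alpha4):
        with pytest.raises(ValueError):
            tumor_factor(Grid1D(1.0, 8), eps, alpha4)


class TestReactions:
    def test_zero_state_leaves_only_constitutive_protease_source(self, grid, params, profile):
        state = SystemState.zeros(grid.n_nodes)
        r = reaction_terms(state, params, profile)
        np.testing.assert_allclose(r[1], params.k5 * profile.T)
        for k in (0, 2, 3, 4):
            np.testing.assert_allclose(r[k], 0.0)

    def test_full_density_kills_proliferation(self, grid, params, profile):
        state = SystemState.zeros(grid.n_nodes)
        state.C[:] = 1.0
        state.O[:] = 0.7
        r = reaction_terms(state, params, profile)
        np.testing.assert_allclose(r[0], 0.0, atol=1e-15)

    def test_hand_computed_single_node(self, grid, params, profile):
        """Elementwise evaluation against independent scalar arithmetic."""
        n = grid.n_nodes
        state = SystemState.from_fields(
            *[np.full(n, v) for v in (0.5, 0.1, 0.2, 1.0, 0.2)]
        )
        prof = dataclasses.replace(profile, T=np.ones(n))
        r = reaction_terms(state, params, prof)
        np.testing.assert_allclose(
            r[:, 0], [0.0125, 0.07, -0.01, -0.005, -0.005], atol=1e-15
        )

    def test_nan_input_identifies_component(self, grid, params, profile):
        state = SystemState.zeros(grid.n_nodes)
        state.I[3] = np.nan
        with pytest.raises(FloatingPointError, match="component I"):
            reaction_terms(state, params, profile)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_finite_on_invariant_region(self, seed):
        """Reactions stay finite for any state inside the invariant box."""
        from angiosim import build_region

        params = ModelParameters()
        grid = Grid1D(1.0, 8)
        profile = tumor_factor(grid, params.eps, params.alpha4)
        region = build_region(params)
        rng = np.random.default_rng(seed)
        data = np.stack(
            [rng.uniform(lo, hi, grid.n_nodes) for lo, hi in region.intervals.values()]
        )
        r = reaction_terms(SystemState(data), params, profile)
        assert np.all(np.isfinite(r))


class TestAdvection:
    def test_zero_cell_density_gives_zero_flux(self, grid, params, profile):
        state = SystemState.zeros(grid.n_nodes)
        state.F[:] = np.sin(grid.nodes)
        state.I[:] = grid.nodes**2
        out = advective_flux_divergence(state, profile, grid, params)
        np.testing.assert_allclose(out, 0.0)

    def test_uniform_cues_give_zero_flux(self, grid, params, zero_taf_profile):
        state = SystemState.zeros(grid.n_nodes)
        state.C[:] = 0.8
        state.F[:] = 0.5
        state.I[:] = 0.2
        out = advective_flux_divergence(state, zero_taf_profile, grid, params)
        np.testing.assert_allclose(out, 0.0, atol=1e-14)

    def test_linear_fields_give_exact_constant_divergence(self, params, zero_taf_profile):
        # F = x and C = x make the flux alpha1 * x, whose gradient is alpha1
        grid = Grid1D(L_f=1.0, M=8)
        x = grid.nodes
        state = SystemState.zeros(grid.n_nodes)
        state.C[:] = x
        state.F[:] = x
        out = advective_flux_divergence(state, zero_taf_profile, grid, params)
        np.testing.assert_allclose(out, params.alpha1, atol=1e-12)


class TestSemiDiscreteRHS:
    def test_zero_state_is_fixed_point_without_tumor_factor(
        self, grid, params, zero_taf_profile
    ):
        state = SystemState.zeros(grid.n_nodes)
        rhs = semi_discrete_rhs(state, 0.0, params, zero_taf_profile, grid)
        np.testing.assert_allclose(rhs, 0.0)

    def test_assembly_decomposes_into_diffusion_plus_transport_reaction(
        self, grid, params, profile
    ):
        rng = np.random.default_rng(11)
        state = SystemState(rng.uniform(0.0, 1.0, (5, grid.n_nodes)))
        total = semi_discrete_rhs(state, 0.0, params, profile, grid)
        diffusion = np.zeros_like(total)
        for k, d in [(0, params.d_C), (1, params.d_P), (2, params.d_I), (4, params.d_O)]:
            diffusion[k] = d * apply_laplacian(state.data[k], grid.dx)
        nonlinear = reaction_terms(state, params, profile)
        nonlinear[0] -= advective_flux_divergence(state, profile, grid, params)
        np.testing.assert_allclose(total, diffusion + nonlinear, rtol=1e-12, atol=1e-12)

    def test_matrix_free_oxygen_row_matches_dense_product(self, params, profile):
        """With C = 0 the oxygen row is pure diffusion: d_O * D_xx @ O."""
        grid = Grid1D(L_f=1.0, M=4)
        prof = tumor_factor(grid, params.eps, params.alpha4)
        state = SystemState.zeros(grid.n_nodes)
        state.O[:] = np.cos(np.pi * grid.nodes)
        rhs = semi_discrete_rhs(state, 0.0, params, prof, grid)
        dense = build_laplacian_matrix(grid).toarray()
        np.testing.assert_allclose(rhs[4], params.d_O * dense @ state.O, atol=1e-13)

    def test_matrix_row_is_purely_local(self, grid, params, profile):
        """The ECM equation has no spatial operator: rough F, smooth output."""
        rng = np.random.default_rng(5)
        state = SystemState.zeros(grid.n_nodes)
        state.F[:] = rng.standard_normal(grid.n_nodes)
        state.P[:] = 0.3
        rhs = semi_discrete_rhs(state, 0.0, params, profile, grid)
        np.testing.assert_allclose(rhs[3], -params.k2 * 0.3 * state.F, atol=1e-14)

    def test_converges_to_continuous_rhs_at_second_order(self):
        """On smooth no-flux fields the discrete RHS approaches the PDE RHS."""
        from angiosim.mms import _continuous_rhs_expressions, _x, _t, manufactured_solution
        import sympy as sym

        params = ModelParameters(eps=0.09)
        sol = manufactured_solution("neumann_compatible")
        rhs_exprs = _continuous_rhs_expressions(sol.expressions, params)
        rhs_funcs = {k: sym.lambdify((_x, _t), e, "numpy") for k, e in rhs_exprs.items()}
        errs = []
        for M in (16, 32, 64):
            grid = Grid1D(L_f=1.0, M=M)
            prof = tumor_factor(grid, params.eps, params.alpha4)
            x = grid.nodes
            data = np.stack([np.broadcast_to(sol.fields[k](x, 0.0), x.shape) for k in "CPIFO"])
            num = semi_discrete_rhs(SystemState(data.copy()), 0.0, params, prof, grid)
            exact = np.stack(
                [np.broadcast_to(rhs_funcs[k](x, 0.0), x.shape) for k in "CPIFO"]
            )
            errs.append(np.sqrt(grid.dx * np.sum((num - exact) ** 2)))
        rates = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(rates > 1.7) and np.all(rates < 2.4)

    def test_sources_are_added(self, grid, params, zero_taf_profile):
        state = SystemState.zeros(grid.n_nodes)
        bump = [lambda x, t, k=k: np.full_like(x, float(k)) for k in range(5)]
        rhs = make_rhs(params, zero_taf_profile, grid, sources=bump)(state.data, 0.0)
        for k in range(5):
            np.testing.assert_allclose(rhs[k], float(k))
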