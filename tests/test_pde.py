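"""Coefficient construction, initialization, and the spatial operators."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gliosim as g
from gliosim.grids import TissueLabel


class TestQuiescenceSwitch:
    @pytest.mark.parametrize(
        "u, expected", [(0.0, 0.0), (1.0, 1.0), (0.5, 0.125), (1.7, 1.0)]
    )
    def test_values(self, u, expected):
        assert g.quiescence_switch(u) == pytest.approx(expected, abs=1e-15)

    def test_rejects_negative_density(self):
        with pytest.raises(ValueError):
            g.quiescence_switch(-0.1)

    @given(st.floats(0, 2), st.floats(0, 2))
    def test_monotone(self, a, b):
        lo, hi = sorted([a, b])
        assert g.quiescence_switch(lo) <= g.quiescence_switch(hi)


class TestReactionRates:
    def test_zero_population_is_inert(self):
        dp, dq = g.reaction_rates(
            np.zeros(3), np.array([0.0, 0.5, 1.0]), np.full(3, 0.1), np.full(3, 0.2)
        )
        assert np.all(dp == 0) and np.all(dq == 0)

    def test_low_density_growth_is_nearly_exponential(self):
        p = np.array([1e-5])
        dp, dq = g.reaction_rates(p, np.zeros(1), np.array([0.05]), np.array([0.04]))
        assert dp[0] == pytest.approx(0.05 * 1e-5, rel=1e-9)
        assert dq[0] == pytest.approx(0.0, abs=1e-20)

    def test_at_capacity_growth_stops_and_total_is_conserved(self):
        p = np.array([0.4])
        q = np.array([0.6])  # p + q = 1
        dp, dq = g.reaction_rates(p, q, np.array([0.05]), np.array([0.04]))
        assert dp[0] == pytest.approx(-0.04 * 0.4, rel=1e-12)
        assert dq[0] == pytest.approx(0.04 * 0.4, rel=1e-12)


class TestCoefficients:
    def test_tissue_rules(self, grid32, baseline32, row1):
        coeffs = g.build_coefficients(grid32, baseline32, row1)
        lab = grid32.labels
        tumor = baseline32.enhancing_mask | baseline32.edema_mask | baseline32.necrotic_mask
        white_clean = (lab == TissueLabel.WHITE) & ~tumor
        gray_clean = (lab == TissueLabel.GRAY) & ~tumor
        assert np.all(coeffs.D[white_clean] == row1.D_w)
        assert np.all(coeffs.D[gray_clean] == row1.D_w / 2)
        assert np.all(coeffs.D[tumor] == row1.D_w)
        fluid = (lab == TissueLabel.CSF) | (lab == TissueLabel.BACKGROUND)
        for f in (coeffs.D, coeffs.rho, coeffs.k):
            assert np.all(f[fluid] == 0)

    def test_rate_regions(self, grid32, baseline32, row1):
        coeffs = g.build_coefficients(grid32, baseline32, row1)
        enh = baseline32.enhancing_mask
        ede = baseline32.edema_mask
        assert np.allclose(coeffs.rho[enh], row1.rho1)
        assert np.allclose(coeffs.k[enh], row1.k1)
        # edema and unsegmented tissue share the low-density rates
        assert np.allclose(coeffs.rho[ede], row1.rho0)
        normal = grid32.tissue_mask & ~enh & ~ede & ~baseline32.necrotic_mask
        assert np.allclose(coeffs.rho[normal], row1.rho0)
        assert np.allclose(coeffs.k[normal], row1.k0)


class TestImputation:
    def test_intensity_window_endpoints(self, baseline32, row1):
        state = g.impute_initial_state(baseline32, row1)
        enh = baseline32.enhancing_mask
        ede = baseline32.edema_mask
        t1 = baseline32.t1c[enh]
        assert state.p[enh][np.argmax(t1)] == pytest.approx(row1.I_c[1], abs=1e-12)
        assert state.p[enh][np.argmin(t1)] == pytest.approx(row1.I_c[0], abs=1e-12)
        t2 = baseline32.t2[ede]
        # brighter T2 signal means lower imputed density
        assert state.p[ede][np.argmax(t2)] == pytest.approx(row1.I_e[0], abs=1e-12)
        assert state.p[ede][np.argmin(t2)] == pytest.approx(row1.I_e[1], abs=1e-12)

    def test_necrotic_core_is_dense_quiescent(self, baseline32, row1):
        state = g.impute_initial_state(baseline32, row1)
        nec = baseline32.necrotic_mask
        assert np.all(state.p[nec] == 0)
        assert np.all(state.q[nec] == 0.9)
        assert np.all(state.q[~nec] == 0)

    def test_constant_intensity_maps_to_midpoint(self, baseline32, row1):
        study = g.ImagingStudy(
            grid=baseline32.grid,
            t1c=np.full(baseline32.grid.dims, 7.0),
            t2=np.full(baseline32.grid.dims, 9.0),
            enhancing_mask=baseline32.enhancing_mask,
            edema_mask=baseline32.edema_mask,
        )
        state = g.impute_initial_state(study, row1)
        mid_c = sum(row1.I_c) / 2
        mid_e = sum(row1.I_e) / 2
        assert np.allclose(state.p[study.enhancing_mask], mid_c)
        assert np.allclose(state.p[study.edema_mask], mid_e)

    def test_empty_enhancing_mask_is_an_error(self, baseline32, row1):
        study = g.ImagingStudy(
            grid=baseline32.grid,
            t1c=baseline32.t1c,
            t2=baseline32.t2,
            enhancing_mask=np.zeros(baseline32.grid.dims, bool),
            edema_mask=baseline32.edema_mask,
        )
        with pytest.raises(ValueError, match="enhancing"):
            g.impute_initial_state(study, row1)


class TestDiffusionDivergence:
    def test_uniform_field_has_zero_divergence(self):
        rng = np.random.default_rng(0)
        D = rng.uniform(0, 0.06, (6, 5, 4))
        out = g.diffusion_divergence(np.full((6, 5, 4), 0.7), D, (0.9, 0.9, 7.0))
        assert np.allclose(out, 0.0, atol=1e-15)

    def test_discrete_conservation(self):
        rng = np.random.default_rng(1)
        field = rng.uniform(0, 1, (7, 6, 5))
        D = rng.uniform(0, 0.06, (7, 6, 5))
        D[rng.uniform(size=D.shape) < 0.3] = 0.0
        out = g.diffusion_divergence(field, D, (0.9, 0.9, 7.0))
        assert abs(out.sum()) < 1e-12

    def test_blocked_face_hand_example(self):
        # 1-D line of three voxels: D = (1, 1, 0), field = (0, 1, 0).
        # Only the left face carries flux; the middle voxel loses mass at
        # rate 1 and the right face is sealed by zero diffusivity.
        field = np.array([0.0, 1.0, 0.0]).reshape(3, 1, 1)
        D = np.array([1.0, 1.0, 0.0]).reshape(3, 1, 1)
        out = g.diffusion_divergence(field, D, (1.0, 1.0, 1.0))
        assert out[1, 0, 0] == pytest.approx(-1.0)
        assert out[0, 0, 0] == pytest.approx(1.0)
        assert out[2, 0, 0] == pytest.approx(0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            g.diffusion_divergence(np.zeros((3, 3, 3)), np.zeros((4, 3, 3)), (1, 1, 1))
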