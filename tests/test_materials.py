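"""Constitutive stress laws: closed-form values, the tension–compression
switch, tensor-vs-1D equivalence, and analytic tangents."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tissuevisco as tv
from tissuevisco.kinematics import StretchPoint, uniaxial_state
from tissuevisco.materials import (
    CartilageParams,
    LigamentParams,
    TissueModel,
    VolumetricConfig,
    uniaxial_components,
    uniaxial_nominal_stress_tensor_route,
)

A2, A3, A4, A5 = 2.213e6, 3.879, 0.3653e6, 0.652
B1, B2, B3, B4 = 0.425e5, 0.5e5, 14.2e6, 190e6


class TestElasticEnergy:
    def test_ligament_reference_state_offset(self, ligament_model):
        """The exponential fiber law leaves the constant a2/(2a3) at λ = 1."""
        s = uniaxial_state(StretchPoint(1.0))
        assert tv.elastic_energy(s, ligament_model) == pytest.approx(A2 / (2 * A3))

    def test_compression_has_no_fiber_energy(self):
        model = TissueModel(LigamentParams(a1=1.0e5, a2=A2, a3=A3))
        s = uniaxial_state(StretchPoint(0.9))
        assert tv.elastic_energy(s, model) == pytest.approx(1.0e5 * (s.I1 - 3.0))

    def test_cartilage_zero_at_reference(self, cartilage_model):
        s = uniaxial_state(StretchPoint(1.0))
        assert tv.elastic_energy(s, cartilage_model) == 0.0


class TestElasticStress:
    def test_fiber_term_vanishes_at_I4_equal_1(self, ligament_model, cartilage_model):
        s = uniaxial_state(StretchPoint(1.0))
        np.testing.assert_allclose(tv.elastic_stress(s, ligament_model), 0.0)
        S_c = tv.elastic_stress(s, cartilage_model)
        np.testing.assert_allclose(S_c, 2.0 * B1 * np.eye(3))

    def test_ligament_fiber_stress_value(self, ligament_model):
        s = uniaxial_state(StretchPoint(1.1))
        u = 1.1 ** 2 - 1.0
        expected = 2.0 * A2 * u * np.exp(A3 * u ** 2)
        assert tv.elastic_stress(s, ligament_model)[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_cartilage_fiber_stress_value(self, cartilage_model):
        s = uniaxial_state(StretchPoint(1.1))
        u = 1.1 ** 2 - 1.0
        expected = 2.0 * B1 + 2.0 * B2 * u + 2.0 * B3 * u ** 2
        assert tv.elastic_stress(s, cartilage_model)[0, 0] == pytest.approx(expected, rel=1e-12)


class TestShortTermViscousStress:
    def test_zero_rate_gives_zero(self, ligament_model):
        s = uniaxial_state(StretchPoint(1.12, 0.0))
        np.testing.assert_allclose(tv.short_term_viscous_stress(s, ligament_model), 0.0)

    def test_compression_gives_zero(self, ligament_model, cartilage_model):
        s = uniaxial_state(StretchPoint(0.95, 0.4))
        np.testing.assert_allclose(tv.short_term_viscous_stress(s, ligament_model), 0.0)
        np.testing.assert_allclose(tv.short_term_viscous_stress(s, cartilage_model), 0.0)

    def test_ligament_uniaxial_value(self, ligament_model):
        lam, lamdot = 1.1, 0.25
        s = uniaxial_state(StretchPoint(lam, lamdot))
        u = lam ** 2 - 1.0
        expected = 4.0 * A4 * lam * u * np.exp(A5 * u ** 2) * lamdot
        assert tv.short_term_viscous_stress(s, ligament_model)[0, 0] == pytest.approx(
            expected, rel=1e-12
        )


class TestPressureAndLateralStress:
    def test_zero_matrix_constant(self, ligament_model):
        assert tv.uniaxial_pressure(1.3, ligament_model) == 0.0

    def test_reference_value(self):
        model = TissueModel(LigamentParams(a1=2.0e5))
        assert tv.uniaxial_pressure(1.0, model) == pytest.approx(-4.0e5)

    @pytest.mark.parametrize("lam", [1.0, 1.05, 1.15])
    def test_lateral_stress_free(self, lam):
        """With p = −2a1/λ the lateral second PK components vanish."""
        model = TissueModel(LigamentParams(a1=2.0e5, a2=A2, a3=A3))
        s = uniaxial_state(StretchPoint(lam, 0.0))
        S = tv.elastic_stress(s, model) + tv.uniaxial_pressure(lam, model) * np.linalg.inv(s.C)
        assert abs(S[1, 1]) < 1e-6 * max(abs(S[0, 0]), 1.0)
        assert abs(S[2, 2]) < 1e-6 * max(abs(S[0, 0]), 1.0)


class TestUniaxialNominalStress:
    def test_zero_at_reference(self, ligament_model, cartilage_model):
        for model in (ligament_model, cartilage_model):
            assert tv.uniaxial_nominal_stress(StretchPoint(1.0, 0.7), model) == 0.0

    def test_ligament_equilibrium_at_10pct(self, ligament_model):
        """P11(λ=1.10, λ̇=0) ≈ 1.213 MPa for the reference constants."""
        P = tv.uniaxial_nominal_stress(StretchPoint(1.10, 0.0), ligament_model)
        assert P == pytest.approx(1.2132e6, rel=2e-4)

    @pytest.mark.parametrize("tissue", ["ligament", "cartilage"])
    def test_closed_form_matches_tensor_pipeline(self, tissue, ligament_model, cartilage_model):
        """1D closed forms equal uniaxial_state → stresses → P = J⁻¹FS."""
        base = ligament_model if tissue == "ligament" else cartilage_model
        params = (
            LigamentParams(a1=1.1e5, a2=A2, a3=A3, a4=A4, a5=A5)
            if tissue == "ligament"
            else base.params
        )
        model = TissueModel(params)
        for lam in np.linspace(0.9, 1.2, 13):
            for lamdot in (0.0, 0.25, -0.1):
                pt = StretchPoint(float(lam), lamdot)
                a = tv.uniaxial_nominal_stress(pt, model)
                b = uniaxial_nominal_stress_tensor_route(pt, model)
                assert a == pytest.approx(b, rel=1e-10, abs=1e-6)

    @settings(deadline=None, derandomize=True)
    @given(lam=st.floats(1.001, 1.3), d1=st.floats(0.01, 1.0), scale=st.floats(0.1, 3.0))
    def test_rate_linearity(self, lam, d1, scale, ligament_model, cartilage_model):
        """P11(λ, λ̇) − P11(λ, 0) is proportional to λ̇ for both tissues."""
        for model in (ligament_model, cartilage_model):
            p0 = tv.uniaxial_nominal_stress(StretchPoint(lam, 0.0), model)
            v1 = tv.uniaxial_nominal_stress(StretchPoint(lam, d1), model) - p0
            v2 = tv.uniaxial_nominal_stress(StretchPoint(lam, scale * d1), model) - p0
            assert v2 == pytest.approx(scale * v1, rel=1e-9, abs=1e-9)

    def test_continuity_at_tension_compression_switch(self, ligament_model, cartilage_model):
        for model in (ligament_model, cartilage_model):
            below = tv.uniaxial_nominal_stress(StretchPoint(1.0 - 1e-9, 0.5), model)
            above = tv.uniaxial_nominal_stress(StretchPoint(1.0 + 1e-9, 0.5), model)
            assert abs(above - below) < 1.0  # Pa, for MPa-scale stresses

    def test_convexity_guard(self, ligament_model, cartilage_model):
        """dP11/dλ > 0 on (1, 1.3] at non-negative rates."""
        for model in (ligament_model, cartilage_model):
            for lam in np.linspace(1.01, 1.3, 30):
                for rate in (0.0, 0.25, 1.0):
                    dP, _ = tv.material_tangents_uniaxial(StretchPoint(float(lam), rate), model)
                    assert dP > 0.0


class TestMaterialTangents:
    @pytest.mark.parametrize("tissue", ["ligament", "cartilage"])
    def test_matches_central_differences(self, tissue, ligament_model, cartilage_model):
        model = ligament_model if tissue == "ligament" else cartilage_model
        rng = np.random.default_rng(42)
        for _ in range(20):
            lam = float(rng.uniform(1.02, 1.2))
            rate = float(rng.uniform(0.0, 0.5))
            dP_dlam, dP_drate = tv.material_tangents_uniaxial(StretchPoint(lam, rate), model)
            h = 1e-5
            fd_lam = (
                tv.uniaxial_nominal_stress(StretchPoint(lam + h, rate), model)
                - tv.uniaxial_nominal_stress(StretchPoint(lam - h, rate), model)
            ) / (2 * h)
            hr = 1e-4
            fd_rate = (
                tv.uniaxial_nominal_stress(StretchPoint(lam, rate + hr), model)
                - tv.uniaxial_nominal_stress(StretchPoint(lam, rate - hr), model)
            ) / (2 * hr)
            assert dP_dlam == pytest.approx(fd_lam, rel=1e-6)
            assert dP_drate == pytest.approx(fd_rate, rel=1e-6)

    def test_rate_tangent_independent_of_rate(self, ligament_model):
        _, d1 = tv.material_tangents_uniaxial(StretchPoint(1.1, 0.0), ligament_model)
        _, d2 = tv.material_tangents_uniaxial(StretchPoint(1.1, 0.9), ligament_model)
        assert d1 == pytest.approx(d2, rel=1e-14)

    def test_compression_branch_rejected(self, ligament_model):
        with pytest.raises(ValueError):
            tv.material_tangents_uniaxial(StretchPoint(0.99, 0.1), ligament_model)


class TestConfinedCompression:
    def test_zero_at_reference(self, cartilage_model):
        assert tv.confined_compression_equilibrium(1.0, cartilage_model.params) == 0.0

    def test_matrix_only_value(self):
        params = CartilageParams(b1=B1)
        P = tv.confined_compression_equilibrium(0.9, params, VolumetricConfig(kappa=0.0))
        assert P == pytest.approx(2.0 * B1 * (0.9 - 1.0 / 0.9), rel=1e-12)

    def test_monotone_in_compression(self, cartilage_model):
        lam = np.linspace(0.7, 1.0, 40)
        P = tv.confined_compression_equilibrium(lam, cartilage_model.params)
        assert np.all(np.diff(P) > 0.0)  # less compressive toward λ = 1

    def test_tension_rejected(self, cartilage_model):
        with pytest.raises(ValueError):
            tv.confined_compression_equilibrium(1.05, cartilage_model.params)


class TestParameterValidation:
    def test_negative_constants_rejected(self):
        with pytest.raises(ValueError):
            LigamentParams(a2=-1.0)
        with pytest.raises(ValueError):
            CartilageParams(b4=-1.0)

    def test_vectorized_components_match_scalar(self, ligament_model):
        lam = np.array([0.95, 1.0, 1.05, 1.15])
        rate = np.array([0.1, 0.1, 0.2, 0.3])
        P_el, P_vs = uniaxial_components(lam, rate, ligament_model.params)
        for i in range(lam.size):
            total = tv.uniaxial_nominal_stress(StretchPoint(lam[i], rate[i]), ligament_model)
            assert P_el[i] + P_vs[i] == pytest.approx(total, rel=1e-12, abs=1e-9)
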