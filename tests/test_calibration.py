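"""Staged parameter identification: per-stage round trips, constraint
handling, determinism, and prediction across rates."""

import numpy as np
import pandas as pd
import pytest

import tissuevisco as tv
from tissuevisco.calibration import (
    ExperimentDataset,
    fit_confined_compression,
    fit_elastic,
    fit_short_term,
    fit_spectrum,
    staged_calibration,
)
from tissuevisco.materials import (
    CartilageParams,
    LigamentParams,
    VolumetricConfig,
    uniaxial_components,
)


def _equilibrium_dataset(params, lam_max=1.16, n=40):
    lam = np.linspace(1.0, lam_max, n)
    P, _ = uniaxial_components(lam, np.zeros_like(lam), params)
    return ExperimentDataset(
        kind="equilibrium_tension", table=pd.DataFrame({"stretch": lam, "P11_Pa": P})
    )


def _ramp_dataset(params, rate, strain=0.16, n=80):
    t = np.linspace(0.0, strain / rate, n)
    lam = 1.0 + rate * t
    P_el, P_vs = uniaxial_components(lam, np.full_like(lam, rate), params)
    return ExperimentDataset(
        kind="ramp_tension",
        table=pd.DataFrame({"time_s": t, "stretch": lam, "P11_Pa": P_el + P_vs}),
        rate=rate,
    )


class TestFitElastic:
    def test_ligament_round_trip(self, ligament_model):
        st = fit_elastic(_equilibrium_dataset(ligament_model.params), "ligament")
        assert st.params["a2"] == pytest.approx(ligament_model.params.a2, rel=1e-3)
        assert st.params["a3"] == pytest.approx(ligament_model.params.a3, rel=1e-3)
        assert st.converged

    def test_cartilage_round_trip_with_fixed_b1(self, cartilage_model):
        p = cartilage_model.params
        st = fit_elastic(_equilibrium_dataset(p, lam_max=1.10, n=12), "cartilage", p.b1)
        assert st.params["b2"] == pytest.approx(p.b2, rel=1e-6)
        assert st.params["b3"] == pytest.approx(p.b3, rel=1e-6)

    def test_all_zero_stress_flags_lower_bound(self):
        lam = np.linspace(1.0, 1.1, 10)
        ds = ExperimentDataset(
            kind="equilibrium_tension",
            table=pd.DataFrame({"stretch": lam, "P11_Pa": np.zeros_like(lam)}),
        )
        st = fit_elastic(ds, "ligament")
        assert st.params["a2"] == 0.0
        assert "a2" in st.active_constraints

    def test_wrong_kind_rejected(self, ligament_model):
        ds = _ramp_dataset(ligament_model.params, 0.25)
        with pytest.raises(ValueError, match="equilibrium_tension"):
            fit_elastic(ds, "ligament")


class TestFitShortTerm:
    def test_ligament_round_trip(self, ligament_model):
        elastic = LigamentParams(a2=ligament_model.params.a2, a3=ligament_model.params.a3)
        st = fit_short_term(_ramp_dataset(ligament_model.params, 0.25), elastic)
        assert st.params["a4"] == pytest.approx(ligament_model.params.a4, rel=1e-3)
        assert st.params["a5"] == pytest.approx(ligament_model.params.a5, rel=1e-3)

    def test_fit_at_25_predicts_faster_rates(self, ligament_model):
        """Constants fit at 25 %/s reproduce the 38 and 50 %/s curves."""
        elastic = LigamentParams(a2=ligament_model.params.a2, a3=ligament_model.params.a3)
        st = fit_short_term(_ramp_dataset(ligament_model.params, 0.25), elastic)
        fitted = LigamentParams(
            a2=elastic.a2, a3=elastic.a3, a4=st.params["a4"], a5=st.params["a5"]
        )
        for rate in (0.38, 0.50):
            truth = _ramp_dataset(ligament_model.params, rate).table["P11_Pa"].to_numpy()
            lam = _ramp_dataset(ligament_model.params, rate).table["stretch"].to_numpy()
            P_el, P_vs = uniaxial_components(lam, np.full_like(lam, rate), fitted)
            assert np.abs(P_el + P_vs - truth).max() < 1e-3 * truth.max()

    def test_cartilage_round_trip(self, cartilage_model):
        p = cartilage_model.params
        elastic = CartilageParams(b1=p.b1, b2=p.b2, b3=p.b3)
        st = fit_short_term(_ramp_dataset(p, 0.0015, strain=0.02), elastic)
        assert st.params["b4"] == pytest.approx(p.b4, rel=1e-6)

    def test_zero_rate_rejected(self, ligament_model):
        ds = _ramp_dataset(ligament_model.params, 0.25)
        ds.rate = None
        with pytest.raises(ValueError, match="rate"):
            fit_short_term(ds, ligament_model.params)


class TestFitSpectrum:
    def test_weights_sum_exactly_to_one(self, ligament_model):
        spec = ligament_model.spectrum
        t = np.concatenate([[0.0], np.geomspace(0.1, 5e4, 150)])
        y = np.asarray(spec.reduced_relaxation(t))
        fitted, st = fit_spectrum((t, y), n_terms=3, seed=0)
        assert abs(fitted.w.sum() - 1.0) < 1e-9
        assert st.residual_rms < 1e-4

    def test_round_trip_curve_level(self, ligament_model):
        spec = ligament_model.spectrum
        t = np.concatenate([[0.0], np.geomspace(0.1, 5e4, 200)])
        y = np.asarray(spec.reduced_relaxation(t))
        fitted, st = fit_spectrum((t, y), n_terms=3, seed=1)
        R_fit = np.asarray(fitted.reduced_relaxation(t))
        assert np.sqrt(np.mean((R_fit - y) ** 2)) < 1e-4
        # parameter level, with the ill-conditioning allowance
        np.testing.assert_allclose(fitted.tau, spec.tau, rtol=0.05)
        np.testing.assert_allclose(fitted.w, spec.w, rtol=0.05)

    def test_single_exponential_exact_recovery(self):
        t = np.linspace(0.0, 50.0, 60)
        y = np.exp(-t / 7.5)
        fitted, _ = fit_spectrum((t, y), n_terms=1, seed=0)
        assert fitted.tau[0] == pytest.approx(7.5, rel=1e-6)
        assert fitted.w[0] == 1.0

    def test_non_normalized_input_rejected(self):
        t = np.linspace(0.0, 50.0, 60)
        with pytest.raises(ValueError, match="normalized"):
            fit_spectrum((t, 1.0e6 * np.exp(-t / 7.5)))

    def test_short_span_warns(self):
        t = np.concatenate([[0.0], np.linspace(0.5, 1.0, 20)])
        y = np.exp(-t / 5.0)
        with pytest.warns(UserWarning, match="decade"):
            fit_spectrum((t, y), n_terms=1, seed=0)


class TestFitConfinedCompression:
    def test_round_trip(self, cartilage_model):
        b1 = cartilage_model.params.b1
        vol = VolumetricConfig(kappa_ratio=10.0)
        lam = np.linspace(0.85, 1.0, 10)
        P = tv.confined_compression_equilibrium(lam, cartilage_model.params, vol)
        ds = ExperimentDataset(
            kind="confined_compression", table=pd.DataFrame({"stretch": lam, "P11_Pa": P})
        )
        st = fit_confined_compression(ds, vol)
        assert st.params["b1"] == pytest.approx(b1, rel=1e-3)

    def test_zero_data_flagged(self):
        lam = np.linspace(0.9, 1.0, 8)
        ds = ExperimentDataset(
            kind="confined_compression",
            table=pd.DataFrame({"stretch": lam, "P11_Pa": np.zeros_like(lam)}),
        )
        st = fit_confined_compression(ds)
        assert st.params["b1"] == 0.0
        assert "b1" in st.active_constraints

    def test_tension_samples_rejected(self):
        lam = np.linspace(0.95, 1.05, 8)
        with pytest.raises(ValueError, match="tension"):
            ExperimentDataset(
                kind="confined_compression",
                table=pd.DataFrame({"stretch": lam, "P11_Pa": np.zeros_like(lam)}),
            )

    def test_kappa_misspecification_biases_b1(self, cartilage_model):
        """Fitting with a 2× wrong volumetric ratio shifts b1 — the documented
        sensitivity of the confined-compression stage to the volumetric law."""
        gen_vol = VolumetricConfig(kappa_ratio=10.0)
        lam = np.linspace(0.85, 1.0, 10)
        P = tv.confined_compression_equilibrium(lam, cartilage_model.params, gen_vol)
        ds = ExperimentDataset(
            kind="confined_compression", table=pd.DataFrame({"stretch": lam, "P11_Pa": P})
        )
        st_wrong = fit_confined_compression(ds, VolumetricConfig(kappa_ratio=20.0))
        b1_true = cartilage_model.params.b1
        rel_bias = abs(st_wrong.params["b1"] - b1_true) / b1_true
        assert 0.2 < rel_bias < 0.8


class TestStagedCalibration:
    def test_ligament_end_to_end_round_trip(self, ligament_model):
        suite = tv.reference_suite("ligament")
        res = staged_calibration(suite, "ligament", seed=0)
        p, truth = res.params, ligament_model.params
        for name in ("a2", "a3", "a4", "a5"):
            assert getattr(p, name) == pytest.approx(getattr(truth, name), rel=1e-3)
        t = np.geomspace(0.1, 5e4, 100)
        R_fit = np.asarray(res.spectrum.reduced_relaxation(t))
        R_true = np.asarray(ligament_model.spectrum.reduced_relaxation(t))
        assert np.sqrt(np.mean((R_fit - R_true) ** 2)) < 1e-4

    def test_cartilage_end_to_end_round_trip(self, cartilage_model):
        suite = tv.reference_suite("cartilage")
        res = staged_calibration(suite, "cartilage", seed=0)
        p, truth = res.params, cartilage_model.params
        for name in ("b1", "b2", "b3", "b4"):
            assert getattr(p, name) == pytest.approx(getattr(truth, name), rel=1e-3)

    def test_permuted_dataset_order_identical(self):
        suite = tv.reference_suite("ligament")
        a = staged_calibration(suite, "ligament", seed=0)
        b = staged_calibration(list(reversed(suite)), "ligament", seed=0)
        assert a.to_dict() == b.to_dict()

    def test_same_seed_bit_identical(self):
        suite = tv.reference_suite("ligament", noise=tv.NoiseSpec(relative_sd=0.02, seed=5))
        a = staged_calibration(suite, "ligament", seed=7)
        b = staged_calibration(suite, "ligament", seed=7)
        assert a.to_dict() == b.to_dict()

    def test_missing_stage_names_the_kind(self):
        suite = [d for d in tv.reference_suite("ligament") if d.kind != "relaxation"]
        with pytest.raises(ValueError, match="relaxation"):
            staged_calibration(suite, "ligament")

    def test_refit_is_a_fixed_point(self, ligament_model):
        """Simulating with fitted parameters and refitting returns the same
        parameters (noiseless self-consistency)."""
        res1 = staged_calibration(tv.reference_suite("ligament"), "ligament", seed=0)
        model1 = tv.TissueModel(params=res1.params, spectrum=res1.spectrum)
        suite2 = tv.reference_suite("ligament", model=model1)
        res2 = staged_calibration(suite2, "ligament", seed=0)
        for name in ("a2", "a3", "a4", "a5"):
            assert getattr(res2.params, name) == pytest.approx(
                getattr(res1.params, name), rel=1e-3
            )

    def test_sigma_w_constraint_exact(self):
        res = staged_calibration(tv.reference_suite("ligament"), "ligament", seed=0)
        assert abs(res.spectrum.w.sum() - 1.0) < 1e-9
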