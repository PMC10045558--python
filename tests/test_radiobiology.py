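"""LQ survival model, survival fractions, RBE and CBE derivation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from borondose.dose import DoseComponents
from borondose.errors import (
    DegenerateFitError,
    InputValidationError,
    InsufficientDataError,
    UndefinedSFError,
)
from borondose.radiobiology import (
    ColonyAssayRecord,
    LQModel,
    LQParameters,
    MixedFieldModel,
    beam_rbe,
    carrier_cbe,
    dose_for_sf,
    fit_lq,
    lq_survival,
    survival_fraction,
)

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")

params_strategy = st.tuples(
    st.floats(min_value=0.0, max_value=1.0),
    st.floats(min_value=0.0, max_value=0.2),
).filter(lambda ab: ab[0] + ab[1] > 1e-6)


class TestSurvivalFraction:
    def test_equal_plating_efficiency_gives_unity(self):
        control = ColonyAssayRecord("control", 0.0, 100, [60, 60, 60])
        treated = ColonyAssayRecord("t", 2.0, 100, [60, 60, 60])
        assert survival_fraction(treated, control).sf == pytest.approx(1.0)

    def test_hand_computed_ratio(self):
        # treated mean PE = (30+35+25)/300 = 0.30, control PE = 0.60 -> SF = 0.5
        control = ColonyAssayRecord("control", 0.0, 100, [60, 60, 60])
        treated = ColonyAssayRecord("t", 2.0, 100, [30, 35, 25])
        res = survival_fraction(treated, control)
        assert res.sf == pytest.approx(0.5)
        assert res.se > 0

    def test_all_treated_dishes_empty_is_undefined(self):
        control = ColonyAssayRecord("control", 0.0, 100, [60, 60, 60])
        treated = ColonyAssayRecord("t", 8.0, 100, [0, 0, 0])
        with pytest.raises(UndefinedSFError):
            survival_fraction(treated, control)

    def test_zero_control_is_undefined(self):
        control = ColonyAssayRecord("control", 0.0, 100, [0, 0, 0])
        treated = ColonyAssayRecord("t", 2.0, 100, [10, 10, 10])
        with pytest.raises(UndefinedSFError):
            survival_fraction(treated, control)

    def test_sf_above_one_is_flagged_not_fatal(self):
        control = ColonyAssayRecord("control", 0.0, 100, [50, 50, 50])
        treated = ColonyAssayRecord("t", 1.0, 100, [60, 60, 60])
        with pytest.warns(UserWarning, match="> 1"):
            res = survival_fraction(treated, control)
        assert res.sf == pytest.approx(1.2)

    def test_colonies_cannot_exceed_seeded(self):
        with pytest.raises(InputValidationError):
            ColonyAssayRecord("bad", 0.0, 100, [150])


class TestLQSurvival:
    def test_unit_survival_at_zero_dose(self):
        assert lq_survival(LQParameters(0.3, 0.03), 0.0) == 1.0

    def test_pure_exponential_when_beta_zero(self):
        p = LQParameters(alpha=0.5, beta=0.0)
        assert lq_survival(p, 2.0) == pytest.approx(np.exp(-1.0))

    def test_negative_dose_rejected(self):
        with pytest.raises(InputValidationError):
            lq_survival(LQParameters(0.3, 0.03), -1.0)

    @given(params_strategy, st.floats(min_value=0.01, max_value=10))
    def test_strictly_decreasing_in_dose(self, ab, d):
        p = LQParameters(*ab)
        assert lq_survival(p, d + 0.5) < lq_survival(p, d)


class TestDoseForSF:
    def test_sf_one_needs_no_dose(self):
        assert dose_for_sf(LQParameters(0.2, 0.02), 1.0) == 0.0

    @given(params_strategy, st.floats(min_value=0.01, max_value=0.99))
    def test_round_trip_with_lq_survival(self, ab, target):
        p = LQParameters(*ab)
        d = dose_for_sf(p, target)
        assert lq_survival(p, d) == pytest.approx(target, abs=1e-9)

    def test_beta_zero_limit_is_analytic(self):
        p = LQParameters(alpha=0.5, beta=0.0)
        assert dose_for_sf(p, 0.1) == pytest.approx(np.log(10) / 0.5)

    def test_monotone_decreasing_in_target(self):
        p = LQParameters(0.2, 0.02)
        targets = [0.8, 0.5, 0.2, 0.1, 0.01]
        doses = [dose_for_sf(p, s) for s in targets]
        assert all(a < b for a, b in zip(doses, doses[1:]))

    def test_invalid_targets_rejected(self):
        p = LQParameters(0.2, 0.02)
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(InputValidationError):
                dose_for_sf(p, bad)


class TestFitLQ:
    def test_noise_free_recovery_is_exact(self):
        true = LQParameters(0.21, 0.021)
        doses = np.array([1.0, 2.0, 4.0, 6.0, 8.0])
        sfs = [lq_survival(true, d) for d in doses]
        est = fit_lq(doses, sfs)
        assert est.alpha == pytest.approx(true.alpha, rel=1e-6)
        assert est.beta == pytest.approx(true.beta, rel=1e-6)

    def test_fit_inverts_its_own_predictions(self):
        true = LQParameters(0.4, 0.0)
        doses = [1.0, 3.0, 5.0, 7.0]
        res = LQModel(doses, [lq_survival(true, d) for d in doses]).fit()
        assert res.predict(3.0) == pytest.approx(lq_survival(true, 3.0), rel=1e-9)

    def test_too_few_doses_is_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_lq([2.0], [0.5])
        with pytest.raises(InsufficientDataError):
            fit_lq([2.0, 4.0], [0.5, 0.2])

    def test_flat_survival_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_lq([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])

    def test_from_assay_builds_weighted_fit(self, rng):
        true = LQParameters(0.217, 0.0217)
        control = ColonyAssayRecord("control", 0.0, 1000, [620, 590, 610])
        records = []
        for d in (1.0, 2.0, 4.0, 6.0, 8.0):
            mean = 1000 * 0.6 * lq_survival(true, d)
            records.append(ColonyAssayRecord(f"d{d}", d, 1000, rng.poisson(mean, size=3)))
        res = LQModel.from_assay(records, control).fit()
        assert res.alpha == pytest.approx(true.alpha, abs=0.15)
        ci = res.conf_int(n_boot=99, seed=7)
        assert (ci["lower"] <= ci["upper"]).all()

    def test_bootstrap_is_reproducible(self):
        control = ColonyAssayRecord("control", 0.0, 1000, [620, 590, 610])
        records = [
            ColonyAssayRecord(f"d{d}", d, 1000, c)
            for d, c in [(1.0, [450, 470, 440]), (2.0, [300, 310, 295]), (4.0, [120, 110, 125]), (6.0, [40, 45, 38])]
        ]
        res = LQModel.from_assay(records, control).fit()
        b1 = res.bootstrap(n_boot=50, seed=3)
        b2 = res.bootstrap(n_boot=50, seed=3)
        assert np.array_equal(b1, b2)


class TestBeamRBE:
    def test_equal_doses_give_unity(self):
        assert beam_rbe(3.0, 3.0) == 1.0

    def test_simple_ratio(self):
        assert beam_rbe(6.45, 3.225) == pytest.approx(2.0)

    def test_nonpositive_doses_rejected(self):
        with pytest.raises(InputValidationError):
            beam_rbe(6.45, 0.0)

    def test_matches_grid_search_on_simulated_beam_curve(self, mixed_field, photon_lq, invitro_preset):
        """RBE from the model equals a brute-force endpoint search on the curve."""
        from borondose.radiobiology import lq_survival as sf

        rbe_nh = invitro_preset["rbe_nh"]
        w = mixed_field.photon_equivalent_dose_rate_weight(rbe_nh)
        ref = dose_for_sf(photon_lq, 0.1)
        # grid search the beam physical dose whose photon-equivalent SF crosses 0.1
        grid = np.linspace(0.01, 10, 200001)
        sf_grid = sf(photon_lq, grid * w)
        d_beam = grid[np.argmin(np.abs(sf_grid - 0.1))]
        assert beam_rbe(ref, d_beam) == pytest.approx(w, rel=1e-2)


class TestCarrierCBE:
    def test_boron_only_field_has_unit_cbe(self):
        c = DoseComponents(d_boron=6.45, d_nitrogen=0, d_hydrogen=0, d_gamma=0)
        assert carrier_cbe(6.45, c) == pytest.approx(1.0)

    @given(
        st.floats(min_value=0.2, max_value=5.0),
        st.floats(min_value=0.1, max_value=3.0),
        st.floats(min_value=0.0, max_value=0.5),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_planted_cbe_round_trip_is_exact(self, cbe_true, d_b, d_nh, d_g):
        c = DoseComponents.from_lumped(d_b, d_nh, d_g)
        ref = cbe_true * d_b + 3.0 * d_nh + d_g
        assert carrier_cbe(ref, c, rbe_nh=3.0) == pytest.approx(cbe_true, abs=1e-9)

    def test_no_boron_dose_is_an_error(self):
        c = DoseComponents(d_boron=0, d_nitrogen=0.2, d_hydrogen=0.2, d_gamma=0.5)
        with pytest.raises(InputValidationError):
            carrier_cbe(6.45, c)

    def test_negative_cbe_is_flagged(self):
        c = DoseComponents.from_lumped(0.5, 2.0, 2.0)
        with pytest.warns(UserWarning, match="negative CBE"):
            assert carrier_cbe(1.0, c) < 0

    def test_below_unity_cbe_is_valid_without_warning(self, mixed_field, invitro_preset):
        import warnings

        spec = invitro_preset["carriers"]["cRGD+MID"]
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            cbe = mixed_field.derive_cbe(
                "cRGD+MID", spec["beam_dose_at_endpoint"], invitro_preset["d_photon_ref"]
            )
        assert cbe == pytest.approx(0.75, abs=1e-9)

    def test_calibrated_model_transfers_across_carriers(self, invitro_preset):
        """Calibrating on one carrier predicts the other carrier's CBE."""
        p = invitro_preset
        beam = p["beam"]
        ladder = sorted(beam["ladder"].items())
        model = MixedFieldModel(
            [t for t, _ in ladder],
            [d for _, d in ladder],
            nh_fraction=float(beam["nh_fraction"]),
            boron_gy_per_s_per_conc=float(beam["kerma_b10"]) * float(beam["thermal_flux"]),
            concentrations={},
        )
        bpa = p["carriers"]["BPA"]
        model.calibrate_concentration(
            "BPA", bpa["beam_dose_at_endpoint"], bpa["cbe"], p["d_photon_ref"], p["rbe_nh"]
        )
        assert model.derive_cbe(
            "BPA", bpa["beam_dose_at_endpoint"], p["d_photon_ref"], p["rbe_nh"]
        ) == pytest.approx(2.69, abs=1e-9)
        # same physical model, the other carrier's preset concentration
        crgd = p["carriers"]["cRGD-MID-AC"]
        model.concentrations["cRGD-MID-AC"] = crgd["effective_concentration"]
        derived = model.derive_cbe(
            "cRGD-MID-AC", crgd["beam_dose_at_endpoint"], p["d_photon_ref"], p["rbe_nh"]
        )
        assert derived == pytest.approx(2.26, rel=0.10)


class TestMixedFieldModel:
    def test_ladder_interpolates_and_extrapolates(self, mixed_field):
        assert mixed_field.beam_dose(600) == pytest.approx(0.48)
        assert mixed_field.beam_dose(900) == pytest.approx((0.48 + 1.01) / 2)
        beyond = mixed_field.beam_dose(2400)
        assert beyond > 1.21
        assert mixed_field.time_for_beam_dose(beyond) == pytest.approx(2400)

    def test_decompose_splits_by_fractions(self, mixed_field):
        c = mixed_field.decompose("BPA", 0.8)
        assert c.d_nh == pytest.approx(0.8 * 0.3125)
        assert c.d_gamma == pytest.approx(0.8 * 0.6875)
        assert c.d_boron > 0

    def test_group_survival_hits_endpoint_at_calibrated_beam_dose(
        self, mixed_field, photon_lq, invitro_preset
    ):
        """At the calibrated endpoint beam dose the mixed-field SF is exactly 0.1."""
        for carrier, spec in invitro_preset["carriers"].items():
            t = mixed_field.time_for_beam_dose(spec["beam_dose_at_endpoint"])
            sf = mixed_field.group_survival(carrier, t, spec["cbe"], photon_lq)
            assert sf == pytest.approx(0.1, abs=1e-9)
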