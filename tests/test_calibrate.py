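import numpy as np
import pytest

from nemaindent.calibrate import (
    CalibrationProblem,
    CalibrationResult,
    fit_envelope,
    fit_moduli,
    objective,
    percent_change,
)
from nemaindent.curves import FDCurve


class TestObjective:
    def test_self_consistency_is_zero(self, bdm_curve_l0):
        """A target generated by the same forward model evaluates to ~0."""
        prob = CalibrationProblem(target=bdm_curve_l0, level=0)
        val = objective((150.0, 1200.0, 840.0), prob)
        # bounded by the terminal-point force tolerance of the set-force
        # protocol (1e-3 nN), far below any physical misfit
        assert val < 0.01

    def test_scaled_target_gives_positive_misfit(self, bdm_curve_l0):
        target = FDCurve(
            bdm_curve_l0.displacement, 1.5 * bdm_curve_l0.force,
            {"source": "measured"},
        )
        prob = CalibrationProblem(target=target, level=0)
        assert objective((150.0, 1200.0, 840.0), prob) > 10.0

    def test_wrong_compartment_alternative_fits_worse(self, bdm_curve_l0):
        prob = CalibrationProblem(target=bdm_curve_l0, level=0)
        good = objective((150.0, 1200.0, 840.0), prob)
        bad = objective((150.0, 900.0, 1400.0), prob)
        assert good < bad

    def test_out_of_bounds_moduli_rejected(self, bdm_curve_l0):
        prob = CalibrationProblem(target=bdm_curve_l0, level=0)
        with pytest.raises(ValueError):
            objective((1.0, 1200.0, 840.0), prob)

    def test_cache_returns_identical_value(self, bdm_curve_l0):
        prob = CalibrationProblem(target=bdm_curve_l0, level=0)
        v1 = objective((120.0, 1000.0, 700.0), prob)
        v2 = objective((120.0, 1000.0, 700.0), prob)
        assert v1 == v2


class TestFitModuli:
    def test_collapsed_bounds_return_that_point(self, bdm_curve_l0):
        prob = CalibrationProblem(
            target=bdm_curve_l0,
            bounds=((150.0, 150.0001), (1200.0, 1200.0001), (840.0, 840.0001)),
            level=0,
        )
        res = fit_moduli(prob, max_evaluations=6, with_sensitivities=False)
        assert res.moduli_kPa[0] == pytest.approx(150.0, rel=1e-4)
        assert res.objective < 0.1

    def test_same_seed_identical_trace(self, bdm_curve_l0):
        def run():
            prob = CalibrationProblem(target=bdm_curve_l0, level=0)
            return fit_moduli(
                prob, max_evaluations=6, seed=3, multi_start=1,
                with_sensitivities=False, method="nelder-mead",
            )

        a, b = run(), run()
        assert len(a.trace) == len(b.trace)
        for (ma, fa), (mb, fb) in zip(a.trace, b.trace):
            assert ma == mb and fa == fb

    def test_never_worse_than_initial_guess(self, bdm_curve_l0):
        prob = CalibrationProblem(target=bdm_curve_l0, level=0)
        x0 = (200.0, 800.0, 500.0)
        res = fit_moduli(prob, max_evaluations=6, x0_kPa=x0, with_sensitivities=False)
        assert res.objective <= objective(x0, prob)


class TestFitEnvelope:
    def test_plumbing_orders_and_brackets(self, monkeypatch, bdm_curve_l0):
        """With a stubbed per-curve fit, the envelope reports fits in paper
        order and the mean lies within the min/max bracket."""
        import nemaindent.calibrate as cal

        canned = {
            0.9: CalibrationResult((100.0, 280.0, 800.0), 0.1, 5, True),
            1.0: CalibrationResult((150.0, 1200.0, 840.0), 0.1, 5, True),
            1.1: CalibrationResult((200.0, 2350.0, 1100.0), 0.1, 5, True),
        }

        def fake_fit(problem, **kwargs):
            scale = round(problem.target.force[-1] / bdm_curve_l0.force[-1], 1)
            return canned[scale]

        monkeypatch.setattr(cal, "fit_moduli", fake_fit)
        targets = {
            "min": FDCurve(bdm_curve_l0.displacement, 0.9 * bdm_curve_l0.force,
                           {"source": "measured"}),
            "mean": bdm_curve_l0,
            "max": FDCurve(bdm_curve_l0.displacement, 1.1 * bdm_curve_l0.force,
                           {"source": "measured"}),
        }
        prob = CalibrationProblem(target=bdm_curve_l0, level=0)
        env = cal.fit_envelope(targets, prob)
        ranges = env.ranges_kPa()
        assert list(ranges) == ["cuticle", "muscle", "pseudocoelom"]
        for i, name in enumerate(ranges):
            lo, hi = ranges[name]
            assert lo <= env.mean_fit.moduli_kPa[i] <= hi
        assert env.failed == ()

    def test_missing_target_rejected(self, bdm_curve_l0):
        prob = CalibrationProblem(target=bdm_curve_l0, level=0)
        with pytest.raises(ValueError, match="max"):
            fit_envelope({"min": bdm_curve_l0, "mean": bdm_curve_l0}, prob)


class TestPercentChange:
    def test_salt_pseudocoelom_drop(self):
        pc = percent_change((105.0, 390.0, 880.0), (90.0, 650.0, 76.0))
        assert pc.pseudocoelom == pytest.approx((880 - 76) / 880 * 100)
        assert pc.rounded()["pseudocoelom"] == 91

    def test_salt_cuticle_drop(self):
        pc = percent_change((105.0, 390.0, 880.0), (90.0, 650.0, 76.0))
        assert pc.rounded()["cuticle"] == 14

    def test_salt_muscle_increase(self):
        pc = percent_change((105.0, 390.0, 880.0), (90.0, 650.0, 76.0))
        assert pc.muscle == pytest.approx(-(650 - 390) / 390 * 100)
        assert pc.rounded()["muscle"] == -67  # negative = increase

    def test_accepts_calibration_results(self):
        a = CalibrationResult((105.0, 390.0, 880.0), 0.0, 1, True)
        b = CalibrationResult((90.0, 650.0, 76.0), 0.0, 1, True)
        pc = percent_change(a, b)
        assert pc.rounded() == {"cuticle": 14, "muscle": -67, "pseudocoelom": 91}

    def test_non_positive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change((0.0, 390.0, 880.0), (90.0, 650.0, 76.0))
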