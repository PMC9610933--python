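"""Tests for course simulation, recovery detection, and sedation-depth measure."""

import numpy as np
import pytest

from sedsim import (
    NoRecoveryWithinHorizon,
    NoSedationEvent,
    Regimen,
    SedationCourse,
    SimulationSettings,
    deep_sedation_ratio,
    predicted_recovery_time,
    simulate_course,
    triangle_crossing,
    planted_triangle,
)
from sedsim.pd_surface import ProbabilityTrajectory


def _course_from_p(grid, p, window=(3.0, 13.0)):
    return SedationCourse(
        regimen_id="plant",
        grid=grid,
        trajectories={},
        ce_alf_equiv=np.zeros_like(grid),
        p_lor=ProbabilityTrajectory(grid=grid, p_lor=p),
        procedure_window=window,
    )


class TestSimulateCourse:
    def test_empty_regimen_has_zero_probability(self, cfg):
        reg = Regimen(id="empty", boluses=(), T_p=10.0)
        course = simulate_course(reg, cfg.pk_registry, cfg.potency, cfg.surface)
        assert np.all(course.p_lor.p_lor == 0)

    def test_grid_spans_horizon(self, cfg, fx):
        course = simulate_course(
            fx.regimen("3"), cfg.pk_registry, cfg.potency, cfg.surface, cfg.settings
        )
        assert course.grid[0] == 0.0
        assert course.grid[-1] == pytest.approx(60.0)

    def test_missing_pk_parameters_named(self, cfg, fx):
        registry = {k: v for k, v in cfg.pk_registry.items() if k != "fentanyl"}
        with pytest.raises(KeyError, match="fentanyl"):
            simulate_course(fx.regimen("3"), registry, cfg.potency, cfg.surface)

    def test_course_equals_manual_composition(self, cfg, fx):
        from sedsim import effect_site_trajectory, probability_course

        reg = fx.regimen("3")
        settings = SimulationSettings(grid_step=0.05)
        course = simulate_course(reg, cfg.pk_registry, cfg.potency, cfg.surface, settings)
        grid = settings.grid()
        trajs = {
            d: effect_site_trajectory(
                [b for b in reg.boluses if b.drug_name == d], cfg.pk_registry[d], grid
            )
            for d in reg.drugs
        }
        manual = probability_course(trajs, cfg.potency, cfg.surface)
        np.testing.assert_allclose(course.p_lor.p_lor, manual.p_lor, rtol=1e-14)


class TestPredictedRecoveryTime:
    def test_subthreshold_course_raises_no_sedation_event(self):
        grid = np.linspace(0, 60, 601)
        course = _course_from_p(grid, np.full(601, 0.01))
        with pytest.raises(NoSedationEvent):
            predicted_recovery_time(course, 0.05)

    def test_no_recovery_within_horizon(self):
        grid = np.linspace(0, 60, 601)
        p = np.minimum(0.5, 0.5 * grid / 5.0)
        course = _course_from_p(grid, p)
        with pytest.raises(NoRecoveryWithinHorizon):
            predicted_recovery_time(course, 0.05)

    def test_triangle_crossing_closed_form(self):
        """The planted triangle recovers at exactly 19.375 min at the 5% cutoff."""
        traj = planted_triangle(peak_time=10.0, peak_p=0.8, end_time=20.0)
        t_rm = predicted_recovery_time(_course_from_p(traj.grid, traj.p_lor), 0.05)
        assert t_rm == pytest.approx(19.375, abs=1e-9)
        assert t_rm == pytest.approx(triangle_crossing(0.05), abs=1e-12)

    def test_recovery_is_after_probability_peak(self, cfg, fx):
        course = simulate_course(
            fx.regimen("5"), cfg.pk_registry, cfg.potency, cfg.surface,
            SimulationSettings(grid_step=0.02),
        )
        t_rm = predicted_recovery_time(course, 0.05)
        t_peak = course.grid[np.argmax(course.p_lor.p_lor)]
        assert t_rm > t_peak


class TestDeepSedationRatio:
    def test_fully_deep_window(self):
        grid = np.linspace(0, 20, 201)
        assert deep_sedation_ratio(_course_from_p(grid, np.ones(201))) == 1.0

    def test_never_deep_window(self):
        grid = np.linspace(0, 20, 201)
        assert deep_sedation_ratio(_course_from_p(grid, np.zeros(201))) == 0.0

    def test_half_deep_piecewise_constant(self):
        grid = np.linspace(0, 20, 2001)
        p = np.where(grid < 8.0, 0.9, 0.1)
        ratio = deep_sedation_ratio(_course_from_p(grid, p, window=(3.0, 13.0)))
        assert ratio == pytest.approx(0.5, abs=1e-3)

    def test_boundary_probability_counts_as_not_deep(self):
        grid = np.linspace(0, 20, 201)
        ratio = deep_sedation_ratio(_course_from_p(grid, np.full(201, 0.5)), 0.5)
        assert ratio == 0.0

    def test_ratio_invariant_to_horizon_extension(self, cfg, fx):
        reg = fx.regimen("8")
        short = simulate_course(
            reg, cfg.pk_registry, cfg.potency, cfg.surface, SimulationSettings(horizon=40.0, grid_step=0.02)
        )
        long = simulate_course(
            reg, cfg.pk_registry, cfg.potency, cfg.surface, SimulationSettings(horizon=60.0, grid_step=0.02)
        )
        assert deep_sedation_ratio(short) == pytest.approx(deep_sedation_ratio(long), abs=1e-12)


class TestGridRefinement:
    @pytest.mark.parametrize("regimen_id", ["5", "8"])
    def test_halving_grid_step_is_stable(self, cfg, fx, regimen_id):
        """T_rm and the deep-sedation ratio are step-size robust."""
        reg = fx.regimen(regimen_id)
        vals = []
        for step in (0.01, 0.005):
            course = simulate_course(
                reg, cfg.pk_registry, cfg.potency, cfg.surface, SimulationSettings(grid_step=step)
            )
            vals.append(
                (predicted_recovery_time(course, 0.05), deep_sedation_ratio(course, 0.50))
            )
        assert abs(vals[0][0] - vals[1][0]) < 0.01
        assert abs(vals[0][1] - vals[1][1]) < 0.005
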