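"""Parameter estimation: disparity/surface moments and the sigma_opacity fit."""

import math

import numpy as np
import pandas as pd
import pytest

from depthmatch.fitting import (
    estimate_disparity_params,
    estimate_surface_params,
    fit_panel,
    fit_sigma_opacity,
    recover_parameters,
    sigma_opacity_summary,
    _prediction_objective,
)
from depthmatch.model import ABSENT, DisparityCue, SurfaceCondition, VisibilityParams
from depthmatch.simulate import default_observer, make_design, simulate_trials


def _absent_trials(rows):
    return pd.DataFrame(
        [("o1", "exp1", ABSENT, "constant_angle", d, m, i) for i, (d, m) in enumerate(rows)],
        columns=[
            "observer_id", "experiment", "condition", "size_mode",
            "target_distance_m", "matched_distance_m", "trial_index",
        ],
    )


class TestEstimateDisparityParams:
    def test_two_point_mean_and_sd(self):
        cues = estimate_disparity_params(_absent_trials([(1.0, 0.95), (1.0, 1.05), (1.1, 1.0), (1.1, 1.2)]))
        assert cues[1.0].mu_disp == pytest.approx(1.0)
        assert cues[1.0].sigma_disp == pytest.approx(0.1 / math.sqrt(2))
        assert cues[1.1].mu_disp == pytest.approx(1.1)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(ValueError, match="variance"):
            estimate_disparity_params(_absent_trials([(1.0, 1.0)] * 10))

    def test_single_trial_per_distance_rejected_with_distance_named(self):
        with pytest.raises(ValueError, match="1.3"):
            estimate_disparity_params(_absent_trials([(1.3, 1.25)]))

    def test_surface_present_rows_rejected(self):
        df = _absent_trials([(1.0, 0.95), (1.0, 1.05)])
        df.loc[0, "condition"] = "opaque"
        with pytest.raises(ValueError, match="opaque"):
            estimate_disparity_params(df)

    def test_order_invariance(self):
        rows = [(1.0, 0.97), (1.0, 1.06), (1.0, 1.01), (1.2, 1.18), (1.2, 1.30)]
        a = estimate_disparity_params(_absent_trials(rows))
        b = estimate_disparity_params(_absent_trials(rows[::-1]))
        assert a == b


class TestEstimateSurfaceParams:
    @staticmethod
    def _loc(rows):
        return pd.DataFrame(
            [("o1", c, v, i) for i, (c, v) in enumerate(rows)],
            columns=["observer_id", "condition", "localized_distance_m", "trial_index"],
        )

    def test_two_point_mean_and_sd(self):
        conds = estimate_surface_params(self._loc([("opaque", 1.18), ("opaque", 1.22)]))
        assert conds["opaque"].mu_surf == pytest.approx(1.20)
        assert conds["opaque"].sigma_surf == pytest.approx(0.04 / math.sqrt(2))

    def test_each_condition_estimated_once(self):
        rows = [(c, v) for c in ("opaque", "highly_transparent") for v in (1.15, 1.2, 1.25)]
        conds = estimate_surface_params(self._loc(rows))
        assert sorted(conds) == ["highly_transparent", "opaque"]

    def test_translation_equivariance(self):
        rows = [("opaque", 1.1), ("opaque", 1.2), ("opaque", 1.3)]
        base = estimate_surface_params(self._loc(rows))["opaque"]
        shifted = estimate_surface_params(self._loc([(c, v + 0.25) for c, v in rows]))["opaque"]
        assert shifted.mu_surf == pytest.approx(base.mu_surf + 0.25)
        assert shifted.sigma_surf == pytest.approx(base.sigma_surf)


@pytest.fixture(scope="module")
def noiseless_observer():
    return default_observer("o1", seed=7, sigma_resp=0.0)


@pytest.fixture(scope="module")
def noiseless_trials(noiseless_observer, exp1_design):
    return simulate_trials(noiseless_observer, exp1_design, seed=11)


class TestFitSigmaOpacity:
    def test_noiseless_self_consistency(self, noiseless_observer, noiseless_trials, grid):
        p = noiseless_observer
        for label in ("opaque", "highly_transparent"):
            sub = noiseless_trials[noiseless_trials.condition == label]
            res = fit_sigma_opacity(sub, p.disparity_by_distance, p.surface_by_condition[label], grid)
            true = p.sigma_opacity_by_condition[label].sigma_opacity
            assert res.params.sigma_opacity == pytest.approx(true, abs=grid.step_m)
            assert not res.pinned

    def test_monotone_identifiability_around_truth(self, noiseless_observer, noiseless_trials, grid):
        p = noiseless_observer
        label = "opaque"
        sub = noiseless_trials[noiseless_trials.condition == label]
        f = _prediction_objective(
            sub, p.disparity_by_distance, p.surface_by_condition[label], grid, "means"
        )
        true = p.sigma_opacity_by_condition[label].sigma_opacity
        assert f(true) < f(2 * true)
        assert f(true) < f(0.5 * true)

    def test_no_conflict_data_pin_the_upper_bound(self, grid):
        """Means equal to the disparity distance everywhere demand an
        arbitrarily shallow prior, so the optimum lands on the upper bound."""
        rows = []
        for d in (1.3, 1.4, 1.5, 1.6):
            rows.extend(("o1", "exp1", "opaque", "constant_angle", d, d, i) for i in range(3))
        trials = pd.DataFrame(rows, columns=_absent_trials([]).columns)
        disparity = {d: DisparityCue(d, 0.05) for d in (1.3, 1.4, 1.5, 1.6)}
        cond = SurfaceCondition("opaque", mu_surf=1.2, sigma_surf=0.01)
        res = fit_sigma_opacity(trials, disparity, cond, grid, bounds=(0.001, 2.0))
        assert res.pinned
        assert res.params.sigma_opacity == pytest.approx(2.0)

    def test_returned_objective_beats_both_bounds(self, noiseless_observer, noiseless_trials, grid):
        p = noiseless_observer
        sub = noiseless_trials[noiseless_trials.condition == "opaque"]
        bounds = (0.01, 1.0)
        res = fit_sigma_opacity(sub, p.disparity_by_distance, p.surface_by_condition["opaque"], grid, bounds)
        f = _prediction_objective(
            sub, p.disparity_by_distance, p.surface_by_condition["opaque"], grid, "means"
        )
        assert res.objective <= f(bounds[0]) and res.objective <= f(bounds[1])

    def test_in_front_predictions_insensitive_to_sigma_opacity(self, grid):
        """Distances in front of the surface carry no occlusion conflict, so
        including them cannot bias the fit."""
        from depthmatch.model import predict_match

        cond = SurfaceCondition("opaque", mu_surf=1.2, sigma_surf=grid.step_m)
        for d in (0.9, 1.0, 1.1):
            preds = {
                predict_match(DisparityCue(d, 0.05), cond, VisibilityParams(so), grid)
                for so in (0.02, 0.1, 0.5)
            }
            assert len(preds) == 1

    def test_single_distance_rejected(self, grid):
        trials = pd.DataFrame(
            [("o1", "exp1", "opaque", "constant_angle", 1.5, 1.4, i) for i in range(5)],
            columns=_absent_trials([]).columns,
        )
        with pytest.raises(ValueError, match="2 target distances"):
            fit_sigma_opacity(trials, {1.5: DisparityCue(1.5, 0.05)},
                              SurfaceCondition("opaque", 1.2, 0.01), grid)


class TestFitPanel:
    def test_single_observer_panel_matches_direct_fit(self, small_panel, grid):
        oid = small_panel.params[0].observer_id
        trials = small_panel.trials[small_panel.trials.observer_id == oid]
        locs = small_panel.localizations[small_panel.localizations.observer_id == oid]
        fits = fit_panel(trials, locs, grid)
        assert len(fits) == 1
        fo = fits[0]
        disparity = estimate_disparity_params(trials[trials.condition == ABSENT])
        surface = estimate_surface_params(locs)
        direct = fit_sigma_opacity(
            trials[trials.condition == "opaque"], disparity, surface["opaque"], grid
        )
        assert fo.sigma_opacity_by_condition["opaque"] == direct.params
        assert fo.fit_quality["opaque"] == direct.objective

    def test_observer_order_does_not_change_results(self, small_panel, grid):
        trials = small_panel.trials
        shuffled = trials.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = fit_panel(trials, small_panel.localizations, grid)
        b = fit_panel(shuffled, small_panel.localizations, grid)
        assert [f.observer_id for f in a] == [f.observer_id for f in b]
        for fa, fb in zip(a, b):
            assert fa.sigma_opacity_by_condition == fb.sigma_opacity_by_condition

    def test_failure_names_the_observer(self, small_panel, grid):
        locs = small_panel.localizations
        broken = locs[locs.observer_id != small_panel.params[0].observer_id]
        with pytest.raises(RuntimeError, match=small_panel.params[0].observer_id):
            fit_panel(small_panel.trials, broken, grid)

    def test_summary_has_one_row_per_condition(self, small_panel, grid):
        fits = fit_panel(small_panel.trials, small_panel.localizations, grid)
        summary = sigma_opacity_summary(fits)
        assert sorted(summary.condition) == ["highly_transparent", "opaque", "semi_transparent"]
        assert (summary.n_observers == len(small_panel.params)).all()


@pytest.fixture(scope="module")
def tiny_setup():
    design = make_design("exp1", surface_conditions=("opaque", ABSENT))
    params = [default_observer(f"o{i}", seed=50 + i, design=design) for i in range(2)]
    return params, design


class TestRecoverParameters:
    def test_same_seed_reproduces_report(self, tiny_setup, grid):
        params, design = tiny_setup
        a = recover_parameters(params, design, n_reps=1, seed=3, grid=grid)
        b = recover_parameters(params, design, n_reps=1, seed=3, grid=grid)
        pd.testing.assert_frame_equal(a.per_condition, b.per_condition)
        assert a.rank_agreement == b.rank_agreement

    def test_noise_free_recovery_is_exact_to_grid_resolution(self, grid):
        design = make_design("exp1", surface_conditions=("opaque", "highly_transparent", ABSENT))
        params = [default_observer("o1", seed=60, design=design, sigma_resp=0.0)]
        rep = recover_parameters(params, design, n_reps=1, seed=4, grid=grid)
        assert (rep.per_condition.rmse <= grid.step_m).all()
        assert rep.rank_agreement == 1.0

    def test_bias_does_not_grow_with_more_trials(self, tiny_setup, grid):
        params, design = tiny_setup
        few = recover_parameters(params, design, n_reps=1, seed=8, grid=grid)
        many_design = make_design(
            "exp1", surface_conditions=("opaque", ABSENT), trials_per_distance=100
        )
        many = recover_parameters(params, many_design, n_reps=1, seed=8, grid=grid)
        assert abs(many.per_condition.bias.iloc[0]) <= abs(few.per_condition.bias.iloc[0]) + 0.005
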