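import itertools

import numpy as np
import pytest

from ecgtune.metrics import MetricReport
from ecgtune.mlp import ArchitectureSpec, TrialResult
from ecgtune.search import Factor, ParameterSpace
from ecgtune.taguchi import (
    OrthogonalArray,
    TaguchiExperiment,
    catalogue,
    decode_run,
    degrees_of_freedom,
    main_effects,
    predict_best,
    run_experiments,
    select_array,
    sn_ratio,
    verify_orthogonality,
)


def _space(levels_by_factor):
    """Discrete space with the given levels for a subset of factors."""
    defaults = {
        "depth": (3,),
        "units": (8,),
        "activation": ("relu",),
        "final_activation": ("sigmoid",),
        "optimizer": ("rmsprop",),
        "loss": ("mse",),
        "epochs": (10,),
    }
    defaults.update(levels_by_factor)
    return ParameterSpace(
        tuple(
            Factor(name, "categorical", levels=tuple(levels),
                   per_layer=name == "activation")
            for name, levels in defaults.items()
        )
    )


def _result(r2):
    spec = ArchitectureSpec(n_inputs=1, units=(8, 8, 8),
                            activations=("relu", "relu", "sigmoid"), epochs=10)
    return TrialResult(
        spec=spec, metrics=MetricReport(r2=r2, mae=0.1, mse=0.01, sd=0.1),
        best_epoch=0, seed=0,
    )


class TestDegreesOfFreedom:
    def test_single_four_level_factor(self):
        assert degrees_of_freedom(_space({"depth": (3, 4, 5, 6)})) == 3

    def test_reference_factor_mix(self):
        # levels (4, 4, 3, 3) -> 3 + 3 + 2 + 2 = 10, minimum 11 runs
        space = _space(
            {
                "activation": ("relu", "elu", "selu", "sigmoid"),
                "depth": (3, 4, 5, 6),
                "loss": ("mse", "mae", "val_loss"),
                "epochs": (10, 100, 200),
            }
        )
        assert degrees_of_freedom(space) == 10

    def test_all_fixed_space_has_zero_dof(self):
        assert degrees_of_freedom(_space({})) == 0

    def test_continuous_factor_rejected_with_guidance(self):
        space = ParameterSpace(
            (
                Factor("depth", "categorical", levels=(3,)),
                Factor("units", "int", bounds=(5, 255)),
                Factor("activation", "categorical", levels=("relu",)),
            )
        )
        with pytest.raises(ValueError, match="discretize"):
            degrees_of_freedom(space)


class TestOrthogonality:
    @pytest.mark.parametrize("name", ["L4", "L8", "L9", "L16", "L18", "L25", "L27"])
    def test_every_catalogue_array_is_strength_two(self, name):
        ok, violations = verify_orthogonality(catalogue()[name])
        assert ok, violations

    def test_mutated_array_fails_naming_columns(self):
        l9 = catalogue()["L9"]
        broken = l9.matrix.copy()
        broken[0, 0] = (broken[0, 0] + 1) % 3
        ok, violations = verify_orthogonality(
            OrthogonalArray("L9broken", broken, l9.levels)
        )
        assert not ok
        assert any("column" in v for v in violations)

    def test_single_balanced_column_trivially_orthogonal(self):
        arr = OrthogonalArray("single", np.array([[0], [1], [0], [1]]), (2,))
        ok, violations = verify_orthogonality(arr)
        assert ok and not violations


class TestSelectArray:
    def test_four_three_level_factors_take_l9(self):
        space = _space(
            {
                "depth": (3, 4, 5),
                "units": (8, 16, 32),
                "activation": ("relu", "elu", "selu"),
                "epochs": (10, 100, 200),
            }
        )
        arr, assignment = select_array(space)
        assert arr.name == "L9"
        assert set(assignment.column_of) == {"depth", "units", "activation", "epochs"}

    def test_one_two_level_factor_takes_l4(self):
        arr, assignment = select_array(_space({"loss": ("mse", "mae")}))
        assert arr.name == "L4"
        assert list(assignment.column_of) == ["loss"]

    def test_reference_mix_hosts_feasibly_with_dummy_levels(self):
        space = _space(
            {
                "activation": ("relu", "elu", "selu", "sigmoid"),
                "depth": (3, 4, 5, 6),
                "loss": ("mse", "mae", "val_loss"),
                "epochs": (10, 100, 200),
            }
        )
        arr, assignment = select_array(space)
        assert arr.n_runs >= degrees_of_freedom(space) + 1
        assert verify_orthogonality(arr)[0]
        for name, col in assignment.column_of.items():
            assert arr.levels[col] >= space[name].n_levels
            # dummy map is total and surjective onto the factor's levels
            lmap = assignment.level_map[name]
            assert len(lmap) == arr.levels[col]
            assert set(lmap) == set(range(space[name].n_levels))

    def test_oversized_factor_reported(self):
        space = _space({"units": tuple(range(5, 12))})  # 7 levels: no column fits
        with pytest.raises(ValueError, match="units"):
            select_array(space)


class TestSnRatio:
    def test_unit_response_is_zero_db(self):
        assert sn_ratio([1.0, 1.0], "larger") == pytest.approx(0.0)

    def test_hand_computed_values(self):
        assert sn_ratio([0.1], "smaller") == pytest.approx(20.0)
        assert sn_ratio([10.0], "larger") == pytest.approx(20.0)

    def test_zero_under_larger_the_better_rejected(self):
        with pytest.raises(ValueError):
            sn_ratio([1.0, 0.0], "larger")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            sn_ratio([1.0], "nominal")


class TestRunExperiments:
    def test_counts_and_containment(self, small_task):
        train, test = small_task
        space = _space(
            {
                "units": (5, 6, 8),
                "activation": ("relu", "elu", "selu"),
            }
        )
        arr, assignment = select_array(space)
        results = run_experiments(arr, assignment, space, train, test, seed=0)
        assert len(results) == arr.n_runs
        for run in range(arr.n_runs):
            decoded = decode_run(arr, assignment, space, run, n_inputs=2)
            assert space.contains_spec(decoded)
            assert results[run].spec == decoded

    def test_replicates_multiply_trainings(self, small_task):
        train, test = small_task
        space = _space({"units": (5, 8)})
        arr, assignment = select_array(space)
        results = run_experiments(
            arr, assignment, space, train, test, seed=0, replicates=3
        )
        assert len(results) == arr.n_runs * 3
        # replicate r of every run uses seed + r
        assert {t.seed for t in results} == {0, 1, 2}


def _synthetic_effects(space, response_fn, response="r2"):
    """Array results whose response is a deterministic function of the spec."""
    arr, assignment = select_array(space)
    results = []
    for run in range(arr.n_runs):
        spec = decode_run(arr, assignment, space, run, n_inputs=1)
        r = response_fn(spec)
        results.append(
            TrialResult(spec=spec,
                        metrics=MetricReport(r2=r, mae=r, mse=r, sd=0.1),
                        best_epoch=0, seed=0)
        )
    table = main_effects(results, arr, assignment, space, response=response)
    return arr, assignment, results, table


class TestMainEffects:
    SPACE = {
        "depth": (3, 4, 5),
        "units": (8, 16, 32),
        "activation": ("relu", "elu", "selu"),
    }

    def test_constant_response_gives_zero_deltas(self):
        _, _, _, table = _synthetic_effects(_space(self.SPACE), lambda s: 0.5)
        assert np.allclose(table.table["delta"], 0.0)
        means = table.table["mean_response"]
        assert np.allclose(means, 0.5)

    def test_inert_factor_ranks_last(self):
        gains = {3: 0.2, 4: 0.5, 5: 0.8}

        def f(spec):
            return gains[spec.depth] + 0.1  # depth drives, the rest inert

        _, _, _, table = _synthetic_effects(_space(self.SPACE), f)
        ranking = table.delta_ranking()
        assert ranking.iloc[0]["factor"] == "depth"
        inert = table.table[table.table["factor"] != "depth"]["delta"]
        assert np.allclose(inert, 0.0, atol=1e-12)

    def test_weighted_level_means_reproduce_grand_mean(self):
        rng = np.random.default_rng(0)
        values = {}

        def f(spec):
            key = (spec.depth, spec.units[0], spec.activations[0])
            if key not in values:
                values[key] = float(rng.uniform(0.1, 1.0))
            return values[key]

        _, _, _, table = _synthetic_effects(_space(self.SPACE), f)
        for name in table.table["factor"].unique():
            sub = table.factor_levels(name)
            weighted = (sub["mean_response"] * sub["n_runs"]).sum() / sub["n_runs"].sum()
            assert weighted == pytest.approx(table.grand_mean, abs=1e-9)

    def test_missing_runs_reported(self, small_task):
        space = _space({"units": (5, 8)})
        arr, assignment = select_array(space)
        results = [_result(np.nan) for _ in range(arr.n_runs)]
        with pytest.raises(ValueError, match="runs"):
            main_effects(results, arr, assignment, space)


class TestPredictBest:
    def _toy_space(self):
        return _space(
            {
                "depth": (3, 4, 5),
                "units": (8, 16, 32),
                "activation": ("relu", "elu", "selu"),
            }
        )

    def _full_factorial_argmax(self, space, f):
        best, best_val = None, -np.inf
        for depth in space["depth"].levels:
            for units in space["units"].levels:
                for act in space["activation"].levels:
                    spec = ArchitectureSpec(
                        n_inputs=1, units=(units,) * depth,
                        activations=(act,) * (depth - 1) + ("sigmoid",),
                        epochs=10,
                    )
                    v = f(spec)
                    if v > best_val:
                        best, best_val = spec, v
        return best

    def test_additive_surfaces_match_full_factorial_argmax(self):
        rng = np.random.default_rng(17)
        space = self._toy_space()
        for _ in range(10):
            g1 = dict(zip(space["depth"].levels, rng.uniform(0, 1, 3)))
            g2 = dict(zip(space["units"].levels, rng.uniform(0, 1, 3)))
            g3 = dict(zip(space["activation"].levels, rng.uniform(0, 1, 3)))

            def f(spec):
                return 0.5 + g1[spec.depth] + g2[spec.units[0]] + g3[spec.activations[0]]

            _, assignment, _, table = _synthetic_effects(space, f)
            predicted = predict_best(table, space, n_inputs=1,
                                     fixed=assignment.fixed)
            assert predicted == self._full_factorial_argmax(space, f)

    def test_single_level_factors_pass_through(self):
        space = _space({"units": (5, 8)})
        _, assignment, _, table = _synthetic_effects(
            space, lambda s: 0.3 + 0.01 * s.units[0]
        )
        predicted = predict_best(table, space, n_inputs=1, fixed=assignment.fixed)
        assert predicted.depth == 3
        assert predicted.optimizer == "rmsprop"
        assert predicted.units == (8, 8, 8)

    def test_smaller_the_better_response_minimizes(self):
        space = _space({"units": (5, 8, 13)})
        _, assignment, _, table = _synthetic_effects(
            space, lambda s: 0.01 * s.units[0], response="mse"
        )
        predicted = predict_best(table, space, n_inputs=1, fixed=assignment.fixed)
        assert predicted.units == (5, 5, 5)


class TestExperimentFrontEnd:
    def test_fit_returns_full_results(self, small_task):
        train, test = small_task
        space = _space({"units": (5, 8), "activation": ("relu", "elu")})
        results = TaguchiExperiment(space, train, test).fit(seed=2)
        assert len(results.trials) == results.experiment.array.n_runs
        assert results.confirmation is not None
        assert results.n_trainings == len(results.trials) + 1
        assert space.contains_spec(results.best_spec)
        text = results.summary()
        assert "predicted best" in text and "confirmation run" in text

    def test_confirmation_on_additive_toy_beats_median(self):
        # additive synthetic response: the predicted best's response must
        # reach at least the median of the array runs
        space = _space(
            {
                "depth": (3, 4, 5),
                "units": (8, 16, 32),
                "activation": ("relu", "elu", "selu"),
            }
        )
        g = {3: 0.1, 4: 0.3, 5: 0.6}

        def f(spec):
            return g[spec.depth] + 0.02 * spec.units[0]

        _, assignment, results, table = _synthetic_effects(space, f)
        predicted = predict_best(table, space, n_inputs=1, fixed=assignment.fixed)
        run_responses = [t.metrics.r2 for t in results]
        assert f(predicted) >= np.median(run_responses)
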