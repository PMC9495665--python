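import numpy as np
import pytest

from ecgtune.metrics import MetricReport
from ecgtune.mlp import ArchitectureSpec, TrialResult
from ecgtune.search import (
    Factor,
    ParameterSpace,
    TrialLog,
    frequency_table,
    narrow_space,
    random_search,
    table4_space,
    wide_space,
)


def _trial(depth, acts, units, optimizer="rmsprop", loss="mse", epochs=100, r2=0.5):
    spec = ArchitectureSpec(
        n_inputs=1,
        units=(units,) * depth,
        activations=tuple(acts) if len(acts) == depth else (acts[0],) * depth,
        optimizer=optimizer,
        loss=loss,
        epochs=epochs,
    )
    return TrialResult(
        spec=spec,
        metrics=MetricReport(r2=r2, mae=0.1, mse=0.02, sd=0.1),
        best_epoch=1,
        seed=0,
    )


def _log(trials, space=None):
    return TrialLog(trials=list(trials), seed=0, budget=len(trials), space=space)


class TestParameterSpace:
    def test_sampling_stays_inside_space(self):
        space = wide_space()
        rng = np.random.default_rng(0)
        for _ in range(50):
            spec = space.sample_spec(rng, n_inputs=2)
            assert space.contains_spec(spec)

    def test_sampling_deterministic_in_seed(self):
        space = wide_space()
        specs1 = []
        specs2 = []
        rng1, rng2 = np.random.default_rng(7), np.random.default_rng(7)
        for _ in range(20):
            specs1.append(space.sample_spec(rng1, 1).as_dict())
            specs2.append(space.sample_spec(rng2, 1).as_dict())
        assert specs1 == specs2

    def test_exact_configuration_count_small_space(self):
        # 2 depths x (2 acts)^d x 3 units^d per-layer x 2 losses:
        # d=3: 8 * 27; d=4: 16 * 81 -> (216 + 1296) * 2 = 3024
        space = ParameterSpace(
            (
                Factor("depth", "categorical", levels=(3, 4)),
                Factor("units", "categorical", levels=(5, 6, 7), per_layer=True),
                Factor("activation", "categorical", levels=("relu", "elu"),
                       per_layer=True),
                Factor("loss", "categorical", levels=("mse", "mae")),
                Factor("epochs", "categorical", levels=(10,)),
            )
        )
        assert space.n_configurations() == 3024

    def test_reference_space_is_astronomical(self):
        n = table4_space().n_configurations()
        assert 200 / n < 1e-3  # 200 trials cover under 0.1 % of the space

    def test_yaml_dict_roundtrip(self):
        space = table4_space()
        again = ParameterSpace.from_dict(space.as_dict())
        assert again.as_dict() == space.as_dict()


class TestRandomSearch:
    def test_budget_and_membership(self, small_task):
        train, test = small_task
        space = _tiny_space()
        log = random_search(space, train, test, budget=3, seed=1)
        assert len(log) == 3
        assert all(space.contains_spec(t.spec) for t in log.trials)

    def test_same_seed_identical_specs(self, small_task):
        train, test = small_task
        space = _tiny_space()
        a = random_search(space, train, test, budget=3, seed=5)
        b = random_search(space, train, test, budget=3, seed=5)
        assert [t.spec for t in a.trials] == [t.spec for t in b.trials]
        assert [t.metrics.mse for t in a.trials] == [t.metrics.mse for t in b.trials]

    def test_best_of_prefix_never_beats_full_log(self):
        rng = np.random.default_rng(3)
        trials = [_trial(3, ["relu"], 10, r2=float(r)) for r in rng.uniform(0, 1, 200)]
        log = _log(trials)
        prefix = _log(trials[:20])
        assert log.best().metrics.r2 >= prefix.best().metrics.r2

    def test_invalid_budget(self, small_task):
        train, test = small_task
        with pytest.raises(ValueError):
            random_search(_tiny_space(), train, test, budget=0, seed=1)


def _tiny_space():
    return ParameterSpace(
        (
            Factor("depth", "categorical", levels=(3,)),
            Factor("units", "categorical", levels=(5, 8)),
            Factor("activation", "categorical", levels=("relu", "elu"),
                   per_layer=True),
            Factor("optimizer", "categorical", levels=("rmsprop",)),
            Factor("loss", "categorical", levels=("mse",)),
            Factor("epochs", "categorical", levels=(10,)),
        )
    )


class TestFrequencyTable:
    def test_scalar_counts_sum_to_top_k(self):
        trials = [
            _trial(3, ["relu"], 10, r2=0.9),
            _trial(3, ["relu"], 10, r2=0.8),
            _trial(4, ["elu"], 64, r2=0.7),
            _trial(5, ["selu"], 100, r2=0.1),
        ]
        table = frequency_table(_log(trials), top_k=3)
        assert table["depth"] == {3: 2, 4: 1}
        assert sum(table["optimizer"].values()) == 3
        assert sum(table["epochs"].values()) == 3

    def test_activation_counts_sum_to_total_depth(self):
        trials = [
            _trial(3, ["relu", "elu", "sigmoid"], 10, r2=0.9),
            _trial(4, ["selu", "selu", "selu", "sigmoid"], 10, r2=0.8),
        ]
        table = frequency_table(_log(trials), top_k=2)
        body = sum(table["activation"].values())
        final = sum(table["final_activation"].values())
        assert body + final == 3 + 4
        assert table["final_activation"] == {"sigmoid": 2}

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(11)
        acts = ("relu", "elu", "selu", "sigmoid", "tanh", "linear")
        trials = []
        for _ in range(30):
            d = int(rng.integers(3, 9))
            layer_acts = [acts[rng.integers(6)] for _ in range(d)]
            trials.append(
                _trial(d, layer_acts, int(rng.integers(5, 256)),
                       epochs=int(rng.choice([10, 100, 200])),
                       r2=float(rng.uniform())),
            )
        log = _log(trials)
        top_k = 10
        table = frequency_table(log, top_k=top_k)
        top = log.top(top_k)
        brute = {}
        for t in top:
            for a in t.spec.activations[:-1]:
                brute[a] = brute.get(a, 0) + 1
        assert table["activation"] == brute

    def test_top_k_exceeding_log_rejected(self):
        with pytest.raises(ValueError):
            frequency_table(_log([_trial(3, ["relu"], 10)]), top_k=2)


class TestNarrowSpace:
    def test_absent_activations_excluded(self):
        # tanh and linear never appear among the winners -> dropped
        winners = [
            _trial(3, ["relu", "elu", "sigmoid"], 10, r2=0.9 - 0.01 * i)
            for i in range(8)
        ]
        losers = [_trial(3, ["tanh", "linear", "tanh"], 10, r2=0.05) for _ in range(4)]
        log = _log(winners + losers, space=wide_space())
        narrowed = narrow_space(log, top_k=8)
        assert "tanh" not in narrowed["activation"].levels
        assert "linear" not in narrowed["activation"].levels
        assert narrowed.is_subspace_of(wide_space())

    def test_single_optimizer_collapses(self):
        trials = [_trial(3, ["relu"], 10, optimizer="rmsprop", r2=0.9)
                  for _ in range(6)]
        trials += [_trial(3, ["relu"], 10, optimizer="sgd", r2=0.01)
                   for _ in range(6)]
        log = _log(trials, space=wide_space())
        narrowed = narrow_space(log, top_k=6)
        assert narrowed["optimizer"].levels == ("rmsprop",)

    def test_uniform_log_keeps_space_unchanged(self):
        space = ParameterSpace(
            (
                Factor("depth", "categorical", levels=(3, 4)),
                Factor("units", "categorical", levels=(10, 64)),
                Factor("activation", "categorical", levels=("relu", "elu"),
                       per_layer=True),
                Factor("final_activation", "categorical", levels=("sigmoid",)),
                Factor("optimizer", "categorical", levels=("rmsprop",)),
                Factor("loss", "categorical", levels=("mse", "mae")),
                Factor("epochs", "categorical", levels=(10, 100)),
            )
        )
        trials = []
        for depth in (3, 4):
            for units in (10, 64):
                for act in ("relu", "elu"):
                    for loss in ("mse", "mae"):
                        for epochs in (10, 100):
                            trials.append(
                                _trial(depth, [act] * (depth - 1) + ["sigmoid"],
                                       units, loss=loss, epochs=epochs, r2=0.5)
                            )
        log = _log(trials, space=space)
        narrowed = narrow_space(log, top_k=len(trials))
        assert narrowed.as_dict() == space.as_dict()

    def test_idempotent_for_fixed_log(self):
        rng = np.random.default_rng(2)
        trials = [
            _trial(int(rng.integers(3, 7)), ["relu"], int(rng.integers(5, 200)),
                   r2=float(rng.uniform()))
            for _ in range(30)
        ]
        log = _log(trials, space=wide_space())
        a = narrow_space(log, top_k=10)
        b = narrow_space(log, top_k=10)
        assert a.as_dict() == b.as_dict()

    def test_units_snap_to_level_grid(self):
        trials = [_trial(3, ["relu"], u, r2=0.9) for u in (12, 60, 95, 210)]
        log = _log(trials, space=wide_space())
        narrowed = narrow_space(log, top_k=4)
        assert narrowed["units"].kind == "categorical"
        assert set(narrowed["units"].levels) <= {10, 64, 100, 200}

    def test_level_cap_keeps_most_frequent(self):
        trials = []
        depths = [3] * 10 + [4] * 8 + [5] * 6 + [6] * 4 + [7] * 2 + [8] * 1
        for i, d in enumerate(depths):
            trials.append(_trial(d, ["relu"], 10, r2=1.0 - 0.001 * i))
        log = _log(trials, space=wide_space())
        narrowed = narrow_space(log, top_k=len(trials), max_levels=4, min_freq=0.01)
        assert narrowed["depth"].levels == (3, 4, 5, 6)
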