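"""Orthogonal-array (Taguchi) optimization of network hyperparameters.

Instead of training every combination of the narrowed factor levels, the
method runs a small orthogonal array: a run matrix in which every level
of every column appears equally often, and every ordered level pair of
every column pair appears equally often (strength-2 balance).  Main
effects — the mean response and mean signal-to-noise ratio per factor
level — can then be estimated from a handful of runs, ranked by their
delta (max minus min level mean), and combined into a predicted best
configuration that a confirmation run validates.

Arrays come from the standard catalogue (L4, L8, L9, L16, L18, L25,
L27), constructed from finite-field recipes and checked exactly by
:func:`verify_orthogonality`.  Factors with fewer levels than their host
column use the dummy-level technique (one designated level repeated).

The user-facing surface follows the model/results convention:
``TaguchiExperiment(space, train, test).fit(seed)`` returns a
:class:`TaguchiResults` carrying the trials, the main-effects table, the
predicted best architecture and its confirmation run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mlp import ArchitectureSpec, TrialResult, build_and_train
from .search import Factor, ParameterSpace

__all__ = [
    "OrthogonalArray",
    "FactorAssignment",
    "MainEffectsTable",
    "catalogue",
    "verify_orthogonality",
    "degrees_of_freedom",
    "select_array",
    "decode_run",
    "run_experiments",
    "sn_ratio",
    "main_effects",
    "predict_best",
    "TaguchiExperiment",
    "TaguchiResults",
]


@dataclass(frozen=True)
class OrthogonalArray:
    """A run-by-column matrix of level indices with known column levels."""

    name: str
    matrix: np.ndarray  # (runs, columns) of int level indices
    levels: tuple  # levels per column

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=int)
        if m.ndim != 2:
            raise ValueError("array matrix must be 2-D")
        if len(self.levels) != m.shape[1]:
            raise ValueError("one level count per column required")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "levels", tuple(int(v) for v in self.levels))

    @property
    def n_runs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def _l8() -> np.ndarray:
    rows = []
    for i in range(8):
        rows.append([bin(i & j).count("1") % 2 for j in range(1, 8)])
    return np.array(rows)


def _l9() -> np.ndarray:
    return np.array(
        [[a, b, (a + b) % 3, (a + 2 * b) % 3] for a in range(3) for b in range(3)]
    )


_GF4_MUL = np.array(
    [[0, 0, 0, 0], [0, 1, 2, 3], [0, 2, 3, 1], [0, 3, 1, 2]]
)  # GF(4) product, elements {0, 1, w, w^2}


def _l16() -> np.ndarray:
    xor = np.bitwise_xor
    rows = []
    for a in range(4):
        for b in range(4):
            rows.append(
                [a, b, xor(a, b), xor(a, _GF4_MUL[2][b]), xor(a, _GF4_MUL[3][b])]
            )
    return np.array(rows)


# the standard L18(2^1 x 3^7) table (0-indexed levels)
_L18 = np.array(
    [
        [0, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 1, 1, 1, 1, 1, 1],
        [0, 0, 2, 2, 2, 2, 2, 2],
        [0, 1, 0, 0, 1, 1, 2, 2],
        [0, 1, 1, 1, 2, 2, 0, 0],
        [0, 1, 2, 2, 0, 0, 1, 1],
        [0, 2, 0, 1, 0, 2, 1, 2],
        [0, 2, 1, 2, 1, 0, 2, 0],
        [0, 2, 2, 0, 2, 1, 0, 1],
        [1, 0, 0, 2, 2, 1, 1, 0],
        [1, 0, 1, 0, 0, 2, 2, 1],
        [1, 0, 2, 1, 1, 0, 0, 2],
        [1, 1, 0, 1, 2, 0, 2, 1],
        [1, 1, 1, 2, 0, 1, 0, 2],
        [1, 1, 2, 0, 1, 2, 1, 0],
        [1, 2, 0, 2, 1, 2, 0, 1],
        [1, 2, 1, 0, 2, 0, 1, 2],
        [1, 2, 2, 1, 0, 1, 2, 0],
    ]
)


def _l25() -> np.ndarray:
    rows = []
    for a in range(5):
        for b in range(5):
            rows.append([a, b] + [(a + k * b) % 5 for k in range(1, 5)])
    return np.array(rows)


def _l27() -> np.ndarray:
    # columns = the 13 lines of PG(2, 3): nonzero GF(3)^3 vectors with
    # leading coefficient 1
    cols = [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, 2, 0), (1, 0, 1), (1, 0, 2),
        (0, 1, 1), (0, 1, 2),
        (1, 1, 1), (1, 1, 2), (1, 2, 1), (1, 2, 2),
    ]
    rows = []
    for x in range(3):
        for y in range(3):
            for z in range(3):
                rows.append([(a * x + b * y + c * z) % 3 for a, b, c in cols])
    return np.array(rows)


def catalogue() -> dict:
    """The standard orthogonal arrays this package selects from."""
    return {
        "L4": OrthogonalArray("L4", np.array([[0, 0, 0], [0, 1, 1], [1, 0, 1], [1, 1, 0]]), (2, 2, 2)),
        "L8": OrthogonalArray("L8", _l8(), (2,) * 7),
        "L9": OrthogonalArray("L9", _l9(), (3,) * 4),
        "L16": OrthogonalArray("L16", _l16(), (4,) * 5),
        "L18": OrthogonalArray("L18", _L18, (2,) + (3,) * 7),
        "L25": OrthogonalArray("L25", _l25(), (5,) * 6),
        "L27": OrthogonalArray("L27", _l27(), (3,) * 13),
    }


def verify_orthogonality(array: OrthogonalArray) -> tuple:
    """Exhaustive integer check of strength-2 balance.

    Returns ``(ok, violations)`` where violations name the offending
    column (unbalanced level counts) or column pair (unbalanced ordered
    level pairs).
    """
    m, levels = array.matrix, array.levels
    R = m.shape[0]
    violations = []
    for j in range(m.shape[1]):
        counts = np.bincount(m[:, j], minlength=levels[j])
        if counts.size > levels[j] or len(set(counts.tolist())) != 1:
            violations.append(f"column {j}: unbalanced level counts {counts.tolist()}")
    for j in range(m.shape[1]):
        for k in range(j + 1, m.shape[1]):
            expected = R / (levels[j] * levels[k])
            pair_counts: dict = {}
            for a, b in zip(m[:, j], m[:, k]):
                pair_counts[(int(a), int(b))] = pair_counts.get((int(a), int(b)), 0) + 1
            counts = [
                pair_counts.get((a, b), 0)
                for a in range(levels[j])
                for b in range(levels[k])
            ]
            if any(c != expected for c in counts):
                violations.append(
                    f"columns ({j}, {k}): ordered pair counts {counts} != {expected}"
                )
    return (not violations, violations)


def _tunable(space: ParameterSpace) -> list:
    """Factors with >= 2 levels, i.e. those that consume array columns."""
    out = []
    for f in space.factors:
        if f.kind != "categorical":
            raise ValueError(
                f"factor {f.name!r} is a continuous range; discretize it "
                "(e.g. via narrow_space) before the orthogonal-array stage"
            )
        if f.n_levels >= 2:
            out.append(f)
    return out


def degrees_of_freedom(space: ParameterSpace) -> int:
    """Sum over factors of (levels - 1); +1 gives the minimum run count."""
    return sum(f.n_levels - 1 for f in _tunable(space))


@dataclass(frozen=True)
class FactorAssignment:
    """Factor-to-column mapping with per-factor dummy-level maps.

    ``column_of[name]`` is the array column hosting the factor and
    ``level_map[name]`` maps each column level index to a factor level
    index (extra column levels repeat level 0 — the dummy-level
    technique).  Factors with a single level are fixed, listed in
    ``fixed`` with their value.
    """

    column_of: dict
    level_map: dict
    fixed: dict


def select_array(space: ParameterSpace) -> tuple:
    """Pick the smallest catalogue array that can host the space.

    Feasibility: one column per multi-level factor, column levels >= the
    factor's levels (dummy-leveling fills the gap), and at least
    dof + 1 runs.  Factors are placed greedily, largest level count
    first, each into the smallest sufficient unused column.
    """
    tunable = _tunable(space)
    dof = degrees_of_freedom(space)
    fixed = {
        f.name: f.levels[0]
        for f in space.factors
        if f.kind == "categorical" and f.n_levels == 1
    }
    arrays = sorted(catalogue().values(), key=lambda a: (a.n_runs, a.n_columns))
    for arr in arrays:
        if arr.n_runs < dof + 1 or arr.n_columns < len(tunable):
            continue
        cols = sorted(range(arr.n_columns), key=lambda j: arr.levels[j])
        used: set = set()
        column_of: dict = {}
        ok = True
        for f in sorted(tunable, key=lambda f: -f.n_levels):
            pick = next(
                (j for j in cols if j not in used and arr.levels[j] >= f.n_levels),
                None,
            )
            if pick is None:
                ok = False
                break
            used.add(pick)
            column_of[f.name] = pick
        if ok:
            level_map = {
                f.name: tuple(
                    k if k < f.n_levels else 0  # dummy: repeat the first level
                    for k in range(arr.levels[column_of[f.name]])
                )
                for f in tunable
            }
            return arr, FactorAssignment(column_of, level_map, fixed)
    biggest = max(tunable, key=lambda f: f.n_levels, default=None)
    raise ValueError(
        f"no catalogue array can host this space (dof={dof}, "
        f"largest factor: {biggest.name if biggest else 'none'} with "
        f"{biggest.n_levels if biggest else 0} levels)"
    )


def _spec_from_levels(space: ParameterSpace, values: dict, n_inputs: int) -> ArchitectureSpec:
    """Assemble a concrete architecture from one value per factor."""
    depth = int(values["depth"])
    units = int(values["units"])
    body = values["activation"]
    final = values.get("final_activation", body)
    kw = {}
    for name in ("optimizer", "loss"):
        if name in values:
            kw[name] = values[name]
    return ArchitectureSpec(
        n_inputs=n_inputs,
        units=(units,) * depth,
        activations=(body,) * (depth - 1) + (final,),
        epochs=int(values.get("epochs", 100)),
        **kw,
    )


def decode_run(
    array: OrthogonalArray,
    assignment: FactorAssignment,
    space: ParameterSpace,
    run: int,
    n_inputs: int,
) -> ArchitectureSpec:
    """Translate one array row into a concrete architecture."""
    values = dict(assignment.fixed)
    for name, col in assignment.column_of.items():
        idx = assignment.level_map[name][int(array.matrix[run, col])]
        values[name] = space[name].levels[idx]
    try:
        return _spec_from_levels(space, values, n_inputs)
    except (KeyError, ValueError) as exc:
        raise ValueError(f"cannot decode run {run}: {exc}") from exc


def run_experiments(
    array: OrthogonalArray,
    assignment: FactorAssignment,
    space: ParameterSpace,
    train: tuple,
    test: tuple,
    seed: int = 0,
    replicates: int = 1,
) -> list:
    """Train every array run (times ``replicates``) and collect results.

    Returns a flat list ordered run-major: entry ``i * replicates + r``
    is replicate r of run i.  Replicate r trains with seed ``seed + r``
    (common random numbers across runs within a replicate).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    Xtr = np.asarray(train[0])
    n_inputs = 1 if Xtr.ndim == 1 else Xtr.shape[1]
    results = []
    for run in range(array.n_runs):
        spec = decode_run(array, assignment, space, run, n_inputs)
        for r in range(replicates):
            results.append(build_and_train(spec, train, test, seed=seed + r))
    return results


def sn_ratio(values, kind: str) -> float:
    """Taguchi signal-to-noise ratio in dB.

    larger-the-better: -10 log10(mean(1 / y^2)); requires y > 0.
    smaller-the-better: -10 log10(mean(y^2)).
    """
    y = np.asarray(values, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("sn_ratio needs at least one value")
    if kind in ("larger", "larger-the-better"):
        if np.any(y <= 0):
            raise ValueError("larger-the-better S/N requires positive responses")
        return float(-10.0 * np.log10(np.mean(1.0 / y**2)))
    if kind in ("smaller", "smaller-the-better"):
        return float(-10.0 * np.log10(np.mean(y**2)))
    raise ValueError(f"unknown S/N kind {kind!r}")


def _sn_kind(response: str) -> str:
    return "larger" if response == "r2" else "smaller"


@dataclass(frozen=True)
class MainEffectsTable:
    """Per-factor, per-level mean response and mean S/N ratio.

    ``table`` is a tidy DataFrame with columns factor, level,
    mean_response, mean_sn_db, n_runs, delta, rank.  Delta is the spread
    (max - min) of a factor's level means of the response; rank 1 is the
    most influential factor.
    """

    table: pd.DataFrame
    response: str
    grand_mean: float

    def factor_levels(self, name: str) -> pd.DataFrame:
        return self.table[self.table["factor"] == name]

    def delta_ranking(self) -> pd.DataFrame:
        return (
            self.table[["factor", "delta", "rank"]]
            .drop_duplicates()
            .sort_values("rank")
            .reset_index(drop=True)
        )


def main_effects(
    results: list,
    array: OrthogonalArray,
    assignment: FactorAssignment,
    space: ParameterSpace,
    response: str = "r2",
    replicates: int = 1,
) -> MainEffectsTable:
    """Level means and S/N ratios for every assigned factor.

    ``results`` is the run-major flat list from :func:`run_experiments`.
    Replicates are averaged per run before level means are taken; the
    S/N ratio is computed per run across replicates, then averaged per
    level.  Occurrence-weighted level means reproduce the grand mean.
    """
    R = array.n_runs
    if len(results) != R * replicates:
        raise ValueError(
            f"expected {R}x{replicates} results, got {len(results)}"
        )
    per_run = [results[i * replicates : (i + 1) * replicates] for i in range(R)]
    missing = [
        i for i, grp in enumerate(per_run)
        if any(t.failed or not np.isfinite(getattr(t.metrics, response)) for t in grp)
    ]
    if missing:
        raise ValueError(f"runs without a finite {response} response: {missing}")

    values = np.array(
        [[getattr(t.metrics, response) for t in grp] for grp in per_run]
    )  # (R, replicates)
    run_mean = values.mean(axis=1)
    kind = _sn_kind(response)
    if kind == "larger" and np.any(values <= 0):
        warnings.warn(
            "non-positive responses clipped to 1e-6 for the larger-the-better "
            "S/N ratio",
            RuntimeWarning,
        )
        values = np.maximum(values, 1e-6)
    run_sn = np.array([sn_ratio(v, kind) for v in values])
    grand_mean = float(run_mean.mean())

    columns = [
        "factor", "level", "mean_response", "mean_sn_db", "n_runs", "delta", "rank",
    ]
    if not assignment.column_of:  # every factor fixed: nothing to analyze
        return MainEffectsTable(
            table=pd.DataFrame(columns=columns),
            response=response,
            grand_mean=grand_mean,
        )

    rows = []
    deltas = {}
    for name, col in assignment.column_of.items():
        factor = space[name]
        lmap = assignment.level_map[name]
        level_idx = np.array([lmap[v] for v in array.matrix[:, col]])
        means = {}
        for li in range(factor.n_levels):
            mask = level_idx == li
            means[li] = (
                float(run_mean[mask].mean()),
                float(run_sn[mask].mean()),
                int(mask.sum()),
            )
        delta = max(m[0] for m in means.values()) - min(m[0] for m in means.values())
        deltas[name] = delta
        for li, (m_resp, m_sn, n) in means.items():
            rows.append(
                {
                    "factor": name,
                    "level": factor.levels[li],
                    "mean_response": m_resp,
                    "mean_sn_db": m_sn,
                    "n_runs": n,
                    "delta": delta,
                }
            )
    ranking = {
        name: rank + 1
        for rank, name in enumerate(
            sorted(deltas, key=lambda n: (-deltas[n], n))
        )
    }
    table = pd.DataFrame(rows)
    table["rank"] = table["factor"].map(ranking)
    return MainEffectsTable(table=table, response=response, grand_mean=grand_mean)


def predict_best(
    table: MainEffectsTable,
    space: ParameterSpace,
    n_inputs: int,
    fixed: dict | None = None,
) -> ArchitectureSpec:
    """Assemble the level-by-level best configuration.

    Per factor, the level with the best mean response wins; ties go to
    the better mean S/N ratio, then to the lower level index.  Level
    means of the response are exact main-effect estimates for additive
    response surfaces under the array's balance, so on such surfaces the
    prediction coincides with the full-factorial argmax; the S/N column
    (a log-domain robustness measure) is reported for every level and
    breaks ties.  Single-level factors pass through unchanged.
    """
    higher_response_better = table.response == "r2"
    values = dict(fixed or {})
    for f in space.factors:
        if f.n_levels == 1:
            values.setdefault(f.name, f.levels[0])
    for name in table.table["factor"].unique():
        sub = table.factor_levels(name).reset_index(drop=True)
        sign = 1.0 if higher_response_better else -1.0
        best_idx = sorted(
            range(len(sub)),
            key=lambda i: (-sign * sub["mean_response"][i],
                           -sub["mean_sn_db"][i], i),
        )[0]
        values[name] = sub["level"][best_idx]
    return _spec_from_levels(space, values, n_inputs)


# ---------------------------------------------------------------------------
# model/results front end


class TaguchiExperiment:
    """Orthogonal-array tuning experiment over a discrete space.

    Parameters
    ----------
    space : ParameterSpace
        Discrete (already narrowed) factor space.
    train, test : (X, y) pairs
        Preprocessed splits the candidate networks train and score on.
    response : str
        Metric driving the analysis: ``r2`` (larger-the-better S/N,
        default), ``mse`` or ``mae`` (smaller-the-better).
    replicates : int
        Trainings per array run (default 1).
    """

    def __init__(self, space, train, test, response="r2", replicates=1):
        if response not in ("r2", "mse", "mae"):
            raise ValueError(f"unsupported response {response!r}")
        self.space = space
        self.train = train
        self.test = test
        self.response = response
        self.replicates = int(replicates)
        self.array, self.assignment = select_array(space)

    def fit(self, seed: int = 0, confirm: bool = True) -> "TaguchiResults":
        """Run the array, analyze main effects, train the predicted best."""
        trials = run_experiments(
            self.array, self.assignment, self.space, self.train, self.test,
            seed=seed, replicates=self.replicates,
        )
        effects = main_effects(
            trials, self.array, self.assignment, self.space,
            response=self.response, replicates=self.replicates,
        )
        Xtr = np.asarray(self.train[0])
        n_inputs = 1 if Xtr.ndim == 1 else Xtr.shape[1]
        best_spec = predict_best(
            effects, self.space, n_inputs, fixed=self.assignment.fixed
        )
        confirmation = (
            build_and_train(best_spec, self.train, self.test, seed=seed)
            if confirm
            else None
        )
        return TaguchiResults(
            experiment=self,
            trials=trials,
            effects=effects,
            best_spec=best_spec,
            confirmation=confirmation,
            seed=seed,
        )


@dataclass
class TaguchiResults:
    """Fitted Taguchi experiment: trials, main effects, predicted best."""

    experiment: TaguchiExperiment
    trials: list
    effects: MainEffectsTable
    best_spec: ArchitectureSpec
    confirmation: TrialResult | None
    seed: int

    @property
    def n_trainings(self) -> int:
        return len(self.trials) + (1 if self.confirmation is not None else 0)

    def best_metric(self) -> float:
        """Best achieved response among array runs and confirmation."""
        pool = list(self.trials) + ([self.confirmation] if self.confirmation else [])
        metric = self.experiment.response
        return max(t.sort_key(metric) for t in pool) * (1 if metric == "r2" else -1)

    def summary(self) -> str:
        exp = self.experiment
        lines = [
            "Taguchi orthogonal-array experiment",
            f"  array: {exp.array.name} ({exp.array.n_runs} runs x "
            f"{exp.array.n_columns} columns), replicates={exp.replicates}",
            f"  response: {exp.response} "
            f"({_sn_kind(exp.response)}-the-better S/N)",
            f"  grand mean response: {self.effects.grand_mean:.4f}",
            "",
            self.effects.table.to_string(index=False, float_format="%.4f"),
            "",
            f"predicted best: depth={self.best_spec.depth}, "
            f"units={self.best_spec.units[0]}, "
            f"activations={'-'.join(self.best_spec.activations)}, "
            f"optimizer={self.best_spec.optimizer}, loss={self.best_spec.loss}, "
            f"epochs={self.best_spec.epochs}",
        ]
        if self.confirmation is not None:
            m = self.confirmation.metrics
            lines.append(
                f"confirmation run: R2={m.r2:.4f}, MAE={m.mae:.4f}, "
                f"MSE={m.mse:.4f}, SD={m.sd:.4f} "
                f"(best epoch {self.confirmation.best_epoch})"
            )
        return "\n".join(lines)
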