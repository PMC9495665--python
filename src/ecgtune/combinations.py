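"""Enumeration and ranking of input -> output channel combinations.

Each recording session captures exactly three synchronized channels:
Lead I, the aortic-site trace (ECGA), and one of the pulmonary,
tricuspid or mitral traces (ECGP/ECGT/ECGM).  Within one session, any
channel can serve as the regression target with any non-empty subset of
the remaining channels as inputs: 3 outputs x 3 input subsets = 9 tasks
per session, 27 across the three sessions.  Sessions are never mixed —
their channels were not recorded simultaneously.

``compare_methods`` runs both tuning pipelines (random-only, and
narrowed random search followed by the orthogonal-array stage) on each
task at an equal training budget and reports their best metrics side by
side, together with distribution summaries (median, quartiles, extremes)
of the predicted versus actual test traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations as _subsets

import numpy as np
import pandas as pd

from .metrics import MetricReport
from .mlp import ArchitectureSpec, build_train_predict
from .preprocess import SplitConfig, minmax_normalize, train_test_split
from .search import ParameterSpace, narrow_space, random_search, wide_space
from .synth_ecg import RecordingSet
from .taguchi import TaguchiExperiment

__all__ = [
    "CombinationSpec",
    "CombinationResult",
    "enumerate_combinations",
    "rank_combinations",
    "prepare_task",
    "compare_methods",
    "distribution_summary",
]

#: Trainings reserved for the final (orthogonal-array + confirmation)
#: stage when a total budget is split across the two tuning stages.
ARRAY_STAGE_RESERVE = 10


@dataclass(frozen=True)
class CombinationSpec:
    """One reconstruction task: output channel and input channels of a set."""

    set_id: str
    output: str
    inputs: tuple

    def __post_init__(self) -> None:
        inputs = tuple(self.inputs)
        if not inputs:
            raise ValueError("at least one input channel required")
        if self.output in inputs:
            raise ValueError(f"output {self.output!r} cannot also be an input")
        if len(set(inputs)) != len(inputs):
            raise ValueError("duplicate input channels")
        object.__setattr__(self, "inputs", inputs)

    def __str__(self) -> str:
        return f"[{self.set_id}] {'+'.join(self.inputs)} -> {self.output}"


@dataclass(frozen=True)
class CombinationResult:
    """Best tuned model for one task under one tuning method."""

    spec: CombinationSpec
    method: str  # "random" | "taguchi"
    metrics: MetricReport
    architecture: ArchitectureSpec

    def sort_key(self, metric: str = "r2") -> float:
        value = getattr(self.metrics, metric)
        if not np.isfinite(value):
            return -np.inf
        return value if metric == "r2" else -value


def enumerate_combinations(sets: dict) -> list:
    """All admissible tasks across recording sets, in lexicographic order.

    ``sets`` maps a set id (e.g. "P", "T", "M") to its three distinct
    channel labels.  Per set: every channel as output, paired with every
    non-empty subset of the remaining channels — 9 tasks for a 3-channel
    set, 2^(k-1) - 1 subsets per output in general.
    """
    out = []
    for set_id in sorted(sets):
        labels = list(sets[set_id])
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate labels in set {set_id!r}: {labels}")
        for output in sorted(labels):
            rest = sorted(lab for lab in labels if lab != output)
            for size in range(1, len(rest) + 1):
                for inputs in _subsets(rest, size):
                    out.append(CombinationSpec(set_id, output, inputs))
    return out


def rank_combinations(results: list, metric: str = "r2") -> list:
    """Order results best-first by the given metric (stable on ties)."""
    if metric not in {"r2", "mae", "mse", "sd"}:
        raise ValueError(f"unknown metric {metric!r}")
    return sorted(results, key=lambda r: (-r.sort_key(metric), str(r.spec)))


def prepare_task(
    rec: RecordingSet,
    spec: CombinationSpec,
    split: SplitConfig = SplitConfig(),
):
    """Slice a recording into normalized train/test splits for one task.

    Channels are min-max normalized with statistics from the training
    block only (the test block reuses them, so no leakage), then split
    chronologically 80-20 by default.
    """
    n_train = int(np.floor(split.train_fraction * rec.n_samples))

    def norm(label: str) -> np.ndarray:
        x = rec.channel(label)
        stats = (float(x[:n_train].min()), float(x[:n_train].max()))
        return minmax_normalize(x, stats=stats)

    X = np.column_stack([norm(lab) for lab in spec.inputs])
    y = norm(spec.output)
    return train_test_split(X, y, split)


def distribution_summary(values: np.ndarray) -> dict:
    """Five-number summary (min, quartiles, median, max) of a trace."""
    v = np.asarray(values, dtype=float).ravel()
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "min": float(v.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(v.max()),
    }


def run_taguchi_pipeline(
    train: tuple,
    test: tuple,
    budget: int,
    seed: int,
    space: ParameterSpace | None = None,
    narrowed: ParameterSpace | None = None,
    top_k: int = 10,
    array_reserve: int = ARRAY_STAGE_RESERVE,
    max_levels: int = 4,
):
    """Two-stage pipeline inside a total training budget.

    Stage 1 spends ``budget - array_reserve`` trainings on random search
    over ``space`` and narrows the factor levels from its top trials
    (each capped at ``max_levels``); the remaining budget funds the
    orthogonal-array stage plus one confirmation run.  A pre-narrowed
    space skips stage 1.

    Returns ``(best_trial, taguchi_results, stage1_log_or_None)``.
    """
    stage1_log = None
    if narrowed is None:
        space = space or wide_space()
        stage1_budget = max(1, budget - array_reserve)
        stage1_log = random_search(space, train, test, budget=stage1_budget, seed=seed)
        narrowed = narrow_space(
            stage1_log, top_k=min(top_k, len(stage1_log)), max_levels=max_levels
        )
    results = TaguchiExperiment(narrowed, train, test).fit(seed=seed)
    pool = list(results.trials) + [results.confirmation]
    if stage1_log is not None:
        pool.extend(stage1_log.trials)
    best = max(pool, key=lambda t: t.sort_key("r2"))
    return best, results, stage1_log


def compare_methods(
    specs: list,
    recordings: dict,
    budget: int = 20,
    seed: int = 0,
    space: ParameterSpace | None = None,
    split: SplitConfig = SplitConfig(),
) -> pd.DataFrame:
    """Run both tuning methods on every task at equal training budget.

    Parameters
    ----------
    specs : list of CombinationSpec
        Tasks to evaluate (e.g. from :func:`enumerate_combinations`).
    recordings : dict
        Maps set id to its :class:`RecordingSet`.
    budget : int
        Total trainings per method per task.
    seed : int
        Master seed; each task derives its own stream.
    space : ParameterSpace, optional
        Stage-1 space (defaults to the wide space).

    Returns
    -------
    pandas.DataFrame
        One row per (task, method) with best R2/MSE/MAE/SD, the chosen
        architecture, the final-stage training count, and five-number
        summaries of the actual and predicted test traces.

    Notes
    -----
    One narrowing pass is run per recording set and reused across its
    nine tasks, mirroring a single narrowing step per session and
    halving stage-1 compute.
    """
    space = space or wide_space()
    rows = []
    narrowed_cache: dict = {}
    for i, spec in enumerate(specs):
        rec = recordings[spec.set_id]
        train, test = prepare_task(rec, spec, split)
        task_seed = int(np.random.default_rng([seed, i]).integers(2**31))

        random_log = random_search(space, train, test, budget=budget, seed=task_seed)
        best_random = random_log.best()

        if spec.set_id not in narrowed_cache:
            stage1_budget = max(1, budget - ARRAY_STAGE_RESERVE)
            s1 = random_search(space, train, test, budget=stage1_budget, seed=task_seed)
            narrowed_cache[spec.set_id] = narrow_space(s1, top_k=min(10, len(s1)))
        narrowed = narrowed_cache[spec.set_id]
        tag = TaguchiExperiment(narrowed, train, test).fit(seed=task_seed)
        pool = list(tag.trials) + [tag.confirmation]
        best_taguchi = max(pool, key=lambda t: t.sort_key("r2"))

        actual = distribution_summary(np.asarray(test[1], dtype=float))
        for method, best, n_final in (
            ("random", best_random, budget),
            ("taguchi", best_taguchi, len(tag.trials) + 1),
        ):
            # deterministic retraining recovers the winner's test trace
            _, pred = build_train_predict(best.spec, train, test, seed=best.seed)
            rows.append(
                {
                    "set": spec.set_id,
                    "inputs": "+".join(spec.inputs),
                    "output": spec.output,
                    "method": method,
                    "r2": best.metrics.r2,
                    "mse": best.metrics.mse,
                    "mae": best.metrics.mae,
                    "sd": best.metrics.sd,
                    "depth": best.spec.depth,
                    "units": max(best.spec.units),
                    "activations": "-".join(best.spec.activations),
                    "epochs": best.spec.epochs,
                    "n_final_stage": n_final,
                    **{f"actual_{k}": v for k, v in actual.items()},
                    **{f"pred_{k}": v for k, v in distribution_summary(pred).items()},
                }
            )
    return pd.DataFrame(rows)
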