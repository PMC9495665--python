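"""Stage-1 budgeted random search and frequency-based space narrowing.

Hyperparameter tuning runs in two stages.  Stage 1 draws a fixed budget
of uniform random configurations (200 in the reference protocol) from a
wide space — depth 3-8, units 5-255 per layer, six activations, three
optimizers, three losses, three epoch settings — and trains each one.
The best trials are then tallied factor by factor: levels that barely
appear among the top performers are dropped, integer ranges shrink to
the observed span snapped onto a small level grid, and factors whose
top-trial distribution stays near-uniform are kept fully spread.  The
narrowed space is what the orthogonal-array stage operates on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .mlp import (
    ACTIVATIONS,
    EPOCH_LEVELS,
    LOSSES,
    OPTIMIZERS,
    ArchitectureSpec,
    TrialResult,
    build_and_train,
)

__all__ = [
    "Factor",
    "ParameterSpace",
    "TrialLog",
    "wide_space",
    "table4_space",
    "random_search",
    "frequency_table",
    "narrow_space",
    "UNITS_LEVEL_GRID",
]

#: Snap grid for hidden-layer widths after narrowing; orthogonal arrays
#: need few discrete levels and these cover the widths that recur in
#: well-performing dense ECG regressors.
UNITS_LEVEL_GRID = (10, 64, 100, 200)


@dataclass(frozen=True)
class Factor:
    """One tunable factor: a named categorical level set or integer range."""

    name: str
    kind: str  # "categorical" | "int"
    levels: tuple = ()
    bounds: tuple = ()
    per_layer: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "int"):
            raise ValueError(f"unknown factor kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.levels:
                raise ValueError(f"factor {self.name!r} has no levels")
            object.__setattr__(self, "levels", tuple(self.levels))
        else:
            lo, hi = self.bounds
            if hi < lo:
                raise ValueError(f"factor {self.name!r} has empty range {self.bounds}")
            object.__setattr__(self, "bounds", (int(lo), int(hi)))

    @property
    def n_levels(self) -> int:
        if self.kind == "categorical":
            return len(self.levels)
        return self.bounds[1] - self.bounds[0] + 1

    def sample(self, rng: np.random.Generator):
        if self.kind == "categorical":
            return self.levels[rng.integers(len(self.levels))]
        return int(rng.integers(self.bounds[0], self.bounds[1] + 1))

    def contains(self, value) -> bool:
        if self.kind == "categorical":
            return value in self.levels
        return self.bounds[0] <= value <= self.bounds[1]

    def as_dict(self) -> dict:
        d = {"type": self.kind, "per_layer": self.per_layer}
        if self.kind == "categorical":
            d["levels"] = list(self.levels)
        else:
            d["range"] = list(self.bounds)
        return d

    @classmethod
    def from_dict(cls, name: str, d: dict) -> "Factor":
        kind = d.get("type", "categorical")
        return cls(
            name=name,
            kind=kind,
            levels=tuple(d.get("levels", ())),
            bounds=tuple(d.get("range", ())),
            per_layer=bool(d.get("per_layer", False)),
        )


# factor names a network space understands
_SCALAR_FACTORS = ("depth", "optimizer", "loss", "epochs")


@dataclass(frozen=True)
class ParameterSpace:
    """Named factors describing a family of network architectures.

    Recognized factors: ``depth``, ``units`` (int range or level set,
    optionally per-layer), ``activation`` (per-layer body pool),
    ``final_activation`` (optional separate pool for the last hidden
    layer), ``optimizer``, ``loss``, ``epochs``.
    """

    factors: tuple  # tuple of Factor, ordered

    def __post_init__(self) -> None:
        factors = tuple(self.factors)
        names = [f.name for f in factors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate factor names")
        for required in ("depth", "units", "activation"):
            if required not in names:
                raise ValueError(f"space is missing the {required!r} factor")
        object.__setattr__(self, "factors", factors)

    def __getitem__(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.factors)

    @property
    def names(self) -> tuple:
        return tuple(f.name for f in self.factors)

    def replace_factor(self, factor: Factor) -> "ParameterSpace":
        out = [factor if f.name == factor.name else f for f in self.factors]
        if factor.name not in self.names:
            out.append(factor)
        return ParameterSpace(tuple(out))

    # -- sampling and counting ------------------------------------------

    def sample_spec(self, rng: np.random.Generator, n_inputs: int) -> ArchitectureSpec:
        """Draw one uniform configuration from the space."""
        depth = int(self["depth"].sample(rng))
        units_f = self["units"]
        if units_f.per_layer:
            units = tuple(units_f.sample(rng) for _ in range(depth))
        else:
            units = (units_f.sample(rng),) * depth
        act_f = self["activation"]
        if "final_activation" in self:
            body = tuple(act_f.sample(rng) for _ in range(depth - 1))
            acts = (*body, self["final_activation"].sample(rng))
        else:
            acts = tuple(act_f.sample(rng) for _ in range(depth))
        kw = {}
        for name in ("optimizer", "loss"):
            if name in self:
                kw[name] = self[name].sample(rng)
        epochs = int(self["epochs"].sample(rng)) if "epochs" in self else 100
        return ArchitectureSpec(
            n_inputs=n_inputs, units=units, activations=acts, epochs=epochs, **kw
        )

    def n_configurations(self) -> int:
        """Exact size of the discrete configuration space (python int)."""
        act = self["activation"].n_levels
        units = self["units"].n_levels
        final = self["final_activation"].n_levels if "final_activation" in self else None
        total = 0
        for depth in self["depth"].levels:
            d = int(depth)
            n_act = act ** (d - 1) * final if final is not None else act**d
            n_units = units**d if self["units"].per_layer else units
            total += n_act * n_units
        for name in ("optimizer", "loss", "epochs"):
            if name in self:
                total *= self[name].n_levels
        return total

    def contains_spec(self, spec: ArchitectureSpec) -> bool:
        if not self["depth"].contains(spec.depth) and not self["depth"].contains(
            str(spec.depth)
        ):
            return False
        units_ok = all(self["units"].contains(u) for u in spec.units)
        if not self["units"].per_layer and len(set(spec.units)) > 1:
            units_ok = False
        body, last = spec.activations[:-1], spec.activations[-1]
        act_ok = all(self["activation"].contains(a) for a in body)
        if "final_activation" in self:
            act_ok = act_ok and self["final_activation"].contains(last)
        else:
            act_ok = act_ok and self["activation"].contains(last)
        scalar_ok = all(
            name not in self or self[name].contains(getattr(spec, name))
            for name in ("optimizer", "loss", "epochs")
        )
        return units_ok and act_ok and scalar_ok

    def is_subspace_of(self, other: "ParameterSpace") -> bool:
        """True when every level of every factor also lies in ``other``."""
        for f in self.factors:
            if f.name == "final_activation" and f.name not in other:
                host = other["activation"]
            elif f.name not in other:
                return False
            else:
                host = other[f.name]
            if f.kind == "categorical":
                values = f.levels
            else:
                values = range(f.bounds[0], f.bounds[1] + 1)
            if not all(host.contains(v) for v in values):
                return False
        return True

    # -- io --------------------------------------------------------------

    def as_dict(self) -> dict:
        return {f.name: f.as_dict() for f in self.factors}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSpace":
        return cls(tuple(Factor.from_dict(name, spec) for name, spec in d.items()))


def wide_space() -> ParameterSpace:
    """The stage-1 search space: every factor at its widest setting."""
    return ParameterSpace(
        (
            Factor("depth", "categorical", levels=(3, 4, 5, 6, 7, 8)),
            Factor("units", "int", bounds=(5, 255), per_layer=True),
            Factor("activation", "categorical", levels=ACTIVATIONS, per_layer=True),
            Factor("optimizer", "categorical", levels=OPTIMIZERS),
            Factor("loss", "categorical", levels=LOSSES),
            Factor("epochs", "categorical", levels=EPOCH_LEVELS),
        )
    )


def table4_space() -> ParameterSpace:
    """The already-narrowed reference space for the orthogonal-array stage.

    Four activations (relu/elu/selu/sigmoid), depth 3-6, units 5-255,
    RMSProp only, three losses, three epoch settings.
    """
    return ParameterSpace(
        (
            Factor("depth", "categorical", levels=(3, 4, 5, 6)),
            Factor("units", "int", bounds=(5, 255), per_layer=True),
            Factor(
                "activation",
                "categorical",
                levels=("relu", "elu", "selu", "sigmoid"),
                per_layer=True,
            ),
            Factor("optimizer", "categorical", levels=("rmsprop",)),
            Factor("loss", "categorical", levels=LOSSES),
            Factor("epochs", "categorical", levels=EPOCH_LEVELS),
        )
    )


@dataclass
class TrialLog:
    """Ordered record of the trials of one search."""

    trials: list
    seed: int
    budget: int
    space: ParameterSpace | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def top(self, k: int, metric: str = "r2") -> list:
        """The k best trials by the given metric (stable order on ties)."""
        if k < 1:
            raise ValueError("top_k must be >= 1")
        if k > len(self.trials):
            raise ValueError(f"top_k {k} exceeds log length {len(self.trials)}")
        order = sorted(
            range(len(self.trials)),
            key=lambda i: (-self.trials[i].sort_key(metric), i),
        )
        return [self.trials[i] for i in order[:k]]

    def best(self, metric: str = "r2") -> TrialResult:
        return self.top(1, metric)[0]

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.trials:
                fh.write(json.dumps(t.as_dict()) + "\n")

    @classmethod
    def from_jsonl(cls, path, space: ParameterSpace | None = None,
                   seed: int = 0) -> "TrialLog":
        from .metrics import MetricReport

        trials = []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                d = json.loads(line)
                trials.append(
                    TrialResult(
                        spec=ArchitectureSpec.from_dict(d["spec"]),
                        metrics=MetricReport(**d["metrics"]),
                        best_epoch=int(d["best_epoch"]),
                        seed=int(d["seed"]),
                        epochs_run=int(d.get("epochs_run", 0)),
                        wall_clock=float(d.get("wall_clock", 0.0)),
                        failed=bool(d.get("failed", False)),
                    )
                )
        return cls(trials=trials, seed=seed, budget=len(trials), space=space)


def random_search(
    space: ParameterSpace,
    train: tuple,
    test: tuple,
    budget: int = 200,
    seed: int = 0,
) -> TrialLog:
    """Stage-1 uniform random search.

    Draws ``budget`` independent configurations from ``space`` and trains
    each with :func:`ecgtune.mlp.build_and_train` on the given splits.
    Deterministic in ``seed``: the sampling stream and every per-trial
    training seed derive from it.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    Xtr = np.asarray(train[0])
    n_inputs = 1 if Xtr.ndim == 1 else Xtr.shape[1]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    trials = []
    for _ in range(budget):
        spec = space.sample_spec(rng, n_inputs)
        train_seed = int(rng.integers(2**31))
        trials.append(build_and_train(spec, train, test, seed=train_seed))
    return TrialLog(trials=trials, seed=seed, budget=budget, space=space)


def frequency_table(log: TrialLog, top_k: int = 10, metric: str = "r2") -> dict:
    """Per-factor level counts among the top trials.

    Scalar factors (depth, optimizer, loss, epochs) are counted once per
    trial, so their counts sum to ``top_k``.  Per-layer factors are
    counted per occurrence, the last hidden layer tallied separately
    under ``final_activation``/``final_units``; body and final activation
    counts together sum to the total depth of the top trials.
    """
    top = log.top(top_k, metric)
    table: dict[str, dict] = {
        name: {} for name in ("depth", "optimizer", "loss", "epochs",
                              "activation", "final_activation", "units", "final_units")
    }

    def bump(factor: str, level) -> None:
        table[factor][level] = table[factor].get(level, 0) + 1

    for t in top:
        s = t.spec
        bump("depth", s.depth)
        bump("optimizer", s.optimizer)
        bump("loss", s.loss)
        bump("epochs", s.epochs)
        for a in s.activations[:-1]:
            bump("activation", a)
        bump("final_activation", s.activations[-1])
        for u in s.units[:-1]:
            bump("units", u)
        bump("final_units", s.units[-1])
    return table


def _narrow_categorical(
    factor: Factor, counts: dict, min_freq: float, max_levels: int | None = None
) -> Factor:
    """Keep levels above the frequency threshold; near-uniform stays spread.

    ``max_levels`` caps the retained set (most frequent first) so the
    narrowed factor stays hostable by a catalogue orthogonal-array
    column.
    """
    total = sum(counts.values())
    if total == 0:
        return factor
    freqs = {lev: counts.get(lev, 0) / total for lev in factor.levels}
    values = list(freqs.values())
    if max(values) - min(values) < min_freq:  # "diverse" factor: keep spread
        kept = factor.levels
    else:
        kept = tuple(lev for lev in factor.levels if freqs[lev] >= min_freq)
        if not kept:  # never empty: fall back to the modal level
            kept = (max(factor.levels, key=lambda lev: freqs[lev]),)
    if max_levels is not None and len(kept) > max_levels:
        order = sorted(kept, key=lambda lev: -freqs[lev])[:max_levels]
        kept = tuple(lev for lev in factor.levels if lev in order)
    return replace(factor, levels=kept)


def narrow_space(
    log: TrialLog,
    top_k: int = 10,
    min_freq: float = 0.1,
    metric: str = "r2",
    units_grid=UNITS_LEVEL_GRID,
    max_levels: int = 4,
) -> ParameterSpace:
    """Shrink the search space to what the best stage-1 trials used.

    Categorical factors keep the levels whose frequency among the top-k
    trials reaches ``min_freq`` (per-occurrence frequency for per-layer
    factors); a factor whose level frequencies stay within ``min_freq``
    of each other is considered diverse and kept fully spread, and every
    factor is capped at ``max_levels`` levels (most frequent first) so an
    orthogonal-array column can host it.  The optimizer always collapses
    to its modal top-k level — the two-stage protocol fixes the
    optimizer after stage 1.  Unit counts are re-bounded to the observed
    [min, max] and snapped onto ``units_grid``.  The returned space
    always carries a separate ``final_activation`` factor so the last
    hidden layer keeps its own pool (narrowed from last-layer
    occurrences only).
    """
    if log.space is None:
        raise ValueError("log carries no originating space")
    table = frequency_table(log, top_k, metric)
    space = log.space

    factors = []
    for name in ("depth", "loss", "epochs"):
        if name in space:
            factors.append(
                _narrow_categorical(space[name], table[name], min_freq, max_levels)
            )
    if "optimizer" in space:
        counts = table["optimizer"]
        modal = max(space["optimizer"].levels, key=lambda lev: counts.get(lev, 0))
        factors.append(replace(space["optimizer"], levels=(modal,)))

    body_pool = space["activation"]
    final_pool = space["final_activation"] if "final_activation" in space else replace(
        body_pool, name="final_activation", per_layer=False
    )
    factors.append(
        _narrow_categorical(body_pool, table["activation"], min_freq, max_levels)
    )
    factors.append(
        _narrow_categorical(
            final_pool, table["final_activation"], min_freq, max_levels
        )
    )

    observed_units = sorted(
        set(table["units"]) | set(table["final_units"])
    )
    units_f = space["units"]
    if units_f.kind == "int":
        lo, hi = min(observed_units), max(observed_units)
        snapped = sorted(
            {min(units_grid, key=lambda g: (abs(g - u), g)) for u in observed_units}
        )
        snapped = [u for u in snapped if units_f.contains(u)]
        if not snapped:  # grid misses the admissible range: keep observed span
            snapped = [lo, hi] if lo != hi else [lo]
        factors.append(Factor("units", "categorical", levels=tuple(snapped)))
    else:
        factors.append(
            _narrow_categorical(
                units_f,
                {u: table["units"].get(u, 0) + table["final_units"].get(u, 0)
                 for u in units_f.levels},
                min_freq,
            )
        )

    order = {"depth": 0, "units": 1, "activation": 2, "final_activation": 3,
             "optimizer": 4, "loss": 5, "epochs": 6}
    factors.sort(key=lambda f: order.get(f.name, 99))
    return ParameterSpace(tuple(factors))
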