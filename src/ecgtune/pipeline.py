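"""End-to-end orchestration: data -> preprocessing -> tuning -> report.

The pipeline mirrors the four-step workflow the package implements:
(1) obtain recordings (synthetic generation or CSV files) and
precondition them (zero-phase Butterworth with automated cutoff,
min-max normalization at task preparation time); (2) stage-1 random
search and frequency narrowing, once per recording set; (3) the
orthogonal-array stage with confirmation run per task; (4) tables,
distribution summaries and figures.  Every stage flushes its artifacts
to the output directory as soon as it completes, and the whole run is
reproducible from (config, seeds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .combinations import (
    ARRAY_STAGE_RESERVE,
    distribution_summary,
    enumerate_combinations,
    prepare_task,
)
from .io import write_recording
from .mlp import build_train_predict
from .preprocess import (
    DEFAULT_CUTOFF_GRID,
    FilterConfig,
    SplitConfig,
    adapt_cutoff,
    butterworth_filter,
    valid_grid,
)
from .search import (
    ParameterSpace,
    frequency_table,
    narrow_space,
    random_search,
    wide_space,
)
from .synth_ecg import (
    BeatModel,
    ChannelSpec,
    RecordingSet,
    calibrate_correlation,
    generate_recording_set,
)
from .taguchi import TaguchiExperiment

__all__ = ["PipelineConfig", "Report", "run_pipeline", "StageError"]

_DEFAULTS = {
    "data": {
        "source": "synthetic",
        "sets": ["P", "T", "M"],
        "fs": 500.0,
        "duration": 30.0,
        "target_corr": 0.5,
        "paths": {},
    },
    "preprocess": {
        "order": 3,
        "cutoff": "auto",
        "grid": list(DEFAULT_CUTOFF_GRID),
        "train_fraction": 0.8,
        "split_mode": "chronological",
    },
    "search": {"budget": 20, "top_k": 10, "min_freq": 0.1},
    "taguchi": {"enabled": True, "replicates": 1, "response": "r2"},
    "seed": 7,
    "output": "ecgtune_out",
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _merge(defaults: dict, override: dict) -> dict:
    out = {}
    for key, val in defaults.items():
        if isinstance(val, dict):
            out[key] = _merge(val, override.get(key, {}) or {})
        else:
            out[key] = override.get(key, val)
    for key, val in override.items():  # keys with no declared default pass through
        if key not in out:
            out[key] = val
    return out


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline options (see module docstring for the stages)."""

    options: dict

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        opts = _merge(_DEFAULTS, d or {})
        data = opts["data"]
        if data["source"] not in ("synthetic", "files"):
            raise ValueError(f"unknown data source {data['source']!r}")
        if data["source"] == "files":
            missing = [
                s for s in data["sets"] if not Path(data["paths"].get(s, "")).exists()
            ]
            if missing:
                raise ValueError(f"recording files missing for sets: {missing}")
        if not 0 < opts["preprocess"]["train_fraction"] < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if opts["search"]["budget"] < 1:
            raise ValueError("search budget must be >= 1")
        return cls(options=opts)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __getitem__(self, key):
        return self.options[key]


@dataclass
class Report:
    """Everything one pipeline run produced, traceable to logged trials."""

    combination_table: pd.DataFrame
    frequency_tables: dict
    effects_tables: dict
    narrowed_spaces: dict
    manifest: dict
    output_dir: Path


#: Per-channel common-share used when a set's correlation target is not
#: calibrated (source == synthetic with target_corr null).
_FALLBACK_LAMBDA = 0.7


def _acquire(config: PipelineConfig, outdir: Path) -> dict:
    data = config["data"]
    if data["source"] == "files":
        from .io import read_recording

        return {s: read_recording(data["paths"][s]) for s in data["sets"]}
    beat = BeatModel()
    seed = int(config["seed"])
    if data.get("target_corr"):
        lam = calibrate_correlation(
            float(data["target_corr"]), beat,
            fs=float(data["fs"]), duration=max(60.0, float(data["duration"])),
            seed=seed,
        )
    else:
        lam = _FALLBACK_LAMBDA
    recordings = {}
    for k, set_id in enumerate(data["sets"]):
        labels = ("LEAD1", "ECGA", f"ECG{set_id}")
        channels = [ChannelSpec(lab, common_share=lam) for lab in labels]
        rec = generate_recording_set(
            beat, channels, fs=float(data["fs"]),
            duration=float(data["duration"]), seed=seed + k,
        )
        recordings[set_id] = rec
        write_recording(
            rec, outdir / f"recording_{set_id}.csv", seed=seed + k,
            channel_meta={lab: {"lambda": lam} for lab in labels},
        )
    return recordings


def _preprocess(config: PipelineConfig, recordings: dict, outdir: Path) -> dict:
    pp = config["preprocess"]
    params = {}
    filtered = {}
    for set_id, rec in recordings.items():
        out = np.empty_like(rec.samples)
        params[set_id] = {}
        for i, lab in enumerate(rec.labels):
            if pp["cutoff"] == "auto":
                cfg = adapt_cutoff(
                    rec.samples[i], rec.fs, grid=valid_grid(pp["grid"], rec.fs),
                    order=int(pp["order"]),
                )
            else:
                cfg = FilterConfig(
                    cutoff=float(pp["cutoff"]), fs=rec.fs, order=int(pp["order"])
                )
            out[i] = butterworth_filter(rec.samples[i], cfg)
            params[set_id][lab] = {"cutoff": cfg.cutoff, "order": cfg.order}
        filtered[set_id] = RecordingSet(
            labels=rec.labels, samples=out, fs=rec.fs, duration=rec.duration
        )
    (outdir / "filter_params.json").write_text(json.dumps(params, indent=2))
    return filtered


def run_pipeline(config: PipelineConfig) -> Report:
    """Execute every configured stage and write artifacts under the output dir.

    Raises :class:`StageError` naming the failing stage; artifacts of the
    stages that completed stay on disk as the last valid checkpoint.
    """
    opts = config.options
    outdir = Path(opts["output"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(opts["seed"])
    split = SplitConfig(
        train_fraction=float(opts["preprocess"]["train_fraction"]),
        mode=opts["preprocess"]["split_mode"],
        seed=seed,
    )

    try:
        recordings = _acquire(config, outdir)
    except Exception as exc:  # noqa: BLE001
        raise StageError("data", str(exc)) from exc
    try:
        recordings = _preprocess(config, recordings, outdir)
    except Exception as exc:  # noqa: BLE001
        raise StageError("preprocess", str(exc)) from exc

    budget = int(opts["search"]["budget"])
    top_k = int(opts["search"]["top_k"])
    min_freq = float(opts["search"]["min_freq"])
    taguchi_on = bool(opts["taguchi"]["enabled"])
    space = wide_space()
    combos = enumerate_combinations(
        {s: recordings[s].labels for s in opts["data"]["sets"]}
    )

    rows = []
    freq_tables: dict = {}
    effects_tables: dict = {}
    narrowed: dict = {}
    for i, spec in enumerate(combos):
        rec = recordings[spec.set_id]
        train, test = prepare_task(rec, spec, split)
        task_seed = int(np.random.default_rng([seed, i]).integers(2**31))
        try:
            log = random_search(space, train, test, budget=budget, seed=task_seed)
            log.to_jsonl(outdir / f"trials_random_{spec.set_id}_{i}.jsonl")
            best_random = log.best()
        except Exception as exc:  # noqa: BLE001
            raise StageError("random_search", f"{spec}: {exc}") from exc
        entries = [("random", best_random, budget, None)]

        if taguchi_on:
            try:
                if spec.set_id not in narrowed:
                    stage1 = random_search(
                        space, train, test,
                        budget=max(1, budget - ARRAY_STAGE_RESERVE), seed=task_seed,
                    )
                    stage1.to_jsonl(outdir / f"trials_stage1_{spec.set_id}.jsonl")
                    freq_tables[spec.set_id] = frequency_table(
                        stage1, top_k=min(top_k, len(stage1))
                    )
                    narrowed[spec.set_id] = narrow_space(
                        stage1, top_k=min(top_k, len(stage1)), min_freq=min_freq
                    )
                    (outdir / f"narrowed_{spec.set_id}.yaml").write_text(
                        yaml.safe_dump(narrowed[spec.set_id].as_dict())
                    )
                tag = TaguchiExperiment(
                    narrowed[spec.set_id], train, test,
                    response=opts["taguchi"]["response"],
                    replicates=int(opts["taguchi"]["replicates"]),
                ).fit(seed=task_seed)
                effects_tables.setdefault(spec.set_id, tag.effects.table)
                pool = list(tag.trials) + [tag.confirmation]
                best_t = max(pool, key=lambda t: t.sort_key("r2"))
                entries.append(("taguchi", best_t, len(tag.trials) + 1, tag))
            except Exception as exc:  # noqa: BLE001
                raise StageError("taguchi", f"{spec}: {exc}") from exc

        actual = distribution_summary(np.asarray(test[1], dtype=float))
        for method, best, n_final, _ in entries:
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
        pd.DataFrame(rows).to_csv(outdir / "combination_table.csv", index=False)

    table = pd.DataFrame(rows)
    manifest = {
        "seed": seed,
        "budget": budget,
        "n_combinations": len(combos),
        "taguchi_enabled": taguchi_on,
        "sets": list(opts["data"]["sets"]),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for set_id, ft in freq_tables.items():
        (outdir / f"frequency_{set_id}.json").write_text(
            json.dumps({k: {str(kk): vv for kk, vv in v.items()} for k, v in ft.items()},
                       indent=2)
        )
    for set_id, et in effects_tables.items():
        et.to_csv(outdir / f"effects_{set_id}.csv", index=False)

    try:
        from .plots import plot_combination_bars, plot_main_effects

        plot_combination_bars(table, outdir / "r2_bars.png")
        for set_id, et in effects_tables.items():
            from .taguchi import MainEffectsTable

            plot_main_effects(
                MainEffectsTable(
                    table=et, response=opts["taguchi"]["response"],
                    grand_mean=float(table[table["set"] == set_id]["r2"].mean()),
                ),
                outdir / f"effects_{set_id}.png",
            )
    except Exception:  # noqa: BLE001  plotting must never abort the pipeline
        pass

    return Report(
        combination_table=table,
        frequency_tables=freq_tables,
        effects_tables=effects_tables,
        narrowed_spaces=narrowed,
        manifest=manifest,
        output_dir=outdir,
    )
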