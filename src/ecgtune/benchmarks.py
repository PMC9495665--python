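"""Desk-scale reference benchmarks for the tuning pipelines.

These helpers pin down the synthetic reconstruction task the package
uses to validate itself end to end: a three-channel recording (Lead I
and the aortic trace as inputs, a third site as output) whose common
share is calibrated to a target inter-channel correlation, prepared with
the standard 80-20 chronological split and train-block min-max
normalization.  A linear least-squares predictor on the same splits
serves as the independent reference: the shared-rhythm generator makes
the input->output map partly nonlinear, so a well-tuned network should
match or beat it.

Problem sizes here are desk-scale by design (hundreds of trainings on a
single CPU in minutes): hidden widths up to a few dozen units and
recordings of tens of seconds, with the full-scale spaces available in
:mod:`ecgtune.search` for larger studies.
"""

from __future__ import annotations

import numpy as np

from .combinations import CombinationSpec, prepare_task
from .preprocess import SplitConfig
from .search import Factor, ParameterSpace
from .synth_ecg import BeatModel, ChannelSpec, calibrate_correlation, generate_recording_set

__all__ = [
    "make_benchmark_task",
    "linear_oracle_r2",
    "l9_benchmark_space",
    "desk_wide_space",
]


def make_benchmark_task(
    fs: float = 500.0,
    duration: float = 60.0,
    target_r: float = 0.6,
    seed: int = 0,
    output: str = "ECGP",
):
    """Two-input one-output reconstruction task on calibrated synthetic data.

    Generates LEAD1 + ECGA + ``output`` with the common share calibrated
    so channel pairs correlate at ``target_r``, then returns the
    normalized chronological 80-20 ``(train, test)`` splits for
    predicting ``output`` from the other two channels.
    """
    beat = BeatModel()
    lam = calibrate_correlation(
        target_r, beat, fs=fs, duration=max(60.0, duration), seed=seed
    )
    labels = ("LEAD1", "ECGA", output)
    channels = [ChannelSpec(lab, common_share=lam) for lab in labels]
    rec = generate_recording_set(beat, channels, fs=fs, duration=duration, seed=seed)
    task = CombinationSpec(set_id="bench", output=output, inputs=("LEAD1", "ECGA"))
    return prepare_task(rec, task, SplitConfig())


def linear_oracle_r2(train: tuple, test: tuple) -> float:
    """Test R^2 of the ordinary least-squares predictor with intercept."""
    Xtr = np.asarray(train[0], dtype=float)
    Xte = np.asarray(test[0], dtype=float)
    if Xtr.ndim == 1:
        Xtr, Xte = Xtr[:, None], Xte[:, None]
    ytr = np.asarray(train[1], dtype=float).ravel()
    yte = np.asarray(test[1], dtype=float).ravel()
    A = np.column_stack([Xtr, np.ones(len(ytr))])
    coef, *_ = np.linalg.lstsq(A, ytr, rcond=None)
    pred = np.column_stack([Xte, np.ones(len(yte))]) @ coef
    sst = float(np.sum((yte - yte.mean()) ** 2))
    sse = float(np.sum((yte - pred) ** 2))
    return 1.0 - sse / sst


def l9_benchmark_space() -> ParameterSpace:
    """Four 3-level factors (an exact L9 fit) at desk-scale widths.

    Depth, width, body activation and epoch budget vary; the final
    hidden layer is sigmoid, the optimizer RMSProp and the loss MSE —
    the levels the narrowing stage settles on.
    """
    return ParameterSpace(
        (
            Factor("depth", "categorical", levels=(3, 4, 5)),
            Factor("units", "categorical", levels=(8, 16, 32)),
            Factor(
                "activation", "categorical", levels=("relu", "elu", "selu"),
                per_layer=True,
            ),
            Factor("final_activation", "categorical", levels=("sigmoid",)),
            Factor("optimizer", "categorical", levels=("rmsprop",)),
            Factor("loss", "categorical", levels=("mse",)),
            Factor("epochs", "categorical", levels=(10, 100, 200)),
        )
    )


def desk_wide_space() -> ParameterSpace:
    """A stage-1 space with full factor structure at desk-scale widths."""
    return ParameterSpace(
        (
            Factor("depth", "categorical", levels=(3, 4, 5, 6)),
            Factor("units", "int", bounds=(5, 64), per_layer=True),
            Factor(
                "activation",
                "categorical",
                levels=("relu", "elu", "selu", "sigmoid", "tanh", "linear"),
                per_layer=True,
            ),
            Factor("optimizer", "categorical", levels=("rmsprop", "adam", "sgd")),
            Factor("loss", "categorical", levels=("mse", "mae", "val_loss")),
            Factor("epochs", "categorical", levels=(10, 100, 200)),
        )
    )
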