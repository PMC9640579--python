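"""Reference study protocols on synthetic gait data.

Two standard runs are defined here so the test suite and the reproduction
script execute the exact same conditions:

* :func:`full_protocol` — the full acquisition emulation (11 trials of 60 s
  at 5 kHz, LG channel) with the reference training schedule (50 epochs,
  learning rate 1e-3) and 5-fold trial-level cross-validation of the
  FG-CNN + random-forest pipeline.
* :func:`comparison_benchmark` — a scaled-down analogue used for the
  three-way feature-set comparison (HF vs CNN vs FG-CNN, all through the
  same RF).  Trials, duration and training epochs are scaled together
  (5 trials of 15 s, 10 epochs): with ~1/9 of the data, longer training
  makes the learned features memorize within-trial noise and the comparison
  degenerates, so the schedule shrinks with the dataset.  Reported values
  are medians over per-fold metrics, then over benchmark seeds.
"""

from __future__ import annotations

import numpy as np

from .experiment import ExperimentConfig, run_experiment
from .fgcnn import FGCNNConfig
from .regression import RegressorSpec
from .synthetic_gait import GaitSimConfig


def full_protocol(seed=0, feature_sets=("FGCNN",), verbose=False):
    """Full-scale FG-CNN-RF evaluation on the default synthetic subject."""
    cfg = ExperimentConfig(
        sim=GaitSimConfig(seed=seed),
        muscle="LG",
        feature_sets=tuple(feature_sets),
        fgcnn=FGCNNConfig(epochs=50, learning_rate=1e-3),
        regressor=RegressorSpec("RF"),
        seed=seed,
    )
    return run_experiment(cfg, verbose=verbose)


def comparison_benchmark(seeds=(0, 1, 2), verbose=False):
    """Three-way feature-set comparison on the scaled-down benchmark.

    Returns ``(medians, frames)``: per-feature-set median held-out CC and
    NRMSE (median over folds, then over seeds), plus the per-seed result
    frames.
    """
    frames = []
    for seed in seeds:
        cfg = ExperimentConfig(
            sim=GaitSimConfig(n_trials=5, trial_duration_s=15.0, seed=seed),
            muscle="LG",
            feature_sets=("HF", "CNN", "FGCNN"),
            fgcnn=FGCNNConfig(epochs=10, learning_rate=1e-3),
            regressor=RegressorSpec("RF"),
            seed=seed,
        )
        frames.append(run_experiment(cfg, verbose=verbose).frame)
    medians = {}
    for fs in ("HF", "CNN", "FGCNN"):
        per_seed_cc = [
            float(f.loc[f.feature_set == fs, "cc"].median()) for f in frames
        ]
        per_seed_nrmse = [
            float(f.loc[f.feature_set == fs, "nrmse"].median()) for f in frames
        ]
        medians[fs] = {
            "cc": float(np.median(per_seed_cc)),
            "nrmse": float(np.median(per_seed_nrmse)),
        }
    return medians, frames
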