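"""End-to-end experiment orchestration.

One experiment runs, for a chosen muscle channel: simulate-or-load ->
band-pass filter -> window -> handcrafted features -> (train FG-CNN and/or
baseline CNN) -> regressor -> per-fold NRMSE/CC -> Kruskal-Wallis comparison
across feature sets.  Every run is a pure function of (config, seed); the
written results CSV is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ConfigError
from .evaluation import cc, kruskal_wallis, make_folds, nrmse, train_test_indices
from .fgcnn import BaselineCNN, FGCNN, FGCNNConfig
from .handcrafted_features import feature_matrix
from .regression import AngleRegressor, RegressorSpec
from .signal_io import AngleScaler, build_windowed_dataset, read_recording
from .synthetic_gait import GaitSimConfig, generate_subject

FEATURE_SETS = ("HF", "CNN", "FGCNN")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one comparison run."""

    sim: GaitSimConfig | None = None
    data_dir: str | None = None          # directory of recording stems
    muscle: str = "LG"
    feature_sets: tuple = FEATURE_SETS
    regressor: RegressorSpec = field(default_factory=RegressorSpec)
    k_folds: int = 5
    cv_scheme: str = "trial"
    window_ms: float = 50.0
    step_ms: float = 20.0
    band: tuple = (10.0, 500.0)
    filter_order: int = 4
    zc_threshold: float = 0.0
    ssc_threshold: float = 0.0
    fgcnn: FGCNNConfig | None = None
    seed: int = 0

    def __post_init__(self):
        if (self.sim is None) == (self.data_dir is None):
            raise ConfigError("exactly one data source: sim or data_dir")
        bad = [f for f in self.feature_sets if f not in FEATURE_SETS]
        if bad:
            raise ConfigError(f"feature_sets: unknown entries {bad}")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        if d["sim"] is not None:
            d["sim"]["angle_template"] = list(np.asarray(d["sim"]["angle_template"]))
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _load_recordings(config: ExperimentConfig):
    if config.sim is not None:
        return generate_subject(config.sim)
    stems = sorted(
        p.name[: -len(".meta.json")]
        for p in Path(config.data_dir).glob("*.meta.json")
    )
    if not stems:
        raise ConfigError(f"no recordings found under {config.data_dir}")
    return [read_recording(Path(config.data_dir) / s) for s in stems]


def _fold_seed(seed: int, feature_set: str, fold: int) -> int:
    key = f"{seed}:{feature_set}:{fold}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2 ** 31)


class ExperimentResult:
    """Per-fold metrics table, statistical comparisons, and provenance."""

    def __init__(self, frame: pd.DataFrame, tests: dict, config: ExperimentConfig,
                 extras: dict | None = None):
        self.frame = frame
        self.tests = tests
        self.config = config
        self.extras = extras or {}

    def summary(self) -> str:
        agg = (
            self.frame.groupby("feature_set")[["nrmse", "cc"]]
            .agg(["mean", "std"])
            .round(4)
        )
        lines = [
            f"muscle {self.config.muscle}  regressor {self.config.regressor.kind}  "
            f"{self.config.k_folds}-fold ({self.config.cv_scheme})",
            "=" * 60,
            agg.to_string(),
        ]
        for metric, res in self.tests.items():
            lines.append(
                f"Kruskal-Wallis on {metric}: H = {res['H']:.4f}, p = {res['p']:.4g}"
            )
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(out / "results.csv", index=False, float_format="%.10g")
        payload = {
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "code_version": __version__,
            "tests": self.tests,
        }
        (out / "summary.json").write_text(json.dumps(payload, indent=1, default=str))

    def plot(self, path=None):
        """Bar chart of mean +- SD NRMSE and CC per feature set."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        agg = self.frame.groupby("feature_set")[["nrmse", "cc"]].agg(["mean", "std"])
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
        for ax, metric, unit in zip(axes, ("nrmse", "cc"), ("%", "")):
            ax.bar(agg.index, agg[(metric, "mean")], yerr=agg[(metric, "std")],
                   capsize=4)
            ax.set_ylabel(f"{metric.upper()} {unit}".strip())
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


class KneeAngleExperiment:
    """Model-object wrapper: construct with a config, then :meth:`run`."""

    def __init__(self, config: ExperimentConfig):
        self.config = config

    def run(self, verbose=False) -> ExperimentResult:
        return run_experiment(self.config, verbose=verbose)


def run_experiment(config: ExperimentConfig, verbose=False) -> ExperimentResult:
    """Execute the full pipeline; returns an :class:`ExperimentResult`."""
    recordings = _load_recordings(config)
    ds = build_windowed_dataset(
        recordings, config.muscle, config.window_ms, config.step_ms,
        band=config.band, filter_order=config.filter_order,
    )
    P = feature_matrix(ds.windows, config.zc_threshold, config.ssc_threshold)
    fold_ids = make_folds(
        n=len(ds), k=config.k_folds, scheme=config.cv_scheme,
        trial_ids=ds.trial_ids, seed=config.seed,
    )
    fg_cfg = config.fgcnn or FGCNNConfig(input_len=ds.windows.shape[1])
    rows = []
    predictions = {}
    for feature_set in config.feature_sets:
        for fold in range(config.k_folds):
            tr, te = train_test_indices(fold_ids, fold)
            scaler = AngleScaler.fit(ds.targets_deg[tr])
            if feature_set == "HF":
                feats_tr, feats_te = P[tr], P[te]
            else:
                seed = _fold_seed(config.seed, feature_set, fold)
                if feature_set == "FGCNN":
                    model = FGCNN(ds.windows[tr], P[tr],
                                  scaler.scale(ds.targets_deg[tr]), config=fg_cfg)
                    res = model.fit(seed=seed)
                    feats_tr = res.extract_features(ds.windows[tr], P[tr])
                    feats_te = res.extract_features(ds.windows[te], P[te])
                else:  # CNN baseline
                    base_cfg = FGCNNConfig(
                        input_len=fg_cfg.input_len,
                        conv_filters=fg_cfg.conv_filters,
                        conv_kernels=fg_cfg.conv_kernels,
                        fc_sizes=(fg_cfg.fc_sizes[0], 28),
                        learning_rate=fg_cfg.learning_rate,
                        epochs=fg_cfg.epochs,
                        batch_size=fg_cfg.batch_size,
                    )
                    model = BaselineCNN(ds.windows[tr], None,
                                        scaler.scale(ds.targets_deg[tr]),
                                        config=base_cfg)
                    res = model.fit(seed=seed)
                    feats_tr = res.extract_features(ds.windows[tr])
                    feats_te = res.extract_features(ds.windows[te])
            spec = RegressorSpec(config.regressor.kind,
                                 dict(config.regressor.hyperparameters),
                                 seed=_fold_seed(config.seed, feature_set + "-reg", fold))
            reg = AngleRegressor(spec).fit(feats_tr, ds.targets_deg[tr])
            y_hat = reg.predict(feats_te)
            rows.append({
                "subject": recordings[0].subject_id,
                "muscle": config.muscle,
                "feature_set": feature_set,
                "regressor": config.regressor.kind,
                "fold": fold,
                "nrmse": nrmse(ds.targets_deg[te], y_hat),
                "cc": cc(ds.targets_deg[te], y_hat),
            })
            predictions[(feature_set, fold)] = (te, y_hat)
            if verbose:
                r = rows[-1]
                print(f"{feature_set:6s} fold {fold}: "
                      f"NRMSE {r['nrmse']:6.2f}%  CC {r['cc']:.4f}")
    frame = pd.DataFrame(rows)
    tests = {}
    if len(config.feature_sets) >= 2:
        for metric in ("nrmse", "cc"):
            groups = [frame.loc[frame.feature_set == fs, metric].to_numpy()
                      for fs in config.feature_sets]
            h, p = kruskal_wallis(*groups)
            tests[metric] = {"H": h, "p": p,
                             "groups": list(config.feature_sets)}
    return ExperimentResult(frame, tests, config,
                            extras={"predictions": predictions,
                                    "targets_deg": ds.targets_deg,
                                    "fold_ids": fold_ids})
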