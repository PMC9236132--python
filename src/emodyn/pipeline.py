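"""End-to-end analysis: recordings -> features -> trajectory -> modulation fit.

``analyze_cohort`` is the in-memory core; ``run_pipeline`` wraps it with
configuration, synthesis/loading, persistence of every intermediate, and a
manifest (versions, seed, config hash) so a run is reproducible
bit-for-bit from its config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bands import EMOTION_CHANNELS
from .dynamics import (ZCRParams, cognitive_load_index, fit_modulation,
                       raw_signal_zcr, zcr_ec, ModulationFit)
from .entropy_features import EntropyParams, sliding_feature_series
from .preprocess import EEGRecording, epoch_signal, preprocess_recording
from .spectral_hht import band_powers
from .stats_report import anova_report
from .synthetic_data import CohortConfig, ConfigError, generate_cohort
from .trajectory import FeatureMatrix, cfs_select, isomap_embed, EmotionTrajectory

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "CohortAnalysis", "analyze_cohort", "run_pipeline"]

# default trajectory feature set: ordinal complexity + the frequency-domain
# wavelet features (entropy plus rhythm energy ratios) per emotion channel
_DEFAULT_ESTIMATORS = ("pen", "wavelet")


@dataclass
class PipelineConfig:
    """All stage parameters; every field has a usable default."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    synthesize: bool = True
    input_dir: str | None = None
    line_freq: float | None = 50.0
    hp: float = 1.0
    lp: float = 50.0
    epoch_length: float = 4.0
    estimators: tuple[str, ...] = _DEFAULT_ESTIMATORS
    entropy: EntropyParams = field(default_factory=EntropyParams)
    cfs_n_select: int = 15
    isomap_k: int = 10
    zcr: ZCRParams = field(default_factory=ZCRParams)

    def __post_init__(self) -> None:
        self.estimators = tuple(self.estimators)
        if not self.synthesize and not self.input_dir:
            raise ConfigError("either synthesize=true or input_dir must be set")
        if self.cfs_n_select < 1:
            raise ConfigError("cfs_n_select must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig(**d["cohort"])
        if "entropy" in d and isinstance(d["entropy"], dict):
            d["entropy"] = EntropyParams(**d["entropy"])
        if "zcr" in d and isinstance(d["zcr"], dict):
            d["zcr"] = ZCRParams(**d["zcr"])
        try:
            return cls(**d)
        except TypeError as err:
            raise ConfigError(f"invalid pipeline config: {err}") from err

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=_json_default, sort_keys=True)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    return str(o)


@dataclass
class CohortAnalysis:
    """All per-subject and cohort-level outputs of one analysis run."""

    subjects: pd.DataFrame            # participant, condition, cli, zcr_ec, raw_zcr, features...
    selected_features: list[str]
    fit_trajectory: ModulationFit     # trajectory ZCR_EC ~ CLI
    fit_raw: ModulationFit            # raw-signal ZCR ~ CLI
    anova: pd.DataFrame               # per-feature group comparison
    trajectories: dict[str, EmotionTrajectory]


def _subject_features(rec: EEGRecording, cfg: PipelineConfig):
    """Preprocess one recording; return (CLI, raw ZCR, window features)."""
    clean = preprocess_recording(rec, line_freq=cfg.line_freq, hp=cfg.hp, lp=cfg.lp)
    epochs = epoch_signal(clean, cfg.epoch_length)
    bands = band_powers(epochs)
    cli = cognitive_load_index(bands)
    rz = raw_signal_zcr(clean, channels=tuple(
        c for c in EMOTION_CHANNELS if c in clean.channel_labels))
    em_channels = tuple(c for c in EMOTION_CHANNELS if c in clean.channel_labels)
    fs = sliding_feature_series(clean, cfg.estimators, cfg.entropy, channels=em_channels)
    return cli, rz, fs


def analyze_cohort(recordings: list[EEGRecording], cfg: PipelineConfig | None = None
                   ) -> CohortAnalysis:
    """Run the full analysis on labelled recordings.

    Every recording's ``meta`` must carry ``condition`` and ``participant``.
    Feature selection is joint (pooled windows across subjects, class =
    condition); the Isomap embedding is per subject, so each participant
    gets an individual emotion trajectory and ZCR_EC.
    """
    cfg = cfg or PipelineConfig()
    per_subject = []
    frames = []
    for rec in recordings:
        pid = rec.meta.get("participant")
        cond = rec.meta.get("condition")
        if pid is None or cond is None:
            raise ValueError("each recording needs meta['participant'] and meta['condition']")
        cli, rz, feats = _subject_features(rec, cfg)
        wide = feats.wide()
        frames.append((pid, cond, wide))
        row = {"participant": pid, "condition": cond,
               "cli": cli.subject_mean, "raw_zcr": rz}
        # subject-level mean of each estimator over windows and channels
        for f_i, name in enumerate(feats.feature_names):
            row[f"mean_{name}"] = float(feats.values[:, :, f_i].mean())
        per_subject.append(row)
        logger.info("subject %s (%s): cli=%.4f raw_zcr=%.1f windows=%d",
                    pid, cond, cli.subject_mean, rz, feats.n_windows)

    pooled = pd.concat([w for _, _, w in frames], ignore_index=True)
    labels = np.concatenate([[cond] * len(w) for _, cond, w in frames])
    subj_ids = np.concatenate([[pid] * len(w) for pid, _, w in frames])
    fm = FeatureMatrix(pooled.to_numpy(float), tuple(pooled.columns),
                       labels=labels, subject_ids=subj_ids)
    n_sel = min(cfg.cfs_n_select, len(fm.feature_names))
    selected = cfs_select(fm, n_select=n_sel)

    # standardize selected columns on pooled statistics, then embed per subject
    sel_idx = [fm.feature_names.index(n) for n in selected]
    mu = fm.values[:, sel_idx].mean(axis=0)
    sd = fm.values[:, sel_idx].std(axis=0)
    sd[sd == 0] = 1.0

    trajectories: dict[str, EmotionTrajectory] = {}
    for row, (pid, cond, wide) in zip(per_subject, frames):
        X = (wide.to_numpy(float)[:, sel_idx] - mu) / sd
        sub_fm = FeatureMatrix(X, tuple(selected))
        traj = isomap_embed(sub_fm, k_neighbors=cfg.isomap_k,
                            timestamps=wide.index.to_numpy(float))
        trajectories[pid] = traj
        row["zcr_ec"] = zcr_ec(traj, cfg.zcr).zcr_ec

    subjects = pd.DataFrame(per_subject)
    fit_traj = fit_modulation(subjects["cli"].to_numpy(), subjects["zcr_ec"].to_numpy())
    fit_raw = fit_modulation(subjects["cli"].to_numpy(), subjects["raw_zcr"].to_numpy())

    feature_cols = [c for c in subjects.columns if c.startswith("mean_")] + ["cli"]
    conds = sorted(subjects["condition"].unique())
    groups = {c: [subjects.loc[subjects.condition == g, c].to_numpy() for g in conds]
              for c in feature_cols}
    anova = anova_report(groups)

    return CohortAnalysis(subjects, selected, fit_traj, fit_raw, anova, trajectories)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> CohortAnalysis:
    """Synthesize (or load) a cohort, analyze it, persist everything.

    Writes per-subject table, selected features, trajectories, modulation
    fits, the ANOVA report, and a manifest with the config hash and
    library versions.  Re-running with the same config reproduces all
    numeric outputs bit-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.synthesize:
        recordings, truth = generate_cohort(cfg.cohort)
        (out / "ground_truth.json").write_text(json.dumps(truth.as_dict(), indent=2))
    else:
        from .io import load_recording
        paths = sorted(Path(cfg.input_dir).glob("*.csv"))
        if not paths:
            raise FileNotFoundError(f"no .csv recordings under {cfg.input_dir}")
        recordings = [load_recording(p) for p in paths]
        for p, rec in zip(paths, recordings):
            rec.meta.setdefault("participant", p.stem)

    result = analyze_cohort(recordings, cfg)

    result.subjects.to_csv(out / "subjects.csv", index=False)
    (out / "selected_features.json").write_text(json.dumps(result.selected_features))
    traj_rows = [
        {"participant": pid, "time": float(t), "value": float(v)}
        for pid, tr in result.trajectories.items()
        for t, v in zip(tr.timestamps, tr.values)
    ]
    pd.DataFrame(traj_rows).to_csv(out / "trajectories.csv", index=False)
    fits = {"trajectory": asdict(result.fit_trajectory), "raw_signal": asdict(result.fit_raw)}
    (out / "modulation_fit.json").write_text(json.dumps(fits, indent=2))
    result.anova.to_csv(out / "anova.csv")
    (out / "anova.md").write_text(result.anova.to_markdown())

    cfg_json = cfg.to_json()
    outputs = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.cohort.seed,
        "numpy": np.__version__,
        "outputs": {
            name: hashlib.sha256((out / name).read_bytes()).hexdigest()
            for name in outputs
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
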