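"""Run configuration and the end-to-end pipeline.

A :class:`RunConfig` is a single YAML-serializable document holding every
tunable of the workflow (paradigm, effect, filter band, artifact threshold,
feature options, classifier and CV settings, seeds). Unknown keys are
rejected at parse time. :func:`run_pipeline` executes

    simulate -> preprocess -> extract -> classify -> groupstats

into a run directory and writes a provenance manifest with content hashes,
so re-running an identical config reproduces identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .montage import CHANNELS_30, OCCIPITAL, PREFRONTAL

log = logging.getLogger("attnfuse")


class ParadigmConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_trials: int = 20
    cue_s: float = 3.0
    task_s: float = 60.0
    rest_s: float = 10.0
    fs: float = 250.0
    channels: list[str] = list(CHANNELS_30)


class EffectConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    band_gain: dict[str, float] = {"theta": 0.7, "alpha": 0.7, "beta": 0.7}
    affected_channels: list[str] = list(PREFRONTAL + OCCIPITAL)
    noise_exponent: float = 1.0
    artifact_rate: float = 0.0
    subject_gain_sd: float = 0.1
    shared_background: float = 0.3


class FilterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    low: float = 0.5
    high: float = 50.0


class FeatureConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    blocks: list[str] = ["time", "freq", "nonlinear"]
    wavelet: str = "db4"
    quantile: float = 0.75
    sef_percentile: float = 0.95
    entropy_q: float = 2.0


class ClassifyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    classifier: str = "rf"
    mode: str = "intra"                 # "intra" | "loso" | "both"
    n_folds: int = 5


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_subjects: int = 3
    seed: int = 0
    amp_threshold: float = 100.0
    paradigm: ParadigmConfig = ParadigmConfig()
    effect: EffectConfig = EffectConfig()
    filter: FilterConfig = FilterConfig()
    features: FeatureConfig = FeatureConfig()
    classify: ClassifyConfig = ClassifyConfig()
    group_stats: bool = True

    @model_validator(mode="after")
    def _validate(self) -> "RunConfig":
        if not (0 < self.filter.low < self.filter.high < self.paradigm.fs / 2):
            raise ValueError(
                f"filter band ({self.filter.low}, {self.filter.high}) must "
                f"satisfy 0 < low < high < fs/2 = {self.paradigm.fs / 2}"
            )
        if self.amp_threshold <= 0:
            raise ValueError("amp_threshold must be positive")
        unknown = set(self.features.blocks) - {"time", "freq", "nonlinear"}
        if unknown:
            raise ValueError(f"unknown feature blocks {sorted(unknown)}")
        return self

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(text) or {})

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full workflow into ``out_dir``; returns the manifest."""
    from .fusion_classify import build_design_matrix, intra_subject_cv, loso_cv
    from .group_stats import band_topography, paired_feature_ttests, \
        subject_state_means
    from .io_preprocess import bandpass_fir, reject_artifacts, segment_epochs
    from .synthetic import EffectSpec, ParadigmSpec, generate_cohort

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    paradigm = ParadigmSpec(
        n_trials=cfg.paradigm.n_trials, cue_s=cfg.paradigm.cue_s,
        task_s=cfg.paradigm.task_s, rest_s=cfg.paradigm.rest_s,
        fs=cfg.paradigm.fs, channels=tuple(cfg.paradigm.channels),
    )
    effect = EffectSpec(
        band_gain=dict(cfg.effect.band_gain),
        affected_channels=tuple(cfg.effect.affected_channels),
        noise_exponent=cfg.effect.noise_exponent,
        artifact_rate=cfg.effect.artifact_rate,
        subject_gain_sd=cfg.effect.subject_gain_sd,
        shared_background=cfg.effect.shared_background,
    )

    def stage(name):
        log.info("stage %s", name)

    stage("simulate")
    sessions = generate_cohort(cfg.n_subjects, paradigm, effect, seed=cfg.seed)

    stage("preprocess")
    cohort = []
    for s in sessions:
        rec = bandpass_fir(s.recording, cfg.filter.low, cfg.filter.high)
        es = reject_artifacts(segment_epochs(rec, subject_id=s.subject_id),
                              amp_threshold=cfg.amp_threshold)
        cohort.append((s, es))
    log.info("epochs per subject: %s", [len(es) for _, es in cohort])

    stage("extract")
    dms = [
        build_design_matrix(es, fs=paradigm.fs,
                            blocks=tuple(cfg.features.blocks),
                            channel_names=paradigm.channels)
        for _, es in cohort
    ]
    features_path = out / "features.csv"
    frames = []
    for dm in dms:
        f = dm.X.copy()
        f.insert(0, "state", dm.y)
        f.insert(0, "subject", dm.subject)
        frames.append(f)
    import pandas as pd

    pd.concat(frames, ignore_index=True).to_csv(features_path, index=False)

    stage("classify")
    results = {"config_hash": cfg.content_hash(), "seed": cfg.seed, "runs": []}
    if cfg.classify.mode in ("intra", "both"):
        for dm in dms:
            r = intra_subject_cv(dm, cfg.classify.classifier,
                                 cfg.classify.n_folds, seed=cfg.seed)
            d = r.as_dict()
            d.update(mode="intra", subject=str(dm.subject[0]))
            results["runs"].append(d)
    if cfg.classify.mode in ("loso", "both"):
        r = loso_cv(dms, cfg.classify.classifier, seed=cfg.seed)
        d = r.as_dict()
        d.update(mode="loso")
        results["runs"].append(d)
    results_path = out / "results.json"
    results_path.write_text(json.dumps(results, indent=1, sort_keys=True))

    outputs = [features_path, results_path]
    if cfg.group_stats and cfg.n_subjects >= 3 and "freq" in cfg.features.blocks:
        stage("groupstats")
        all_dm = _concat_design(dms)
        means = subject_state_means(all_dm)
        pmat = paired_feature_ttests(means)
        p_path = out / "feature_pvalues.csv"
        pmat.to_csv(p_path)
        topo = band_topography(all_dm)
        t_path = out / "topography.csv"
        topo.to_csv(t_path)
        outputs += [p_path, t_path]

    manifest = {
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "config": cfg.model_dump(),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    (out / "config.yaml").write_text(cfg.to_yaml())
    return manifest


def _concat_design(dms):
    import pandas as pd

    from .fusion_classify import DesignMatrix

    return DesignMatrix(
        X=pd.concat([dm.X for dm in dms], ignore_index=True),
        y=np.concatenate([dm.y for dm in dms]),
        subject=np.concatenate([dm.subject for dm in dms]),
        trial=np.concatenate([dm.trial for dm in dms]),
        epoch=np.concatenate([dm.epoch for dm in dms]),
    )
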