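"""End-to-end orchestration: simulate -> preprocess -> features -> models -> report.

A :class:`PipelineConfig` carries every constant of the analysis (all
defaulting to the study values) and round-trips losslessly through YAML.
:func:`run_pipeline` executes the stages into a run directory with
checksum-guarded caching, per-stage timing logs and seeded determinism;
:func:`analyze_cohort` is the in-memory equivalent used by tests and
programmatic callers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arhmm, modeling, preprocess, synthetic, tffeatures
from .errors import InvalidConfigError
from .recordings import read_manifest, read_recording, write_manifest
from .seeds import STREAM_GIBBS_STAGE1, STREAM_MODEL, child_rng

logger = logging.getLogger("imukit")


@dataclass
class GeneratorSection:
    n_ataxia: int = 20
    n_control: int = 14
    n_parkinsonism: int = 6
    repeat_fraction: float = 0.2


@dataclass
class PreprocessSection:
    denoise_threshold: float = 0.04
    downsample_factor: int = 10


@dataclass
class SSTSection:
    fmin_hz: float = 0.1
    fmax_hz: float = 15.0
    voices_per_octave: int = 32


@dataclass
class GibbsSection:
    # production schedule; tests use the reduced (200 / 20 / 100) schedule
    stage1_iters: int = 2000
    stage1_burn: int = 100
    stage1_truncate_at: int = 1000
    stage2_iters: int = 200
    stage2_burn: int = 50


@dataclass
class ModelingSection:
    classes: tuple = ("ataxia", "control")
    feature_subset: str = "all"
    regression_targets: tuple = ("bars_total", "bars_right_arm", "bars_arm_leg")


@dataclass
class PipelineConfig:
    seed: int = 0
    generator: GeneratorSection = field(default_factory=GeneratorSection)
    preprocessing: PreprocessSection = field(default_factory=PreprocessSection)
    sst: SSTSection = field(default_factory=SSTSection)
    arhmm_hyper: arhmm.ARHMMHyperParams = field(default_factory=arhmm.ARHMMHyperParams)
    gibbs: GibbsSection = field(default_factory=GibbsSection)
    modeling: ModelingSection = field(default_factory=ModelingSection)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        h = d["arhmm_hyper"]
        for key in ("S0", "M0", "K0"):
            h[key] = np.asarray(h[key]).tolist()
        d["modeling"]["classes"] = list(d["modeling"]["classes"])
        d["modeling"]["regression_targets"] = list(d["modeling"]["regression_targets"])
        return d

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        if "seed" in d:
            cfg.seed = int(d["seed"])
        for name, section_cls in (
            ("generator", GeneratorSection),
            ("preprocessing", PreprocessSection),
            ("sst", SSTSection),
            ("gibbs", GibbsSection),
        ):
            if name in d:
                setattr(cfg, name, section_cls(**d[name]))
        if "modeling" in d:
            m = dict(d["modeling"])
            for key in ("classes", "regression_targets"):
                if key in m:
                    m[key] = tuple(m[key])
            cfg.modeling = ModelingSection(**m)
        if "arhmm_hyper" in d:
            h = dict(d["arhmm_hyper"])
            for key in ("S0", "M0", "K0"):
                if key in h and h[key] is not None:
                    h[key] = np.asarray(h[key], dtype=float)
            cfg.arhmm_hyper = arhmm.ARHMMHyperParams(**h)
        return cfg

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        if not p.exists():
            raise InvalidConfigError(f"config file not found: {source}")
        return cls.from_dict(yaml.safe_load(p.read_text()) or {})


def _config_hash(payload) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[
        :16
    ]


# ---------------------------------------------------------------------------
# in-memory analysis


def analyze_cohort(config: PipelineConfig) -> dict:
    """Run the whole analysis in memory and return all intermediate artifacts."""
    g = config.generator
    profiles, recordings, manifest = synthetic.generate_cohort(
        g.n_ataxia, g.n_control, g.n_parkinsonism, g.repeat_fraction, seed=config.seed
    )

    obs_store = {}
    for (_, mrow), rec in zip(manifest.iterrows(), recordings):
        _, _, obs = preprocess.preprocess_session(
            rec,
            denoise_threshold=config.preprocessing.denoise_threshold,
            downsample_factor=config.preprocessing.downsample_factor,
        )
        obs_store[(mrow["session_id"], mrow["task"], mrow["side"])] = obs

    tf_table = tffeatures.build_tf_feature_table(manifest, recordings)

    training_keys = arhmm.select_training_sessions(manifest)
    training_obs = [obs_store[k] for k in training_keys if k in obs_store]
    stage1 = arhmm.fit_stage1(
        training_obs,
        config.arhmm_hyper,
        n_iter=config.gibbs.stage1_iters,
        burn=config.gibbs.stage1_burn,
        truncate_at=config.gibbs.stage1_truncate_at,
        seed=child_rng(config.seed, STREAM_GIBBS_STAGE1),
    )
    arhmm_table = arhmm.build_arhmm_feature_table(
        manifest,
        obs_store,
        stage1,
        n_iter=config.gibbs.stage2_iters,
        burn=config.gibbs.stage2_burn,
        seed=config.seed,
    )

    labeled = build_labeled_table(manifest, tf_table, arhmm_table)
    reports = evaluate(labeled, config)
    return {
        "profiles": profiles,
        "recordings": recordings,
        "manifest": manifest,
        "obs_store": obs_store,
        "tf_table": tf_table,
        "stage1": stage1,
        "arhmm_table": arhmm_table,
        "labeled_table": labeled,
        "reports": reports,
    }


def build_labeled_table(
    manifest: pd.DataFrame, tf_table: pd.DataFrame, arhmm_table: pd.DataFrame
) -> pd.DataFrame:
    """Join session-level labels/scores with the 192 TF + 162 AR-HMM features."""
    labels = manifest.drop_duplicates("session_id")[modeling.META_COLUMNS]
    out = labels.merge(tf_table, on=["subject_id", "session_id"], validate="1:1")
    out = out.merge(arhmm_table, on=["subject_id", "session_id"], validate="1:1")
    return out.reset_index(drop=True)


def evaluate(labeled: pd.DataFrame, config: PipelineConfig) -> dict:
    """Classification + regression reports per the configured options."""
    m = config.modeling
    seed = int(child_rng(config.seed, STREAM_MODEL).integers(2**31 - 1))
    reports: dict[str, modeling.EvaluationReport] = {}
    present = set(labeled["diagnosis"].unique())
    if set(m.classes) <= present:
        reports["classification"] = modeling.classify_loso(
            labeled, m.classes, m.feature_subset, seed=seed
        )
    for target in m.regression_targets:
        try:
            reports[f"regression_{target}"] = modeling.regress_loso(labeled, target, seed=seed)
        except Exception as exc:  # missing scores in tiny cohorts
            logger.warning("regression on %s skipped: %s", target, exc)
    return reports


# ---------------------------------------------------------------------------
# cached on-disk pipeline

STAGES = ("simulate", "preprocess", "features_tf", "train_arhmm", "features_arhmm", "model")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages into ``out_dir`` with caching and logging.

    A stage is skipped when its hash file matches the hash of its config
    section plus its upstream stage hash and its outputs exist.  Artifacts
    are plain text (CSV/JSON) except the per-recording state-draw arrays,
    which use compressed ``.npz`` containers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    config.to_yaml(out / "config.yaml")
    cfg = config.to_dict()

    def stage(name: str, payload, upstream_hash: str, outputs: list[Path], fn) -> str:
        h = _config_hash([payload, upstream_hash])
        hash_file = out / f"{name}.hash"
        if hash_file.exists() and hash_file.read_text() == h and all(p.exists() for p in outputs):
            logger.info("stage %s: cached, skipping", name)
            return h
        t0 = time.perf_counter()
        fn()
        hash_file.write_text(h)
        logger.info("stage %s: completed in %.1f s", name, time.perf_counter() - t0)
        return h

    try:
        state: dict = {}

        def do_simulate():
            g = config.generator
            _, recordings, manifest = synthetic.generate_cohort(
                g.n_ataxia, g.n_control, g.n_parkinsonism, g.repeat_fraction, seed=config.seed
            )
            manifest = synthetic.write_cohort(recordings, manifest, out / "data")
            write_manifest(manifest, out / "data" / "manifest.csv")

        h = stage(
            "simulate",
            [cfg["generator"], cfg["seed"]],
            "",
            [out / "data" / "manifest.csv"],
            do_simulate,
        )

        manifest = read_manifest(out / "data" / "manifest.csv")

        def load_recordings():
            if "recordings" not in state:
                state["recordings"] = [
                    read_recording(out / "data" / p) for p in manifest["path"]
                ]
            return state["recordings"]

        def do_preprocess():
            obs_dir = out / "obs"
            obs_dir.mkdir(exist_ok=True)
            for (_, mrow), rec in zip(manifest.iterrows(), load_recordings()):
                _, _, obs = preprocess.preprocess_session(
                    rec,
                    denoise_threshold=config.preprocessing.denoise_threshold,
                    downsample_factor=config.preprocessing.downsample_factor,
                )
                t = np.arange(obs.y.shape[0]) / obs.fs_hz
                pd.DataFrame(
                    {"t": t, "acc_pc1": obs.y[:, 0], "gyro_pc1": obs.y[:, 1]}
                ).to_csv(
                    obs_dir / f"{mrow['session_id']}_{mrow['task']}_{mrow['side']}.csv",
                    index=False,
                    float_format="%.9g",
                )

        h = stage("preprocess", cfg["preprocessing"], h, [out / "obs"], do_preprocess)

        def load_obs_store():
            if "obs_store" not in state:
                store = {}
                for _, mrow in manifest.iterrows():
                    key = (mrow["session_id"], mrow["task"], mrow["side"])
                    df = pd.read_csv(out / "obs" / f"{key[0]}_{key[1]}_{key[2]}.csv")
                    store[key] = preprocess.ObservationSequence(
                        df[["acc_pc1", "gyro_pc1"]].to_numpy()
                    )
                state["obs_store"] = store
            return state["obs_store"]

        def do_tf():
            table = tffeatures.build_tf_feature_table(manifest, load_recordings())
            table.to_csv(out / "features_tf.csv", index=False)

        h_tf = stage("features_tf", cfg["sst"], h, [out / "features_tf.csv"], do_tf)

        def do_train():
            keys = arhmm.select_training_sessions(manifest)
            store = load_obs_store()
            stage1 = arhmm.fit_stage1(
                [store[k] for k in keys if k in store],
                config.arhmm_hyper,
                n_iter=config.gibbs.stage1_iters,
                burn=config.gibbs.stage1_burn,
                truncate_at=config.gibbs.stage1_truncate_at,
                seed=child_rng(config.seed, STREAM_GIBBS_STAGE1),
            )
            arhmm.stage1_to_json(stage1, out / "stage1_model.json")

        h = stage(
            "train_arhmm",
            [cfg["arhmm_hyper"], cfg["gibbs"]],
            h,
            [out / "stage1_model.json"],
            do_train,
        )

        def do_arhmm_features():
            stage1 = arhmm.stage1_from_json(out / "stage1_model.json")
            table, inferences = arhmm.build_arhmm_feature_table(
                manifest,
                load_obs_store(),
                stage1,
                n_iter=config.gibbs.stage2_iters,
                burn=config.gibbs.stage2_burn,
                seed=config.seed,
                return_inferences=True,
            )
            table.to_csv(out / "features_arhmm.csv", index=False)
            inf_dir = out / "inferences"
            inf_dir.mkdir(exist_ok=True)
            for (sid, task, side), inf in inferences.items():
                np.savez_compressed(
                    inf_dir / f"{sid}_{task}_{side}.npz",
                    samples=inf.samples.astype(np.int8),
                    modes=inf.modes.astype(np.int8),
                    pi_posterior_mean=inf.pi_posterior_mean,
                )

        h = stage(
            "features_arhmm", cfg["gibbs"], h, [out / "features_arhmm.csv"], do_arhmm_features
        )

        def do_model():
            tf_table = pd.read_csv(
                out / "features_tf.csv", dtype={"subject_id": str, "session_id": str}
            )
            ar_table = pd.read_csv(
                out / "features_arhmm.csv", dtype={"subject_id": str, "session_id": str}
            )
            labeled = build_labeled_table(manifest, tf_table, ar_table)
            labeled.to_csv(out / "features.csv", index=False)
            reports = evaluate(labeled, config)
            payload = {name: rep.to_dict() for name, rep in reports.items()}
            (out / "report.json").write_text(json.dumps(payload, indent=2))
            for name, rep in reports.items():
                if rep.per_session_scores is not None:
                    rep.per_session_scores.to_csv(out / f"scores_{name}.csv", index=False)

        stage(
            "model",
            [cfg["modeling"], h_tf],
            h,
            [out / "report.json"],
            do_model,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
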