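"""End-to-end orchestration: simulate -> preprocess -> featurize -> train
-> evaluate, as composable functions with a frozen, validated run config.

Every stage reads its predecessor's on-disk artifacts (WAV corpus +
manifest, feature store with JSON sidecars, checkpoint directory), so any
stage can be re-run in isolation.  All randomness flows from a single seed.
"""

from __future__ import annotations

import copy
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as F
from . import preprocess as P
from . import synth
from .evaluation import MetricsReport, evaluate_scores
from .model import ModelConfig
from .training import TrainConfig, TrainResult, pool_time, stratified_split, train

FEATURE_TYPES = ("waveform", "mel", "mfcc", "fused", "fused_normalized")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "birdcall_run",
    "simulate": {
        "n_species": 8,
        "clips_per_species": 25,
        "noise_db": -25.0,
        "clip_dur_lo": 6.0,
        "clip_dur_hi": 14.0,
    },
    "preprocess": {
        "hp_cutoff": 150.0,
        # the gate must sit above the corpus noise floor; -30 dB clears the
        # default -25 dB (peak-referenced) synthetic noise
        "gate_db": -30.0,
        "target_s": 10.0,
    },
    "features": {"type": "fused_normalized", "n_mfcc": 20},
    "model": {
        "hidden": 64,
        "n_layers": 2,
        "dropout": 0.3,
        "use_ca": True,
        "bidirectional": False,
        "ca_mid": 8,
        "activation": "silu",
    },
    "train": {
        "epochs": 15,
        "batch_size": 32,
        "learning_rate": 3e-3,
        "lr_decay_factor": 0.1,
        "lr_decay_every": 15,
        "weight_decay": 0.01,
        "loss": "paper_bce",
        "grad_clip": 1.0,
        "time_pool": 8,
        "eval_every": 0,
    },
}


def validate_config(config: dict) -> dict:
    """Merge over defaults; any unknown key is an error before any work."""
    merged = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in config.items():
        if key not in merged:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(merged[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            for sub, sval in val.items():
                if sub not in merged[key]:
                    raise ValueError(f"unknown config key {key}.{sub}")
                merged[key][sub] = sval
        else:
            merged[key] = val
    if merged["features"]["type"] not in FEATURE_TYPES:
        raise ValueError(f"unknown feature type {merged['features']['type']!r}")
    return merged


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def simulate(config: dict, out_dir: str | Path) -> synth.DatasetManifest:
    sim = config["simulate"]
    specs = synth.make_species_specs(sim["n_species"], seed=config["seed"])
    return synth.build_dataset(
        specs, sim["clips_per_species"], out_dir, seed=config["seed"],
        noise_db=sim["noise_db"],
        clip_dur_range=(sim["clip_dur_lo"], sim["clip_dur_hi"]),
    )


def preprocess_manifest(records: pd.DataFrame, out_dir: str | Path,
                        hp_cutoff: float = 150.0, gate_db: float = -40.0,
                        target_s: float = 10.0
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the cleaning chain over a manifest; write accepted WAVs plus a
    rejection log.  Returns (accepted manifest, rejections)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    accepted, rejected = [], []
    for row in records.itertuples(index=False):
        result = P.preprocess_clip(row.wav_path, hp_cutoff=hp_cutoff,
                                   gate_db=gate_db, target_s=target_s)
        if result.accepted:
            dest = out_dir / Path(row.wav_path).name
            synth.write_wav(dest, result.clip.samples)
            accepted.append({"wav_path": str(dest),
                             "species_id": row.species_id,
                             "duration_s": target_s})
        else:
            rejected.append({"wav_path": row.wav_path,
                             "reason": result.reason})
    acc_df = pd.DataFrame(accepted,
                          columns=["wav_path", "species_id", "duration_s"])
    rej_df = pd.DataFrame(rejected, columns=["wav_path", "reason"])
    acc_df.to_csv(out_dir / "manifest.csv", index=False)
    rej_df.to_csv(out_dir / "rejections.csv", index=False)
    return acc_df, rej_df


def clip_features(clip: P.AudioClip, feature_type: str,
                  n_mfcc: int = 20) -> np.ndarray:
    """Feature matrix of the requested type for one standardised clip."""
    if feature_type == "waveform":
        return F.waveform_features(clip)
    spec = F.stft_magnitude(clip)
    mel_db = F.to_decibels(F.mel_spectrogram(spec))
    if feature_type == "mel":
        return mel_db.values
    mf = F.mfcc(mel_db, n_orders=n_mfcc)
    if feature_type == "mfcc":
        return mf.values
    if feature_type == "fused":
        return F.fuse(mel_db, mf, normalize=False).values
    if feature_type == "fused_normalized":
        return F.fuse(mel_db, mf, normalize=True).values
    raise ValueError(f"unknown feature type {feature_type!r}")


def featurize_manifest(records: pd.DataFrame, out_dir: str | Path,
                       feature_type: str = "fused_normalized",
                       n_mfcc: int = 20) -> pd.DataFrame:
    """Store one feature matrix per clip (``.npy`` + JSON sidecar)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for row in records.itertuples(index=False):
        clip = P.read_wav(row.wav_path)
        mat = clip_features(clip, feature_type, n_mfcc=n_mfcc)
        stem = Path(row.wav_path).stem
        np.save(out_dir / f"{stem}.npy", mat.astype(np.float32))
        sidecar = {"rows": int(mat.shape[0]), "cols": int(mat.shape[1]),
                   "feature_type": feature_type,
                   "normalized": feature_type == "fused_normalized",
                   "mel_rows": F.N_MELS if "fused" in feature_type else None,
                   "mfcc_rows": n_mfcc if "fused" in feature_type else None}
        (out_dir / f"{stem}.json").write_text(json.dumps(sidecar))
        rows.append({"feature_path": str(out_dir / f"{stem}.npy"),
                     "species_id": row.species_id})
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "features.csv", index=False)
    return df


def load_feature_arrays(feature_records: pd.DataFrame
                        ) -> tuple[np.ndarray, np.ndarray, list]:
    """Load a feature store into (X, y, label_order)."""
    labels = sorted(feature_records["species_id"].unique())
    lab_to_idx = {lab: i for i, lab in enumerate(labels)}
    X = np.stack([np.load(p) for p in feature_records["feature_path"]])
    y = np.array([lab_to_idx[s] for s in feature_records["species_id"]])
    return X, y, labels


def corpus_feature_arrays(records: pd.DataFrame, feature_type: str,
                          gate_db: float = -30.0, n_mfcc: int = 20
                          ) -> tuple[np.ndarray, np.ndarray, list]:
    """In-memory convenience: preprocess + featurize a WAV manifest."""
    labels = sorted(records["species_id"].unique())
    lab_to_idx = {lab: i for i, lab in enumerate(labels)}
    mats, ys = [], []
    for row in records.itertuples(index=False):
        result = P.preprocess_clip(row.wav_path, gate_db=gate_db)
        if not result.accepted:
            warnings.warn(f"{row.wav_path} rejected: {result.reason}")
            continue
        mats.append(clip_features(result.clip, feature_type, n_mfcc=n_mfcc))
        ys.append(lab_to_idx[row.species_id])
    return np.stack(mats).astype(np.float32), np.array(ys), labels


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _model_config(config: dict, n_features: int, n_species: int
                  ) -> ModelConfig:
    m = config["model"]
    return ModelConfig(n_features=n_features, n_species=n_species,
                       hidden=m["hidden"], n_layers=m["n_layers"],
                       dropout=m["dropout"], use_ca=m["use_ca"],
                       ca_mid=m["ca_mid"], activation=m["activation"],
                       bidirectional=m["bidirectional"],
                       seed=config["seed"])


def _train_config(config: dict) -> TrainConfig:
    t = config["train"]
    return TrainConfig(epochs=t["epochs"], batch_size=t["batch_size"],
                       learning_rate=t["learning_rate"],
                       lr_decay_factor=t["lr_decay_factor"],
                       lr_decay_every=t["lr_decay_every"],
                       weight_decay=t["weight_decay"], loss=t["loss"],
                       grad_clip=t["grad_clip"],
                       seed=config["seed"], time_pool=t["time_pool"],
                       eval_every=t["eval_every"])


def run_all(config: dict) -> Path:
    """Run every stage; returns the run directory containing the corpus,
    cleaned clips, feature store, checkpoint, training log, metrics report
    and the frozen resolved config."""
    config = validate_config(config)
    run_dir = Path(config["out_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(yaml.safe_dump(config))

    manifest = simulate(config, run_dir / "corpus")
    pp = config["preprocess"]
    accepted, _rej = preprocess_manifest(
        manifest.records, run_dir / "clean", hp_cutoff=pp["hp_cutoff"],
        gate_db=pp["gate_db"], target_s=pp["target_s"])
    if accepted.empty:
        raise RuntimeError("preprocessing rejected every clip")
    feat_records = featurize_manifest(
        accepted, run_dir / "features",
        feature_type=config["features"]["type"],
        n_mfcc=config["features"]["n_mfcc"])
    split = stratified_split(feat_records, seed=config["seed"])
    X_tr, y_tr, labels = load_feature_arrays(split.train_records)
    test_labels = {lab: i for i, lab in enumerate(labels)}
    X_te = np.stack([np.load(p) for p in split.test_records["feature_path"]])
    y_te = np.array([test_labels[s] for s in split.test_records["species_id"]])

    mc = _model_config(config, n_features=X_tr.shape[1], n_species=len(labels))
    tc = _train_config(config)
    result: TrainResult = train(X_tr, y_tr, mc, tc)
    result.model.save(run_dir / "checkpoint")
    result.log.to_csv(run_dir / "train_log.csv", index=False)

    scores = result.model.predict_proba(pool_time(X_te, tc.time_pool))
    report = evaluate_scores(scores, y_te)
    report.save(run_dir / "report")
    return run_dir


def feature_comparison(config: dict, feature_types=FEATURE_TYPES,
                       records: pd.DataFrame | None = None) -> pd.DataFrame:
    """Train one model per feature type on the same corpus/split and report
    all seven metrics per type (desk-scale analogue of a feature-ablation
    table)."""
    config = validate_config(config)
    if not feature_types:
        raise ValueError("need at least one feature type")
    for ft in feature_types:
        if ft not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {ft!r}")
    if records is None:
        import tempfile

        with tempfile.TemporaryDirectory() as tmp:
            manifest = simulate(config, tmp)
            return feature_comparison(config, feature_types,
                                      records=manifest.records)
    rows = {}
    for ft in feature_types:
        X, y, labels = corpus_feature_arrays(
            records, ft, gate_db=config["preprocess"]["gate_db"],
            n_mfcc=config["features"]["n_mfcc"])
        df = pd.DataFrame({"species_id": [labels[i] for i in y],
                           "idx": np.arange(len(y))})
        split = stratified_split(df, seed=config["seed"])
        tr, te = split.train_records["idx"].values, split.test_records["idx"].values
        mc = _model_config(config, n_features=X.shape[1],
                           n_species=len(labels))
        tc = _train_config(config)
        result = train(X[tr], y[tr], mc, tc)
        scores = result.model.predict_proba(pool_time(X[te], tc.time_pool))
        rep: MetricsReport = evaluate_scores(scores, y[te])
        rows[ft] = {"accuracy": rep.accuracy, "precision": rep.precision,
                    "recall": rep.recall, "f1": rep.f1, "auc": rep.auc,
                    "top5_accuracy": rep.top5_accuracy, "map": rep.map_score}
    return pd.DataFrame.from_dict(rows, orient="index")
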