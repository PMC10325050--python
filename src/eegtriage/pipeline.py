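"""End-to-end pipeline: simulate -> preprocess -> featurize -> reduce ->
match -> select -> train -> evaluate -> explain.

Every stage reads and writes plain files inside a run directory, so stages
can be re-run individually and a completed run is reproducible from the
resolved configuration and seeds stored beside its outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from . import edf as edfio
from . import features as feats
from .channels import CANONICAL_19
from .preprocess import (
    concatenate_and_segment as _concat_segment,
    preprocess as _preprocess,
    remove_components as _remove_components,
    standardize as _standardize,
)
from .evaluate import evaluate_model, roc_micro_average
from .interpret import grad_cam_temporal
from .nn import BUILDERS, Model, NetworkSpec, TrainConfig, train_network
from .recording import CLASSES, Recording, Segment
from .reduction import embed_and_score, match_cohort, select_most_similar
from .selection import lda_select, relieff_weights, select_top_k
from .synth import CohortSpec, DEFAULT_PROFILES, generate_cohort

logger = logging.getLogger(__name__)


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_per_class: int = 10
    duration_s: float = 600.0
    fs: float = 250.0
    seed: int = 0
    age_mean: float = 42.0
    age_sd: float = 13.0
    sex_ratio_male: float = 0.65


class PreprocessConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    target_fs: float = 250.0
    discard_s: float = 60.0
    segment_s: float = 180.0


class ReduceConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    keep_fraction: float = 0.5
    k_neighbors: int = 50
    per_class: bool = True
    seed: int = 0

    @field_validator("keep_fraction")
    @classmethod
    def _frac(cls, v):
        if not 0.0 < v <= 1.0:
            raise ValueError("keep_fraction must lie in (0, 1]")
        return v


class MatchConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_age_gap: float = 5.0
    with_replacement: bool = True
    seed: int = 0


class SelectConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: Literal["relieff", "lda", "none"] = "relieff"
    top_k: int = 100
    k_neighbors: int = 10
    max_evals: int = 30
    seed: int = 0


class TrainStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    arch: Literal["feature", "tmn", "stft", "lstm", "sfn"] = "feature"
    learning_rate: float = 3e-4
    max_epochs: int = 90
    holdout: float = 0.1
    batch_size: int = 32
    seed: int = 0
    first_n_segments: Optional[int] = None
    split_by: Literal["segment", "recording"] = "segment"


class ExplainConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    smooth_s: float = 1.0
    target_class: str = "TBI"


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    simulate: SimulateConfig = SimulateConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    reduce: ReduceConfig = ReduceConfig()
    match: MatchConfig = MatchConfig()
    select: SelectConfig = SelectConfig()
    train: TrainStageConfig = TrainStageConfig()
    explain: ExplainConfig = ExplainConfig()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(run_dir: Path, cfg: PipelineConfig) -> pd.DataFrame:
    out = run_dir / "edf"
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.simulate
    cohort = generate_cohort(
        CohortSpec(
            n_per_class=sim.n_per_class,
            age_mean=sim.age_mean,
            age_sd=sim.age_sd,
            sex_ratio_male=sim.sex_ratio_male,
            seed=sim.seed,
        ),
        list(DEFAULT_PROFILES.values()),
        duration_s=sim.duration_s,
        fs=sim.fs,
    )
    rows = []
    for rec in cohort:
        path = out / f"{rec.recording_id}.edf"
        edfio.write_recording(path, rec)
        rows.append(
            {
                "recording_id": rec.recording_id,
                "age": rec.demographics.age,
                "sex": rec.demographics.sex,
                "label": rec.label,
                "path": str(path),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(run_dir / "recordings.csv", index=False)
    return manifest


def stage_preprocess(
    run_dir: Path, cfg: PipelineConfig, edf_paths: list[str] | None = None
) -> pd.DataFrame:
    pc = cfg.preprocess
    if edf_paths is None:
        manifest = pd.read_csv(run_dir / "recordings.csv")
        edf_paths = list(manifest["path"])
    seg_dir = run_dir / "segments"
    seg_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for path in edf_paths:
        rec = edfio.read_recording(path)
        rec = _standardize(rec, target_fs=pc.target_fs)
        rec = _preprocess(rec)
        rec = _remove_components(rec, None)
        segments = _concat_segment(
            [rec], discard_s=pc.discard_s, segment_s=pc.segment_s
        )
        for seg in segments:
            npy = seg_dir / f"{seg.recording_id}_{seg.segment_index:03d}.npy"
            np.save(npy, seg.data.astype(np.float32))
            rows.append(
                {
                    "segment_id": seg.segment_id,
                    "recording_id": seg.recording_id,
                    "segment_index": seg.segment_index,
                    "label": seg.label,
                    "age": seg.demographics.age,
                    "sex": seg.demographics.sex,
                    "fs": seg.fs,
                    "path": str(npy),
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(run_dir / "segments.csv", index=False)
    logger.info("preprocess: %d segments", len(manifest))
    return manifest


def _load_segment(row) -> Segment:
    from .recording import Demographics

    return Segment(
        data=np.load(row["path"]).astype(float),
        fs=float(row["fs"]),
        segment_index=int(row["segment_index"]),
        recording_id=row["recording_id"],
        label=row["label"],
        demographics=Demographics(age=row.get("age"), sex=row.get("sex")),
    )


def stage_featurize(run_dir: Path, cfg: PipelineConfig) -> pd.DataFrame:
    manifest = pd.read_csv(run_dir / "segments.csv")
    vecs = []
    for _, row in manifest.iterrows():
        seg = _load_segment(row)
        vecs.append(feats.feature_vector(seg).values)
    X = pd.DataFrame(np.vstack(vecs), columns=list(feats.REGISTRY))
    X.insert(0, "segment_id", manifest["segment_id"].values)
    X.to_csv(run_dir / "features.csv", index=False)
    return X


def stage_reduce(run_dir: Path, cfg: PipelineConfig) -> list[str]:
    rc = cfg.reduce
    manifest = pd.read_csv(run_dir / "segments.csv").set_index("segment_id")
    X = pd.read_csv(run_dir / "features.csv").set_index("segment_id")
    kept: list[str] = []
    groups = (
        manifest.groupby("label").groups.items()
        if rc.per_class
        else [("all", manifest.index)]
    )
    for label, ids in groups:
        ids = [i for i in ids if i in X.index]
        if len(ids) < 10:
            logger.info("reduce: class %s has %d segments (<10); all kept", label,
                        len(ids))
            kept.extend(ids)
            continue
        scores = embed_and_score(
            X.loc[ids].values, segment_ids=list(ids),
            k_neighbors=rc.k_neighbors, seed=rc.seed,
        )
        kept.extend(select_most_similar(scores, rc.keep_fraction))
    pd.DataFrame({"segment_id": kept}).to_csv(run_dir / "kept.csv", index=False)
    return kept


def _recordings_from_manifest(df: pd.DataFrame) -> list[Recording]:
    from .recording import Demographics

    recs = []
    for _, row in df.iterrows():
        recs.append(
            Recording(
                data=np.zeros((len(CANONICAL_19), 1)),  # demographics-only stub
                fs=250.0,
                channel_names=list(CANONICAL_19),
                demographics=Demographics(
                    age=None if pd.isna(row["age"]) else float(row["age"]),
                    sex=None if pd.isna(row["sex"]) else str(row["sex"]),
                ),
                label=row["label"],
                recording_id=row["recording_id"],
            )
        )
    return recs


def stage_match(run_dir: Path, cfg: PipelineConfig) -> pd.DataFrame:
    mc = cfg.match
    segs = pd.read_csv(run_dir / "segments.csv")
    kept = set(pd.read_csv(run_dir / "kept.csv")["segment_id"])
    segs = segs[segs["segment_id"].isin(kept)]
    recs = segs.drop_duplicates("recording_id")[
        ["recording_id", "age", "sex", "label"]
    ]
    by_label = {
        label: _recordings_from_manifest(recs[recs["label"] == label])
        for label in CLASSES
    }
    cohort = match_cohort(
        by_label.get("TBI", []),
        by_label.get("Normal", []),
        by_label.get("Stroke", []),
        max_age_gap=mc.max_age_gap,
        seed=mc.seed,
        with_replacement=mc.with_replacement,
    )
    rows = [
        {
            "anchor_id": t.anchor_id,
            "normal_id": t.normal_id,
            "stroke_id": t.stroke_id,
            "anchor_age": t.anchor_age,
            "anchor_sex": t.anchor_sex,
        }
        for t in cohort.triplets
    ]
    df = pd.DataFrame(rows)
    df.to_csv(run_dir / "cohort.csv", index=False)
    matched_recs = set(df["anchor_id"]) if len(df) else set()
    if len(df):
        matched_recs |= set(df["normal_id"].dropna())
        matched_recs |= set(df["stroke_id"].dropna())
    matched_segments = segs[segs["recording_id"].isin(matched_recs)]
    matched_segments.to_csv(run_dir / "matched_segments.csv", index=False)
    # demographic summary of the matched cohort, one row per class
    summary_rows = []
    matched = recs[recs["recording_id"].isin(matched_recs)]
    for label in CLASSES:
        grp = matched[matched["label"] == label]
        if not len(grp):
            continue
        summary_rows.append(
            {
                "label": label,
                "recordings": len(grp),
                "age_mean": grp["age"].mean(),
                "age_sd": grp["age"].std(),
                "sex_m": int((grp["sex"] == "M").sum()),
                "sex_f": int((grp["sex"] == "F").sum()),
            }
        )
    pd.DataFrame(summary_rows).to_csv(run_dir / "cohort_summary.csv", index=False)
    return df


def _training_table(run_dir: Path, cfg: PipelineConfig) -> pd.DataFrame:
    path = run_dir / "matched_segments.csv"
    segs = pd.read_csv(path if path.exists() else run_dir / "segments.csv")
    if cfg.train.first_n_segments is not None:
        segs = segs[segs["segment_index"] <= cfg.train.first_n_segments]
    return segs


def stage_select(run_dir: Path, cfg: PipelineConfig) -> dict:
    sc = cfg.select
    segs = _training_table(run_dir, cfg)
    X = pd.read_csv(run_dir / "features.csv").set_index("segment_id")
    X = X.loc[[s for s in segs["segment_id"] if s in X.index]]
    y = segs.set_index("segment_id").loc[X.index, "label"].values
    names = list(X.columns)
    if sc.method == "lda":
        result = lda_select(X.values, y, feature_names=names,
                            max_evals=sc.max_evals, seed=sc.seed)
    elif sc.method == "relieff":
        w = relieff_weights(X.values, y, k_neighbors=sc.k_neighbors)
        result = select_top_k(w, feature_names=names, k=min(sc.top_k, len(names)))
    else:
        result = None
    out = (
        {"method": "none", "selected": names}
        if result is None
        else result.to_dict()
    )
    (run_dir / "selection.json").write_text(json.dumps(out, indent=1))
    return out


def stage_train(run_dir: Path, cfg: PipelineConfig):
    tc = cfg.train
    segs = _training_table(run_dir, cfg)
    model_dir = run_dir / "model"
    model_dir.mkdir(exist_ok=True)
    if tc.arch == "feature":
        selection = json.loads((run_dir / "selection.json").read_text())
        cols = selection["selected"]
        X = pd.read_csv(run_dir / "features.csv").set_index("segment_id")
        X = X.loc[[s for s in segs["segment_id"] if s in X.index], cols]
        y = segs.set_index("segment_id").loc[X.index, "label"].values
        spec = BUILDERS["feature"](X.shape[1])
        data = X.values
        standardize = True
    else:
        from .preprocess import downsample_segment

        spec = BUILDERS[tc.arch]()
        rows = list(segs.iterrows())
        data = np.stack(
            [downsample_segment(_load_segment(r), 100.0).data for _, r in rows]
        )
        y = segs["label"].values
        standardize = False
    cfg_train = TrainConfig(
        learning_rate=tc.learning_rate,
        max_epochs=tc.max_epochs,
        holdout=tc.holdout,
        batch_size=tc.batch_size,
        seed=tc.seed,
        standardize=standardize,
    )
    split = None
    if tc.split_by == "recording":
        # hold out whole recordings (per class) so no subject straddles
        # the split
        rng = np.random.default_rng(tc.seed)
        held: set[str] = set()
        by_rec = segs.drop_duplicates("recording_id")
        for label in by_rec["label"].unique():
            ids = by_rec.loc[by_rec["label"] == label, "recording_id"].values
            n_held = max(1, int(round(tc.holdout * len(ids))))
            held |= set(rng.permutation(ids)[:n_held])
        mask = segs["recording_id"].isin(held).values
        split = (np.flatnonzero(~mask), np.flatnonzero(mask))
    trained = train_network(spec, data, y, cfg_train, split=split)
    spec.to_json(model_dir / "spec.json")
    flat = {
        f"{node}::{key}": arr
        for node, p in trained.model.params.items()
        for key, arr in p.items()
    }
    np.savez(model_dir / "params.npz", **flat)
    pd.DataFrame(trained.history).to_csv(model_dir / "history.csv", index=False)
    meta = {"classes": trained.classes, "arch": tc.arch}
    (model_dir / "meta.json").write_text(json.dumps(meta))
    if trained.scaler is not None:
        np.savez(model_dir / "scaler.npz", mean=trained.scaler[0],
                 std=trained.scaler[1])
    # persist the data used, for evaluate/explain
    np.save(model_dir / "train_X.npy", data.astype(np.float32))
    np.save(model_dir / "holdout_idx.npy", trained.idx_holdout)
    pd.DataFrame({"label": y}).to_csv(model_dir / "train_y.csv", index=False)
    return trained


def load_trained(run_dir: Path):
    from .nn.train import TrainedModel

    model_dir = run_dir / "model"
    spec = NetworkSpec.from_json(model_dir / "spec.json")
    model = Model(spec, seed=0)
    flat = np.load(model_dir / "params.npz")
    for key in flat.files:
        node, pkey = key.split("::")
        model.params[node][pkey] = flat[key]
    meta = json.loads((model_dir / "meta.json").read_text())
    scaler = None
    if (model_dir / "scaler.npz").exists():
        sc = np.load(model_dir / "scaler.npz")
        scaler = (sc["mean"], sc["std"])
    return TrainedModel(model=model, classes=meta["classes"], scaler=scaler)


def stage_evaluate(run_dir: Path, cfg: PipelineConfig) -> dict:
    trained = load_trained(run_dir)
    model_dir = run_dir / "model"
    X = np.load(model_dir / "train_X.npy").astype(float)
    y = pd.read_csv(model_dir / "train_y.csv")["label"].values
    # score the stratified holdout recorded at training time
    idx_te = np.load(model_dir / "holdout_idx.npy")
    scores = trained.predict_scores(X[idx_te])
    try:
        metrics = evaluate_model(scores, y[idx_te], trained.classes)
    except ValueError:
        # tiny holdouts can miss a class entirely; keep what is defined
        from .evaluate import roc_one_vs_all

        metrics = {}
        for c in trained.classes:
            try:
                metrics[c] = roc_one_vs_all(scores, y[idx_te], c,
                                            trained.classes).auc
            except ValueError:
                metrics[c] = None
                logger.warning("holdout lacks both classes for %s; "
                               "AUC undefined", c)
        metrics["micro"] = roc_micro_average(scores, y[idx_te],
                                             trained.classes).auc
    (run_dir / "metrics.json").write_text(json.dumps(metrics, indent=1))
    roc = roc_micro_average(scores, y[idx_te], trained.classes)
    pd.DataFrame(
        {"fpr": roc.fpr, "tpr": roc.tpr, "threshold": roc.thresholds}
    ).to_csv(run_dir / "roc_micro.csv", index=False)
    return metrics


def stage_explain(run_dir: Path, cfg: PipelineConfig) -> Path:
    trained = load_trained(run_dir)
    out = run_dir / "explain"
    out.mkdir(exist_ok=True)
    if trained.model.last_conv_node() is None:
        notice = (
            "Grad-CAM requires a convolutional layer; the trained "
            f"architecture has none. Stage recorded as not applicable."
        )
        (out / "notice.txt").write_text(notice)
        logger.info(notice)
        return out
    X = np.load(run_dir / "model" / "train_X.npy").astype(float)
    target = trained.classes.index(cfg.explain.target_class)
    trace = grad_cam_temporal(
        trained.model, X[0], target, fs=100.0, smooth_s=cfg.explain.smooth_s
    )
    pd.DataFrame(
        {
            "time_s": np.arange(trace.importance.size) / trace.fs,
            "score": trace.importance,
        }
    ).to_csv(out / "trace.csv", index=False)
    return out


STAGES = [
    ("simulate", stage_simulate),
    ("preprocess", stage_preprocess),
    ("featurize", stage_featurize),
    ("reduce", stage_reduce),
    ("match", stage_match),
    ("select", stage_select),
    ("train", stage_train),
    ("evaluate", stage_evaluate),
    ("explain", stage_explain),
]


def run_pipeline(config: PipelineConfig | dict, out_dir: str | Path) -> Path:
    """Execute all stages in order; halts with the stage name on failure.

    The resolved configuration is written beside the outputs so a run is
    reproducible from the directory alone.
    """
    if isinstance(config, dict):
        config = PipelineConfig(**config)
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.json").write_text(config.model_dump_json(indent=1))
    for name, fn in STAGES:
        logger.info("stage %s", name)
        try:
            fn(run_dir, config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return run_dir
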