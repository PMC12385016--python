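"""End-to-end orchestration: data -> backbone -> saliency -> radiomics ->
fusion -> reduction/classification -> evaluation -> explanation.

Every stage reads its inputs from, and writes its outputs to, a shared
artifact directory, so running the stages separately composes to the same
result as the one-shot :func:`run`. All randomness derives from the
single config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .backbone import TinyConvNet, TrainingConfig, build_test_backbone, train_backbone
from .errors import ConfigurationError
from .explain import explanation_bundle, tree_shapley
from .fusion import TtaPolicy, fuse
from .imaging import load_from_manifest, load_split, read_manifest, resize, stratified_split
from .radiomics import RadiomicsConfig, feature_names
from .reduce_classify import ClassifierSpec, ReductionSpec, grid_search_cv
from .saliency import compute_saliency, heatmap_to_png, mask_to_rle_csv
from .stats import metrics, paired_t, permutation_test, wilcoxon_signed_rank, mcnemar
from .synthetic import SyntheticConfig, generate_dataset, write_dataset

log = logging.getLogger("gradiomics")

__all__ = ["PipelineConfig", "EvaluationReport", "run"]


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults follow the reference protocol."""

    seed: int = 0
    out_dir: str = "artifacts"
    # data: either a manifest of existing images or synthetic generation
    manifest: str | None = None
    synthetic: dict = field(default_factory=dict)
    image_side: int = 128
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    # backbone
    backbone_channels: tuple[int, int, int] = (8, 16, 32)
    train: dict = field(default_factory=dict)
    ensemble: bool = False
    # saliency / QC
    saliency_threshold: float = 0.5
    saliency_target: str = "predicted"
    # fusion
    tta_count: int = 5
    radiomics: dict = field(default_factory=dict)
    # reduction / classification
    reduction: dict = field(default_factory=lambda: {"kind": "select_k_best", "k": 100})
    classifier: dict = field(default_factory=lambda: {"kind": "random_forest"})
    folds: int = 5
    protocol: str = "cv5"
    # which samples the cv5 protocol cross-validates: "train+val" mirrors the
    # reference protocol (backbone is a fixed extractor); "val+test" keeps the
    # pool disjoint from the backbone's own training images
    cv_pool: str = "train+val"
    n_permutations: int = 0
    explain_n: int = 3

    def __post_init__(self) -> None:
        if self.protocol not in ("cv5", "holdout80_20", "split70_15_15"):
            raise ConfigurationError(f"unknown protocol {self.protocol!r}")
        if self.cv_pool not in ("train+val", "val+test", "all"):
            raise ConfigurationError(f"unknown cv_pool {self.cv_pool!r}")
        if not 0 <= self.saliency_threshold <= 1:
            raise ConfigurationError("saliency_threshold must be in [0, 1]")
        if self.tta_count < 1:
            raise ConfigurationError("tta_count must be >= 1")

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("split_fractions", "backbone_channels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    # -- derived specs -----------------------------------------------------

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(seed=self.seed, **self.synthetic)

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(seed=self.seed, **self.train)

    def radiomics_config(self) -> RadiomicsConfig:
        return RadiomicsConfig(**self.radiomics)

    def reduction_spec(self) -> ReductionSpec:
        return ReductionSpec(**self.reduction)

    def classifier_spec(self) -> ClassifierSpec:
        return ClassifierSpec(seed=self.seed, **self.classifier)


@dataclass
class EvaluationReport:
    """Per-configuration result rows plus significance tests."""

    rows: list[dict]
    tests: list[dict]
    artifact_dir: str

    def to_dict(self) -> dict:
        return {"rows": self.rows, "tests": self.tests, "artifact_dir": self.artifact_dir}

    def save(self, path: str) -> None:
        # paths are excluded so the file depends only on config + seed
        with open(path, "w") as fh:
            json.dump({"rows": self.rows, "tests": self.tests}, fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _timed(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            log.info("stage %-14s %6.1fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _wd(config: PipelineConfig) -> str:
    os.makedirs(config.out_dir, exist_ok=True)
    return config.out_dir


def _manifest_path(config: PipelineConfig) -> str:
    if config.manifest:
        return config.manifest
    return os.path.join(config.out_dir, "data", "manifest.csv")


@_timed("simulate")
def stage_simulate(config: PipelineConfig) -> str:
    """Generate the synthetic dataset (no-op when a manifest is supplied)."""
    wd = _wd(config)
    if config.manifest:
        return config.manifest
    samples = generate_dataset(config.synthetic_config())
    return write_dataset(samples, os.path.join(wd, "data"))


@_timed("split")
def stage_split(config: PipelineConfig) -> str:
    df = read_manifest(_manifest_path(config))
    labels = dict(zip(df["id"], df["label"].astype(int)))
    split = stratified_split(labels, config.split_fractions, seed=config.seed)
    path = os.path.join(_wd(config), "split.csv")
    split.save(path)
    return path


def _load_resized(config: PipelineConfig):
    samples = load_from_manifest(_manifest_path(config))
    return [resize(s, config.image_side) for s in samples]


def _backbone_seeds(config: PipelineConfig) -> list[int]:
    return [config.seed, config.seed + 1] if config.ensemble else [config.seed]


def _backbone_path(config: PipelineConfig, b: int) -> str:
    return os.path.join(config.out_dir, f"backbone_{b}.npz")


@_timed("train-backbone")
def stage_train_backbone(config: PipelineConfig) -> list[str]:
    samples = _load_resized(config)
    split = load_split(os.path.join(config.out_dir, "split.csv"))
    by_part = {p: [s for s in samples if split.assignment[s.id] == p] for p in ("train", "val")}
    x_tr = np.stack([s.pixels for s in by_part["train"]])
    y_tr = np.array([s.label for s in by_part["train"]])
    x_val = np.stack([s.pixels for s in by_part["val"]]) if by_part["val"] else None
    y_val = np.array([s.label for s in by_part["val"]]) if by_part["val"] else None
    paths = []
    for b, bseed in enumerate(_backbone_seeds(config)):
        net = build_test_backbone(seed=bseed, side=config.image_side, conv_channels=config.backbone_channels)
        train_backbone(net, x_tr, y_tr, x_val, y_val, config.training_config())
        path = _backbone_path(config, b)
        net.save(path)
        paths.append(path)
    return paths


@_timed("saliency")
def stage_saliency(config: PipelineConfig) -> str:
    """Grad-CAM masks + QC for every sample and backbone; masks as RLE CSV."""
    samples = _load_resized(config)
    out = os.path.join(config.out_dir, "saliency")
    os.makedirs(out, exist_ok=True)
    rows = []
    for b in range(len(_backbone_seeds(config))):
        net = TinyConvNet.load(_backbone_path(config, b))
        for s in samples:
            res = compute_saliency(net, s, config.saliency_threshold, config.saliency_target)
            mask_to_rle_csv(res.mask, os.path.join(out, f"mask_b{b}_{s.id}.csv"))
            heatmap_to_png(res.heatmap, os.path.join(out, f"heatmap_b{b}_{s.id}.png"))
            rows.append({
                "id": s.id, "backbone": b,
                "area_fraction": res.qc.area_fraction,
                "border_fraction": res.qc.border_fraction,
                "reliable": res.qc.reliable,
            })
    path = os.path.join(out, "qc.csv")
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


@_timed("radiomics")
def stage_radiomics(config: PipelineConfig) -> str:
    """Masked radiomic feature matrix (rows = samples) with QC columns."""
    from .radiomics import extract_all

    samples = _load_resized(config)
    rconf = config.radiomics_config()
    net = TinyConvNet.load(_backbone_path(config, 0))
    rows = []
    for s in samples:
        sal = compute_saliency(net, s, config.saliency_threshold, config.saliency_target)
        vec = extract_all(s, sal, rconf)
        row = {"id": s.id, "label": s.label, "reliable_mask": vec.reliable_mask,
               "area_fraction": sal.qc.area_fraction, "border_fraction": sal.qc.border_fraction}
        row.update(vec.as_dict())
        rows.append(row)
    path = os.path.join(_wd(config), "radiomics.csv")
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


@_timed("fuse")
def stage_fuse(config: PipelineConfig) -> list[str]:
    """Fused feature matrices: identity view and (optionally) TTA-averaged."""
    samples = _load_resized(config)
    split = load_split(os.path.join(config.out_dir, "split.csv"))
    rconf = config.radiomics_config()
    paths = []
    for b in range(len(_backbone_seeds(config))):
        net = TinyConvNet.load(_backbone_path(config, b))
        for tag, count in (("id", 1), ("tta", config.tta_count)):
            if tag == "tta" and config.tta_count <= 1:
                continue
            rows = []
            for s in samples:
                sal = compute_saliency(net, s, config.saliency_threshold, config.saliency_target)
                fv = fuse(s, net, sal, TtaPolicy(count=count), rconf)
                row = {"id": s.id, "label": s.label, "split": split.assignment[s.id],
                       "reliable_mask": fv.radiomics.reliable_mask}
                row.update(dict(zip(fv.names, fv.vector.tolist())))
                rows.append(row)
            path = os.path.join(config.out_dir, f"features_b{b}_{tag}.csv")
            pd.DataFrame(rows).to_csv(path, index=False)
            paths.append(path)
    with open(os.path.join(config.out_dir, "radiomics_settings.json"), "w") as fh:
        json.dump(dataclasses.asdict(rconf), fh, indent=2)
    return paths


def _feature_matrix(config: PipelineConfig, backbone: int, tag: str):
    path = os.path.join(config.out_dir, f"features_b{backbone}_{tag}.csv")
    if tag == "tta" and config.tta_count <= 1:
        path = os.path.join(config.out_dir, f"features_b{backbone}_id.csv")
    df = pd.read_csv(path, dtype={"id": str})
    meta = ["id", "label", "split", "reliable_mask"]
    cols = [c for c in df.columns if c not in meta]
    return df[meta], df[cols].to_numpy(float), tuple(cols)


def _model_rows(config: PipelineConfig):
    """(name, meta, X_id, X_tta, names) per classified feature block."""
    blocks = []
    n_backbones = len(_backbone_seeds(config))
    loaded = []
    for b in range(n_backbones):
        meta, x_id, names = _feature_matrix(config, b, "id")
        _, x_tta, _ = _feature_matrix(config, b, "tta")
        loaded.append((meta, x_id, x_tta, names))
        blocks.append((f"backbone_{b}", meta, x_id, x_tta, names))
    if n_backbones == 2:
        (meta, a_id, a_tta, a_names), (_, b_id, b_tta, b_names) = loaded
        blocks.append((
            "ensemble",
            meta,
            np.hstack([a_id, b_id]),
            np.hstack([a_tta, b_tta]),
            tuple(f"b0_{n}" for n in a_names) + tuple(f"b1_{n}" for n in b_names),
        ))
    return blocks


@_timed("classify")
def stage_classify_evaluate(config: PipelineConfig) -> EvaluationReport:
    """Protocol evaluation (cv5 / holdout80_20 / split70_15_15) + significance."""
    rows, tests = [], []
    cspec, rspec = config.classifier_spec(), config.reduction_spec()
    final_pipeline = None
    for name, meta, x_id, x_tta, names in _model_rows(config):
        y = meta["label"].to_numpy(int)
        split = meta["split"].to_numpy(str)
        if config.protocol == "cv5":
            if config.cv_pool == "train+val":
                pool = split != "test"
            elif config.cv_pool == "val+test":
                pool = split != "train"
            else:
                pool = np.ones(len(split), dtype=bool)
            base_cv, _ = grid_search_cv(
                x_id[pool], y[pool], cspec, rspec, config.folds, config.seed, feature_names=names
            )
            tta_cv, pipe = grid_search_cv(
                x_id[pool], y[pool], cspec, rspec, config.folds, config.seed,
                X_eval=x_tta[pool], feature_names=names,
            )
            rows.append(_cv_row(name, "cv5", base_cv, tta=False))
            rows.append(_cv_row(name, "cv5+tta", tta_cv, tta=True))
            t = paired_t(tta_cv.fold_scores(), base_cv.fold_scores())
            w = wilcoxon_signed_rank(tta_cv.fold_scores(), base_cv.fold_scores())
            tests.append({"model": name, "comparison": "tta_vs_baseline", **t.to_dict()})
            tests.append({"model": name, "comparison": "tta_vs_baseline", **w.to_dict()})
            if config.n_permutations > 0:
                perm = permutation_test(
                    lambda yy: grid_search_cv(
                        x_id[pool], yy, cspec, rspec, config.folds, config.seed,
                        feature_names=names,
                    )[0].mean("accuracy"),
                    y[pool], base_cv.fold_assignment,
                    n_perm=config.n_permutations, seed=config.seed,
                )
                tests.append({"model": name, "comparison": "permutation", **perm.to_dict()})
        elif config.protocol == "holdout80_20":
            hold = stratified_split(
                dict(zip(meta["id"], y)), (0.80, 0.0, 0.20), seed=config.seed
            )
            idx = {i: k for k, i in enumerate(meta["id"])}
            tr = np.array([hold.assignment[i] == "train" for i in meta["id"]])
            te = ~tr
            _, pipe = grid_search_cv(x_id[tr], y[tr], cspec, rspec, config.folds, config.seed, feature_names=names)
            prob_base = pipe.predict_proba(x_id[te])
            prob_tta = pipe.predict_proba(x_tta[te])
            m_base = metrics(y[te], (prob_base >= 0.5).astype(int), prob_base)
            m_tta = metrics(y[te], (prob_tta >= 0.5).astype(int), prob_tta)
            rows.append({"model": name, "protocol": "holdout80_20", "tta": False, **m_base.to_dict()})
            rows.append({"model": name, "protocol": "holdout80_20", "tta": True, **m_tta.to_dict()})
            mc = mcnemar((prob_base >= 0.5).astype(int), (prob_tta >= 0.5).astype(int), y[te])
            tests.append({"model": name, "comparison": "mcnemar_tta_vs_baseline", **mc.to_dict()})
        else:  # split70_15_15
            tr = split == "train"
            te = split == "test"
            _, pipe = grid_search_cv(x_id[tr], y[tr], cspec, rspec, config.folds, config.seed, feature_names=names)
            prob = pipe.predict_proba(x_tta[te])
            m = metrics(y[te], (prob >= 0.5).astype(int), prob)
            rows.append({"model": name, "protocol": "split70_15_15", "tta": config.tta_count > 1, **m.to_dict()})
        final_pipeline = pipe
        _save_pipeline(config, name, pipe)
    report = EvaluationReport(rows=rows, tests=tests, artifact_dir=config.out_dir)
    report.save(os.path.join(config.out_dir, "metrics.json"))
    _ = final_pipeline
    return report


def _cv_row(name: str, protocol: str, cv, tta: bool) -> dict:
    return {
        "model": name, "protocol": protocol, "tta": tta,
        "mean_accuracy": cv.mean("accuracy"), "sd_accuracy": cv.sd("accuracy"),
        "mean_auc": cv.mean("auc"), "sd_auc": cv.sd("auc"),
        "best_params": cv.best_params,
    }


def _save_pipeline(config: PipelineConfig, name: str, pipe) -> None:
    import joblib

    path = os.path.join(config.out_dir, f"pipeline_{name}.joblib")
    joblib.dump(pipe, path)
    manifest = {
        "package_version": __version__,
        "model": name,
        "reduction": dataclasses.asdict(pipe.reduction_spec),
        "classifier_kind": pipe.classifier_spec.kind,
        "params": pipe.params,
        "feature_census": len(feature_names()),
        "seed": config.seed,
    }
    with open(path + ".manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


@_timed("explain")
def stage_explain(config: PipelineConfig) -> str:
    """Shapley attributions + per-sample bundles for the last model block."""
    import joblib

    blocks = _model_rows(config)
    name, meta, x_id, x_tta, names = blocks[-1]
    pipe = joblib.load(os.path.join(config.out_dir, f"pipeline_{name}.joblib"))
    n = min(config.explain_n, len(meta))
    attr = tree_shapley(pipe, x_tta[:n])
    attr.check_local_accuracy()
    attr.to_frame().assign(id=meta["id"][:n].to_numpy()).to_csv(
        os.path.join(config.out_dir, "attributions.csv"), index=False
    )
    samples = {s.id: s for s in _load_resized(config)}
    net = TinyConvNet.load(_backbone_path(config, len(_backbone_seeds(config)) - 1))
    bundles = []
    probs = pipe.predict_proba(x_tta[:n])
    for k in range(n):
        sid = meta["id"].iloc[k]
        sal = compute_saliency(net, samples[sid], config.saliency_threshold, config.saliency_target)
        bundles.append(explanation_bundle(
            sid, sal, float(probs[k]), attr, k,
            heatmap_ref=os.path.join("saliency", f"heatmap_b0_{sid}.png"),
        ))
    path = os.path.join(config.out_dir, "bundles.json")
    with open(path, "w") as fh:
        json.dump(bundles, fh, indent=2)
    return path


@_timed("report")
def stage_report(config: PipelineConfig) -> str:
    """Provenance manifest: config echo + hash, library versions, seed."""
    import sklearn
    import xgboost

    cfg = config.to_dict()
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "versions": {
            "gradiomics": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "xgboost": xgboost.__version__,
        },
    }
    path = os.path.join(config.out_dir, "provenance.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path


def run(config: PipelineConfig) -> EvaluationReport:
    """One-shot pipeline; composes the stages over the artifact directory."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    log.info("run seed=%d protocol=%s out=%s", config.seed, config.protocol, config.out_dir)
    stage_simulate(config)
    stage_split(config)
    stage_train_backbone(config)
    stage_saliency(config)
    stage_fuse(config)
    report = stage_classify_evaluate(config)
    stage_explain(config)
    stage_report(config)
    return report
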