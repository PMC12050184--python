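"""End-to-end pipeline: register -> correspond -> SSM -> features -> CV.

One declarative :class:`PipelineConfig` carries every stage's parameters;
all randomness flows from its single root seed.  The first subject in the
dataset acts as the reference for registration and correspondence (after
voxel downsampling and normal estimation), so the reference's point count
fixes the shape-vector dimension 3M.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import correspondence, evaluation, nn, registration, ssm
from .errors import RadshapeError, ValidationError
from .io import DatasetManifest, PointCloud, read_point_cloud

log = logging.getLogger("radshape")


class IcpSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    convergence_tol: float = 1e-6
    max_iters: int = 100
    reject_dist: float = 2.5
    rmse_gate: float = 0.5


class TrainSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    learning_rate: float = 0.01
    max_epochs: int = 2000
    batch_size: int = 1
    tol: float = 1e-6
    loss_kind: str = "bce"


class PipelineConfig(BaseModel):
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    voxel: float = 1.0
    normals_k: int = 20
    allow_mirror: bool = True
    icp: IcpSettings = Field(default_factory=IcpSettings)
    unique_correspondence: bool = False
    alpha: float = 0.75
    feature_counts: list[int] = Field(default_factory=lambda: [5, 10, 15])
    k_folds: int = 4
    hidden_size: int = 10
    train: TrainSettings = Field(default_factory=TrainSettings)
    leaky_thresholds: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def icp_params(self) -> registration.IcpParams:
        return registration.IcpParams(**self.icp.model_dump())

    def train_config(self) -> nn.TrainConfig:
        return nn.TrainConfig(seed=self.seed, **self.train.model_dump())


class PipelineResult:
    def __init__(self, model, features, labels, reports, table2,
                 registration_reports, correspondence_summaries):
        self.model = model                      # pooled ShapeModel
        self.features = features                # (N, t) standardized b_k
        self.labels = labels
        self.reports = reports                  # {F: CrossValReport}
        self.table2 = table2                    # per-group cumulative %
        self.registration_reports = registration_reports
        self.correspondence_summaries = correspondence_summaries


def correspond_cohort(clouds: Sequence[PointCloud], config: PipelineConfig,
                      reference_index: int = 0):
    """Register and correspond every cloud to the reference subject.

    Returns ``(ordered clouds, registration reports, correspondence
    summaries, reference cloud)``.
    """
    if not clouds:
        raise ValidationError("no clouds to process")
    ref = clouds[reference_index]
    if config.voxel > 0:
        ref = registration.voxel_downsample(ref, config.voxel)
    ref = registration.estimate_normals(ref, k=config.normals_k)
    params = config.icp_params()
    ordered, reg_reports, corr_summaries = [], [], []
    for i, cloud in enumerate(clouds):
        sid = cloud.subject_id or str(i)
        if i == reference_index:
            out = ref.with_points(ref.points, None)
            reg_reports.append(registration.RegistrationReport(
                iterations=0, final_rmse=0.0, rejected_fraction=0.0,
                converged=True, passed_gate=True))
            corr_summaries.append({"mean": 0.0, "max": 0.0,
                                   "flagged_fraction": 0.0})
            ordered.append(out)
            continue
        work = cloud
        if config.voxel > 0:
            work = registration.voxel_downsample(work, config.voxel)
        try:
            registered, _, report = registration.register_pair(
                work, ref, params, allow_mirror=config.allow_mirror)
        except RadshapeError as exc:
            raise RadshapeError(
                f"registration failed for subject {sid!r}: {exc}") from exc
        if not report.passed_gate:
            log.warning("subject %s: RMSE %.3f mm exceeds the %.2f mm gate",
                        sid, report.final_rmse, params.rmse_gate)
        out, cmap = correspondence.reorder_to_reference(
            ref, registered, unique=config.unique_correspondence)
        reg_reports.append(report)
        corr_summaries.append(correspondence.correspondence_errors(
            cmap, threshold=params.reject_dist))
        ordered.append(out)
    return ordered, reg_reports, corr_summaries, ref


def run_cohort(clouds: Sequence[PointCloud], labels: Sequence[str],
               config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Run the full pipeline on in-memory clouds + labels."""
    config = config or PipelineConfig()
    labels = list(labels)
    if len(labels) != len(clouds):
        raise ValidationError("labels/clouds length mismatch")
    ordered, reg_reports, corr_summaries, _ = correspond_cohort(clouds, config)
    dataset = ssm.build_shape_matrix(ordered, labels=labels)
    model = ssm.fit_ssm(dataset, alpha=config.alpha)
    t = max(config.feature_counts)
    if t > model.rank:
        raise ValidationError(
            f"requested {t} features but the model rank is only {model.rank}")
    raw = np.stack([ssm.project(model, s, t=t).b for s in dataset.shapes])
    features = raw / np.sqrt(model.eigenvalues[:t])    # per-mode sigma units
    table2 = ssm.groupwise_contribution_table(
        dataset, feature_counts=tuple(config.feature_counts),
        alpha=config.alpha)
    reports = evaluation.cross_validate(
        features, labels, feature_counts=config.feature_counts,
        k=config.k_folds, seed=config.seed,
        train_config=config.train_config(), hidden_size=config.hidden_size,
        leaky_thresholds=config.leaky_thresholds)
    return PipelineResult(model, features, labels, reports, table2,
                          reg_reports, corr_summaries)


def run_manifest(manifest: DatasetManifest | str, config: PipelineConfig,
                 base_dir: Optional[Path] = None) -> PipelineResult:
    """Load clouds listed in a manifest and run the pipeline."""
    if not isinstance(manifest, DatasetManifest):
        base_dir = base_dir or Path(manifest).parent
        manifest = DatasetManifest.read(manifest)
    base_dir = Path(base_dir) if base_dir else Path(".")
    clouds, labels = [], []
    for entry in manifest.entries:
        path = base_dir / entry.cloud_path
        try:
            clouds.append(read_point_cloud(path))
        except RadshapeError as exc:
            raise RadshapeError(f"cannot read {path}: {exc}") from exc
        labels.append(entry.label)
    return run_cohort(clouds, labels, config)


def write_report(result: PipelineResult, outdir) -> Path:
    """Write the cumulative-variance, AUC, threshold, accuracy CSVs and the
    per-fold confusion matrices (JSON).  Output bytes are deterministic."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.table2.to_csv(outdir / "cumulative_variance.csv",
                         index_label="group", float_format="%.6f")
    auc_all = pd.concat({f"F={f}": r.auc for f, r in result.reports.items()},
                        names=["features", "fold"])
    auc_all.to_csv(outdir / "auc.csv", float_format="%.6f")
    thr_all = pd.concat({f"F={f}": r.thresholds
                         for f, r in result.reports.items()},
                        names=["features", "fold"])
    thr_all.to_csv(outdir / "thresholds.csv", float_format="%.6f")
    acc = pd.DataFrame(
        {f"F={f}": r.accuracies + [r.mean_accuracy]
         for f, r in result.reports.items()},
        index=[f"k_{i + 1}" for i in
               range(len(next(iter(result.reports.values())).accuracies))]
        + ["Mean"]).T
    acc.to_csv(outdir / "accuracy.csv", float_format="%.6f")
    for f, rep in result.reports.items():
        payload = {"feature_count": f, "classes": list(rep.classes),
                   "confusion_matrices": [m.tolist() for m in rep.confusions],
                   "accuracies": rep.accuracies}
        (outdir / f"confusion_F{f}.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True))
    return outdir
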