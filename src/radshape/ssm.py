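"""Statistical shape model (point distribution model).

Each corresponded cloud is flattened to a 3M-vector
(x1, y1, z1, ..., xM, yM, zM).  The model is the sample mean plus the
eigenpairs of the 1/(N-1) covariance; eigenpairs are computed from the
singular decomposition of the centered data matrix, which is numerically
identical to eigendecomposing the covariance but never forms the 3M x 3M
matrix.  A shape is synthesized as

    T ~= T_bar + sum_k b_k phi_k,

with the usual three-sigma plausibility bound |b_k| <= c * sqrt(lambda_k).
The eigenvalues are variances, so the bound is expressed in standard
deviation units; |c| <= 3 by default.

Eigenvector sign convention: the largest-magnitude entry of each mode is
positive, which makes models reproducible across linear-algebra backends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .io import PointCloud

_RANK_RTOL = 1e-10   # relative eigenvalue cutoff for numerical rank


@dataclass
class ShapeDataset:
    """N flattened shape vectors of length 3M with optional group labels."""

    shapes: np.ndarray
    subject_ids: Optional[Sequence[str]] = None
    labels: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.shapes = np.asarray(self.shapes, dtype=np.float64)
        if self.shapes.ndim != 2:
            raise ValidationError("shapes must be a 2-D (N, 3M) array")
        if self.shapes.shape[1] % 3 != 0:
            raise ValidationError("shape vectors must have length 3M")
        for name in ("subject_ids", "labels"):
            v = getattr(self, name)
            if v is not None and len(v) != len(self.shapes):
                raise ValidationError(f"{name} length != N")

    @property
    def n_subjects(self) -> int:
        return self.shapes.shape[0]

    @property
    def n_points(self) -> int:
        return self.shapes.shape[1] // 3

    def subset(self, mask) -> "ShapeDataset":
        mask = np.asarray(mask)
        return ShapeDataset(
            self.shapes[mask],
            None if self.subject_ids is None else
            [s for s, m in zip(self.subject_ids, mask) if m],
            None if self.labels is None else
            [l for l, m in zip(self.labels, mask) if m])


@dataclass
class ShapeModel:
    mean_shape: np.ndarray
    eigenvalues: np.ndarray        # descending, > 0, length r
    eigenvectors: np.ndarray       # (3M, r) orthonormal columns
    total_variance: float
    alpha: float = 0.75
    t: int = 0

    def __post_init__(self):
        self.mean_shape = np.asarray(self.mean_shape, dtype=np.float64)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=np.float64)
        if np.any(np.diff(self.eigenvalues) > 0):
            raise ValidationError("eigenvalues must be sorted descending")
        if np.any(self.eigenvalues < 0):
            raise ValidationError("eigenvalues must be non-negative")
        r = len(self.eigenvalues)
        if self.eigenvectors.shape != (len(self.mean_shape), r):
            raise ValidationError("eigenvector matrix must be (3M, r)")
        if r:
            gram = self.eigenvectors.T @ self.eigenvectors
            if not np.allclose(gram, np.eye(r), atol=1e-8):
                raise ValidationError("eigenvectors must be orthonormal (1e-8)")

    @property
    def rank(self) -> int:
        return len(self.eigenvalues)


@dataclass
class ShapeCoefficients:
    """Mode coefficients b with the plausibility bound multiplier c."""

    b: np.ndarray
    c_limit: float = 3.0

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=np.float64).reshape(-1)
        if self.c_limit <= 0:
            raise ValidationError("c_limit must be positive")


def build_shape_matrix(clouds: Sequence[PointCloud],
                       labels: Optional[Sequence[str]] = None) -> ShapeDataset:
    """Flatten corresponded clouds into the (N, 3M) shape matrix."""
    if not clouds:
        raise ValidationError("no clouds given")
    m = len(clouds[0])
    bad = [c.subject_id or str(i) for i, c in enumerate(clouds) if len(c) != m]
    if bad:
        raise ValidationError(
            "clouds are not corresponded — point counts differ for subjects: "
            + ", ".join(bad))
    shapes = np.stack([c.points.reshape(-1) for c in clouds])
    ids = [c.subject_id or str(i) for i, c in enumerate(clouds)]
    return ShapeDataset(shapes=shapes, subject_ids=ids, labels=labels)


def fit_ssm(dataset: ShapeDataset, alpha: float = 0.75) -> ShapeModel:
    """Fit the PCA shape model.

    ``alpha`` is the retained-variance target: ``t`` is the smallest mode
    count whose cumulative contribution exceeds ``alpha`` (clipped to the
    numerical rank).  Covariance uses the unbiased 1/(N-1) normalisation.
    """
    if not 0 < alpha <= 1:
        raise ValidationError("alpha must be in (0, 1]")
    n = dataset.n_subjects
    if n < 2:
        raise ValidationError(f"model fitting needs N >= 2 subjects, got {n}")
    x = dataset.shapes
    mean = x.mean(axis=0)
    xc = x - mean
    # economy SVD of the centered data == eigendecomposition of S
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = s ** 2 / (n - 1)
    total = float(eigenvalues.sum())
    keep = eigenvalues > _RANK_RTOL * max(eigenvalues[0], 1e-300)
    if total == 0.0 or not np.any(keep):
        return ShapeModel(mean_shape=mean, eigenvalues=np.empty(0),
                          eigenvectors=np.empty((x.shape[1], 0)),
                          total_variance=0.0, alpha=alpha, t=0)
    eigenvalues = eigenvalues[keep]
    vecs = vt[keep].T
    # sign convention: largest-|entry| component positive
    lead = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[lead, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    vecs = vecs * signs
    cum = np.cumsum(eigenvalues) / total
    above = np.nonzero(cum > alpha)[0]
    t = int(above[0] + 1) if len(above) else len(eigenvalues)
    return ShapeModel(mean_shape=mean, eigenvalues=eigenvalues,
                      eigenvectors=vecs, total_variance=total,
                      alpha=alpha, t=t)


def cumulative_contribution(model: ShapeModel, t: int) -> float:
    """Fraction of total variance captured by the first ``t`` modes."""
    if t < 0:
        raise ValidationError("t must be non-negative")
    if model.total_variance == 0.0:
        raise ValidationError("zero-variance model has no defined contribution")
    if t >= model.rank:
        return 1.0
    return float(model.eigenvalues[:t].sum() / model.total_variance)


def synthesize_shape(model: ShapeModel, coeffs: ShapeCoefficients,
                     enforce_bounds: bool = True) -> np.ndarray:
    """T_bar + sum b_k phi_k; out-of-bound coefficients raise, never clamp."""
    b = coeffs.b
    if len(b) > model.rank:
        raise ValidationError(
            f"{len(b)} coefficients exceed model rank {model.rank}")
    if enforce_bounds and len(b):
        limit = coeffs.c_limit * np.sqrt(model.eigenvalues[:len(b)])
        bad = np.nonzero(np.abs(b) > limit)[0]
        if len(bad):
            raise ValidationError(
                "coefficients outside the plausible range |b_k| <= "
                f"{coeffs.c_limit}*sqrt(lambda_k) at modes {bad.tolist()}")
    return model.mean_shape + model.eigenvectors[:, :len(b)] @ b


def project(model: ShapeModel, shape: np.ndarray, t: Optional[int] = None
            ) -> ShapeCoefficients:
    """b_k = phi_k . (shape - mean) for the first ``t`` modes."""
    shape = np.asarray(shape, dtype=np.float64).reshape(-1)
    if shape.shape != model.mean_shape.shape:
        raise ValidationError("shape vector length != 3M")
    if t is None:
        t = model.t
    if t > model.rank:
        raise ValidationError(f"t ({t}) exceeds model rank {model.rank}")
    b = model.eigenvectors[:, :t].T @ (shape - model.mean_shape)
    return ShapeCoefficients(b=b)


def groupwise_contribution_table(dataset: ShapeDataset,
                                 feature_counts=(5, 10, 15),
                                 alpha: float = 0.75):
    """Per-group cumulative variance contribution (%) at each feature count.

    Groups with fewer than 2 subjects are skipped.  Returns a pandas
    DataFrame (rows = groups, columns = 'F=...').
    """
    import pandas as pd

    if dataset.labels is None:
        raise ValidationError("dataset has no group labels")
    labels = np.asarray(dataset.labels)
    rows = {}
    for g in dict.fromkeys(dataset.labels):   # preserve first-seen order
        sub = dataset.subset(labels == g)
        if sub.n_subjects < 2:
            continue
        model = fit_ssm(sub, alpha=alpha)
        rows[g] = [100.0 * cumulative_contribution(model, f)
                   for f in feature_counts]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"F={f}" for f in feature_counts])
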