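"""Point correspondence by nearest Euclidean distance.

After rigid registration every cloud lives in the reference frame but its
points are still in arbitrary order.  ``reorder_to_reference`` rewrites a
source cloud so that output point j is the source point nearest to
reference point j — the classic nearest-neighbour correspondence rule.
A k-d tree accelerates the search but ties are resolved exactly as an
exhaustive scan would (lowest source index wins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .io import PointCloud


@dataclass
class CorrespondenceMap:
    """indices[j] = source index matched to reference point j (0-based)."""

    indices: np.ndarray
    distances: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if self.indices.shape != self.distances.shape or self.indices.ndim != 1:
            raise ValidationError("indices/distances must be matching 1-D arrays")
        if np.any(self.distances < 0):
            raise ValidationError("distances must be non-negative")


def reorder_to_reference(reference: PointCloud, source: PointCloud,
                         unique: bool = False):
    """Match every reference point to its nearest source point.

    With ``unique=True`` the matching is greedy one-to-one: reference points
    are processed in ascending order of their best distance and each source
    point is used at most once (requires source M >= reference M).

    Returns ``(reordered_cloud, CorrespondenceMap)``.
    """
    ref = reference.points
    src = source.points
    if len(src) == 0:
        raise ValidationError("source cloud is empty")
    tree = cKDTree(src)
    if not unique:
        d, idx = tree.query(ref, k=min(2, len(src)))
        if d.ndim == 1:
            d, idx = d[:, None], idx[:, None]
        best_d, best_i = d[:, 0].copy(), idx[:, 0].copy()
        # exact tie handling: a k-d tree does not promise lowest-index ties
        if d.shape[1] > 1:
            close = d[:, 1] - d[:, 0] <= 1e-12 * (1.0 + d[:, 0])
            for j in np.nonzero(close)[0]:
                all_d = np.linalg.norm(src - ref[j], axis=1)
                best_i[j] = int(np.argmin(all_d))   # argmin -> lowest index
                best_d[j] = all_d[best_i[j]]
        indices, distances = best_i, best_d
    else:
        if len(src) < len(ref):
            raise ValidationError(
                "unique matching needs at least as many source as reference "
                f"points ({len(src)} < {len(ref)})")
        d0, _ = tree.query(ref)
        order = np.argsort(d0, kind="stable")
        used = np.zeros(len(src), dtype=bool)
        indices = np.full(len(ref), -1, dtype=np.int64)
        distances = np.zeros(len(ref))
        for j in order:
            k = min(64, len(src))
            while True:
                dd, ii = tree.query(ref[j], k=k)
                dd, ii = np.atleast_1d(dd), np.atleast_1d(ii)
                free = ~used[ii]
                if np.any(free):
                    pick = int(ii[free][0])
                    break
                if k >= len(src):
                    raise ValidationError("unique matching exhausted source")
                k = min(k * 4, len(src))
            indices[j] = pick
            distances[j] = float(np.linalg.norm(src[pick] - ref[j]))
            used[pick] = True
    normals = None if source.normals is None else source.normals[indices]
    out = source.with_points(src[indices], normals)
    return out, CorrespondenceMap(indices=indices, distances=distances)


def correspondence_errors(cmap: CorrespondenceMap, threshold: float = 2.5):
    """Summary of match distances: mean, max, and fraction above ``threshold``
    (default reuses the 2.5 mm ICP rejection distance)."""
    d = cmap.distances
    if len(d) == 0:
        raise ValidationError("empty correspondence map")
    return {"mean": float(d.mean()), "max": float(d.max()),
            "flagged_fraction": float(np.mean(d > threshold))}
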