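"""Areal-border methods: AUC-threshold contours and surface gradients.

Two complementary ways to turn a continuous myelin-sensitive surface map
into candidate areal borders: (i) thresholding at a percentage of the area
under the global value histogram between the 3rd and 97th percentiles, with
contours along mask boundaries and coverage/overlap quantification; and
(ii) per-vertex tangent-plane gradient magnitudes, whose ridges track sharp
myeloarchitectonic transitions.  Neither method is made observer-free here:
threshold choice and gradient-ridge linking remain explicit user decisions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyRegionError, InvalidArgumentError
from .mesh import SurfaceMesh

__all__ = ["BinaryParcellation", "auc_threshold", "coverage_profile",
           "binarize_and_contour", "jaccard", "surface_gradient",
           "gradient_borders"]


@dataclass
class BinaryParcellation:
    """Boolean vertex mask plus its provenance (parameter, threshold pct)."""

    mask: np.ndarray
    source: tuple = ("", float("nan"))


def auc_threshold(values: np.ndarray, pct: float) -> float:
    """Value at ``pct`` % of the histogram area between the 3rd and 97th
    percentiles — i.e. the pct-quantile of the distribution truncated to
    [p3, p97].  NaN values are ignored."""
    if not 0 <= pct <= 100:
        raise InvalidArgumentError("pct must lie in [0, 100]")
    values = np.asarray(values, dtype=float)
    vals = values[np.isfinite(values)]
    if len(vals) < 2 or np.ptp(vals) == 0:
        raise InvalidArgumentError("non-degenerate distribution required")
    p3, p97 = np.percentile(vals, [3, 97])
    trunc = vals[(vals >= p3) & (vals <= p97)]
    return float(np.quantile(trunc, pct / 100.0))


def coverage_profile(values: np.ndarray, atlas, roi: int,
                     pcts) -> np.ndarray:
    """Percentage of included ROI vertices at or above each AUC threshold.

    Thresholds come from the global (whole-map) distribution; maps should be
    oriented so that values increase with myelination before calling this.
    """
    values = np.asarray(values, dtype=float)
    idx = atlas.vertices_of(roi)
    roi_vals = values[idx]
    roi_vals = roi_vals[np.isfinite(roi_vals)]
    if len(roi_vals) == 0:
        raise EmptyRegionError(f"ROI {roi} empty after exclusion")
    out = np.empty(len(list(pcts)))
    for k, pct in enumerate(pcts):
        thr = auc_threshold(values, pct)
        out[k] = 100.0 * np.mean(roi_vals >= thr)
    return out


def binarize_and_contour(mesh: SurfaceMesh, values: np.ndarray,
                         threshold: float) -> tuple:
    """Threshold a map and trace the mask boundary.

    Returns ``(BinaryParcellation, contour_edges)`` where the contour is the
    (e, 2) array of mesh edges whose endpoints straddle the mask.  Excluded
    (NaN) vertices are false.  On a closed mesh every triangle contains 0 or
    2 straddling edges, so contour edges chain into closed loops.
    """
    values = np.asarray(values, dtype=float)
    mask = np.isfinite(values) & (values >= threshold)
    edges = mesh.edges()
    straddle = mask[edges[:, 0]] != mask[edges[:, 1]]
    return BinaryParcellation(mask, ("", threshold)), edges[straddle]


def jaccard(a, b) -> float:
    """Overlap |A∩B| / |A∪B| of two binary vertex masks.

    Two empty masks are defined as perfectly overlapping (1.0).
    """
    ma = a.mask if isinstance(a, BinaryParcellation) else np.asarray(a, bool)
    mb = b.mask if isinstance(b, BinaryParcellation) else np.asarray(b, bool)
    if ma.shape != mb.shape:
        raise InvalidArgumentError("masks are defined on different vertex sets")
    union = np.count_nonzero(ma | mb)
    if union == 0:
        return 1.0
    return float(np.count_nonzero(ma & mb) / union)


def surface_gradient(mesh: SurfaceMesh, values: np.ndarray,
                     normal_weighting: str = "area") -> np.ndarray:
    """Per-vertex tangent-plane gradient magnitude (value units per mm).

    At each vertex the one-ring neighborhood is projected onto the tangent
    plane (normal from area- or angle-weighted incident triangle normals)
    and a least-squares plane ``value ~ a + g . (u, v)`` is fitted through
    the vertex and its neighbors; the magnitude ``||g||`` is returned.
    Exact for linear fields on planar meshes.  Vertices with fewer than 3
    usable neighbors, or with collinear projected neighbors, are NaN.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != mesh.n_vertices:
        raise InvalidArgumentError("map length does not match vertex count")
    if normal_weighting == "area":
        normals = mesh.vertex_normals()
    elif normal_weighting == "angle":
        normals = _angle_weighted_normals(mesh)
    else:
        raise InvalidArgumentError(f"unknown normal weighting {normal_weighting!r}")

    out = np.full(mesh.n_vertices, np.nan)
    for i, nb in enumerate(mesh.neighbors):
        if len(nb) < 3 or not np.isfinite(values[i]):
            continue
        nb_ok = nb[np.isfinite(values[nb])]
        if len(nb_ok) < 3:
            continue
        nrm = normals[i]
        # tangent basis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(nrm[0]) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(nrm, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(nrm, e1)
        d = mesh.vertices[nb_ok] - mesh.vertices[i]
        uv = np.column_stack([d @ e1, d @ e2])
        X = np.vstack([[1.0, 0.0, 0.0],
                       np.column_stack([np.ones(len(nb_ok)), uv])])
        y = np.concatenate([[values[i]], values[nb_ok]])
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < 3:
            continue  # collinear projected neighbors
        out[i] = float(np.hypot(coef[1], coef[2]))
    return out


def _angle_weighted_normals(mesh: SurfaceMesh) -> np.ndarray:
    tris = mesh.triangles
    v = mesh.vertices
    acc = np.zeros((mesh.n_vertices, 3))
    for k in range(3):
        p0 = v[tris[:, k]]
        a = v[tris[:, (k + 1) % 3]] - p0
        b = v[tris[:, (k + 2) % 3]] - p0
        nrm = np.cross(a, b)
        ln = np.linalg.norm(nrm, axis=1, keepdims=True)
        ln[ln == 0] = 1.0
        cosang = np.clip(np.sum(a * b, axis=1)
                         / (np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)),
                         -1.0, 1.0)
        ang = np.arccos(cosang)
        np.add.at(acc, tris[:, k], nrm / ln * ang[:, None])
    norm = np.linalg.norm(acc, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return acc / norm


def gradient_borders(gradient_magnitude: np.ndarray,
                     threshold: float) -> BinaryParcellation:
    """Vertices whose gradient magnitude is at or above ``threshold``.

    The threshold is an explicit user parameter and no ridge-linking or
    gap-filling is attempted: gradient-based borders are discontinuous and
    completing them requires observer input.
    """
    if threshold < 0:
        raise InvalidArgumentError("threshold must be >= 0")
    g = np.asarray(gradient_magnitude, dtype=float)
    mask = np.isfinite(g) & (g >= threshold)
    return BinaryParcellation(mask, ("gradient", threshold))
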