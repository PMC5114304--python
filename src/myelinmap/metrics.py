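"""Reliability metrics for cortical parameter maps.

Three vertex-wise statistics compare MR parameters on a common footing:

* Normalized coefficient of variation: per-vertex ``(sd / mean)`` across
  subjects (inter) or sessions (intra), divided by the FWHM of the group-
  average map's value distribution after rescaling its 3rd-97th percentile
  range to [0, 1].  The FWHM normalization accounts for how much of the
  dynamic range a parameter actually spreads cortical values over — a map
  that compresses all cortex into a narrow peak gets no credit for a small
  raw COV.
* Parcellability variation (PV): per-vertex scan-rescan sd (averaged across
  rescanned subjects) divided by the raw (unrescaled) distribution FWHM;
  lower PV means a vertex value can be located more reliably within the
  cortical histogram.
* CNR per unit time: absolute contrast between an ROI vertex and a reference
  value from its lightly myelinated neighbor region, divided by the pooled
  inter-vertex sd of both regions and by the square root of the acquisition
  minutes.

Sample (n-1) standard deviations are used throughout — unbiased variance at
the tiny unit counts involved (2-3 sessions/subjects).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats as sps

from . import surface
from .errors import (DegenerateContrastError, DegenerateDistributionError,
                     EmptyRegionError, FWHMEstimationError,
                     InvalidArgumentError)
from .parcellation import auc_threshold

__all__ = ["DistributionSummary", "rescale_unit", "estimate_fwhm",
           "summarize_distribution", "cov_vertexwise", "scan_rescan_sd",
           "pv_vertexwise", "cnr_per_time", "depthwise_correlation"]

GAUSSIAN_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


@dataclass
class DistributionSummary:
    """Shape summary of a cortical value distribution."""

    p3: float
    p97: float
    fwhm_raw: float
    fwhm_rescaled: float
    auc_quantile: Callable[[float], float]


def rescale_unit(values: np.ndarray) -> np.ndarray:
    """Linear rescale sending the 3rd percentile to 0 and the 97th to 1.

    Percentiles use linear interpolation; values outside [p3, p97] map
    outside [0, 1] and are deliberately not clamped — clamping would pile
    mass at the endpoints and distort the half-maximum crossings of the
    rescaled distribution.
    """
    values = np.asarray(values, dtype=float)
    vals = values[np.isfinite(values)]
    if len(vals) < 2 or np.ptp(vals) == 0:
        raise DegenerateDistributionError("need >= 2 distinct values")
    p3, p97 = np.percentile(vals, [3, 97])
    if p97 <= p3:
        raise DegenerateDistributionError("3rd and 97th percentiles coincide")
    return (values - p3) / (p97 - p3)


def _half_max_width(grid: np.ndarray, density: np.ndarray) -> float:
    peak = density.max()
    half = peak / 2.0
    above = density >= half
    i = int(np.argmax(above))                  # leftmost grid point >= half
    j = len(density) - 1 - int(np.argmax(above[::-1]))  # rightmost
    if i == 0 or j == len(density) - 1:
        raise FWHMEstimationError(
            "half-maximum crossing not bracketed: density does not fall "
            "below half of the modal value at the distribution edges")
    # linear interpolation of the outermost crossings
    x_left = grid[i - 1] + (half - density[i - 1]) \
        / (density[i] - density[i - 1]) * (grid[i] - grid[i - 1])
    x_right = grid[j] + (density[j] - half) \
        / (density[j] - density[j + 1]) * (grid[j + 1] - grid[j])
    return float(x_right - x_left)


def estimate_fwhm(values: np.ndarray, method: str = "histogram") -> float:
    """Full width at half the modal density of a value distribution.

    ``histogram``: Freedman-Diaconis binned density; ``kde``: Gaussian
    kernel density with Silverman bandwidth evaluated on a padded grid.
    The width spans the outermost half-maximum crossings, so secondary
    modes inside the envelope widen rather than break the estimate.
    """
    values = np.asarray(values, dtype=float)
    vals = values[np.isfinite(values)]
    if len(vals) < 2 or np.ptp(vals) == 0:
        raise DegenerateDistributionError("non-degenerate distribution required")
    if method == "histogram":
        counts, edges = np.histogram(vals, bins="fd", density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        # pad with zero-density bins so edge crossings are bracketed
        step = edges[1] - edges[0]
        grid = np.concatenate([[centers[0] - step], centers, [centers[-1] + step]])
        density = np.concatenate([[0.0], counts, [0.0]])
        return _half_max_width(grid, density)
    if method == "kde":
        kde = sps.gaussian_kde(vals, bw_method="silverman")
        bw = kde.factor * vals.std(ddof=1)
        grid = np.linspace(vals.min() - 4 * bw, vals.max() + 4 * bw, 1024)
        return _half_max_width(grid, kde(grid))
    raise InvalidArgumentError(f"unknown FWHM method {method!r}")


def summarize_distribution(values: np.ndarray,
                           method: str = "histogram") -> DistributionSummary:
    """Percentiles, raw and rescaled FWHM, and the AUC quantile function of
    a map's value distribution."""
    values = np.asarray(values, dtype=float)
    vals = values[np.isfinite(values)]
    if len(vals) < 2:
        raise DegenerateDistributionError("need >= 2 values")
    p3, p97 = np.percentile(vals, [3, 97])
    fwhm_raw = estimate_fwhm(vals, method)
    fwhm_rescaled = estimate_fwhm(rescale_unit(vals), method)
    return DistributionSummary(float(p3), float(p97), fwhm_raw, fwhm_rescaled,
                               lambda pct: auc_threshold(vals, pct))


def cov_vertexwise(stack, fwhm_rescaled: float, kind: str = "inter",
                   pooling: str = "per_subject") -> np.ndarray:
    """Normalized per-vertex coefficient of variation.

    ``kind='inter'``: ``stack`` is an (n_subjects, n_vertices) array; the
    per-vertex sd/mean across subjects is divided by ``fwhm_rescaled``.
    ``kind='intra'``: ``stack`` is a sequence of (n_sessions, n_vertices)
    arrays, one per rescanned subject; per-subject scan-rescan COVs are
    averaged across subjects before normalization (default), or with
    ``pooling='pooled'`` the within-subject variances are pooled and divided
    by the grand mean first.  Vertices with non-positive mean are NaN.
    """
    if fwhm_rescaled <= 0:
        raise InvalidArgumentError("fwhm_rescaled must be positive")
    if kind == "inter":
        arr = np.asarray(stack, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise InvalidArgumentError("inter COV needs >= 2 subjects")
        cov = _raw_cov(arr)
    elif kind == "intra":
        stacks = [np.asarray(s, dtype=float) for s in stack]
        if len(stacks) == 0 or any(s.shape[0] < 2 for s in stacks):
            raise InvalidArgumentError("intra COV needs >= 2 sessions per subject")
        if pooling == "per_subject":
            per_subj = np.stack([_raw_cov(s) for s in stacks])
            any_ok = np.any(np.isfinite(per_subj), axis=0)
            cov = np.full(per_subj.shape[1], np.nan)
            cov[any_ok] = np.nanmean(per_subj[:, any_ok], axis=0)
        elif pooling == "pooled":
            var = np.mean(np.stack([s.var(axis=0, ddof=1) for s in stacks]), axis=0)
            mu = np.mean(np.stack([s.mean(axis=0) for s in stacks]), axis=0)
            cov = np.where(mu > 0, np.sqrt(var) / np.where(mu > 0, mu, 1.0), np.nan)
        else:
            raise InvalidArgumentError(f"unknown pooling {pooling!r}")
    else:
        raise InvalidArgumentError(f"unknown COV kind {kind!r}")
    return cov / fwhm_rescaled


def _raw_cov(arr: np.ndarray) -> np.ndarray:
    sd = arr.std(axis=0, ddof=1)
    mu = arr.mean(axis=0)
    return np.where(mu > 0, sd / np.where(mu > 0, mu, 1.0), np.nan)


def scan_rescan_sd(stacks) -> np.ndarray:
    """Per-vertex scan-rescan sd averaged across rescanned subjects."""
    stacks = [np.asarray(s, dtype=float) for s in stacks]
    if len(stacks) == 0 or any(s.shape[0] < 2 for s in stacks):
        raise InvalidArgumentError("need >= 2 sessions per rescanned subject")
    return np.mean(np.stack([s.std(axis=0, ddof=1) for s in stacks]), axis=0)


def pv_vertexwise(scanrescan_sd: np.ndarray, fwhm_raw: float) -> np.ndarray:
    """Parcellability variation: scan-rescan sd over raw distribution FWHM.

    Lower PV means higher parcellability.  Invariant under positive affine
    transforms of the parameter (sd and FWHM scale together).
    """
    if fwhm_raw <= 0:
        raise InvalidArgumentError("fwhm_raw must be positive")
    return np.asarray(scanrescan_sd, dtype=float) / fwhm_raw


def cnr_per_time(values: np.ndarray, atlas, roi: int, minutes: float,
                 ref_mode: str = "random_vertex",
                 seed: int | None = None) -> tuple:
    """Contrast-to-noise ratio per unit scan time for one ROI.

    For each included ROI vertex v: ``|S(v) - S(ref)| / sd_pooled /
    sqrt(minutes)``, where the reference is a seeded random vertex value
    from the ROI's designated lightly myelinated neighbor region
    (``ref_mode='random_vertex'``, faithful to a randomly selected reference
    vertex) or the neighbor region's median (``'region_median'``,
    deterministic), and ``sd_pooled`` is the sample sd of all pooled
    vertices of both regions.  Returns ``(per_vertex_cnr, (mean, se, n))``
    with NaN outside the ROI.
    """
    if minutes <= 0:
        raise InvalidArgumentError("minutes must be positive")
    values = np.asarray(values, dtype=float)
    info = atlas.table[roi]
    nb_label = info.neighbor_label
    if nb_label is None:
        raise InvalidArgumentError(f"ROI {info.name!r} has no neighbor region")
    roi_idx = atlas.vertices_of(roi)
    roi_idx = roi_idx[np.isfinite(values[roi_idx])]
    nb_idx = atlas.vertices_of(nb_label)
    nb_idx = nb_idx[np.isfinite(values[nb_idx])]
    if len(roi_idx) == 0 or len(nb_idx) == 0:
        raise EmptyRegionError("ROI or neighbor region empty after exclusion")
    pooled = np.concatenate([values[roi_idx], values[nb_idx]])
    sd = pooled.std(ddof=1)
    if sd == 0:
        raise DegenerateContrastError("pooled ROI/neighbor sd is zero")
    if ref_mode == "random_vertex":
        rng = np.random.default_rng(seed)
        refs = values[rng.choice(nb_idx, size=len(roi_idx), replace=True)]
    elif ref_mode == "region_median":
        refs = np.full(len(roi_idx), np.median(values[nb_idx]))
    else:
        raise InvalidArgumentError(f"unknown ref_mode {ref_mode!r}")
    cnr_roi = np.abs(values[roi_idx] - refs) / sd / np.sqrt(minutes)
    out = np.full(len(values), np.nan)
    out[roi_idx] = cnr_roi
    n = len(cnr_roi)
    se = float(cnr_roi.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return out, (float(cnr_roi.mean()), se, n)


def depthwise_correlation(map_a: np.ndarray, map_b: np.ndarray,
                          exclude: np.ndarray | None = None) -> tuple:
    """Vertex-wise Pearson r between two depth-sampled maps.

    Returns ``(r_per_depth, r_depth_averaged)`` over included vertices
    (finite in both maps and not excluded).  A constant map at some depth
    yields an undefined-correlation NaN marker there.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise InvalidArgumentError("maps must share (n_vertices, n_depths) shape")
    keep = np.ones(a.shape[0], dtype=bool) if exclude is None else ~np.asarray(exclude, bool)
    r_depth = np.array([_pearson(a[keep, d], b[keep, d])
                        for d in range(a.shape[1])])
    r_avg = _pearson(surface.depth_average(a)[keep], surface.depth_average(b)[keep])
    return r_depth, r_avg


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise InvalidArgumentError("need >= 3 included vertices")
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
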