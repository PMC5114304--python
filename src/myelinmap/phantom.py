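"""Synthetic cortical phantom: seeded ground-truth relaxometry maps and
simulated acquisitions.

The phantom emulates a scan-rescan reliability study: a cohort of subjects
sharing one cortical mesh and ROI atlas, each with subject-specific
ground-truth R1 (s^-1) and T2* (s) maps over 11 cortical depth fractions,
and one or two simulated acquisition sessions per subject.  Six parameter
maps are produced per session: quantitative R1 and T2*, their weighted
counterparts T1w (a monotone compressive transform of R1, emulating the
lookup between T1 and the uniform MP2RAGE image) and T2*w (late/early echo
ratio), and the two ratio maps.

Structure of the ground truth
-----------------------------
* Class means: heavily myelinated ROIs have higher R1 and lower T2* than
  moderately and lightly myelinated cortex.
* Shared anatomy: a smooth "myelin anomaly" field common to all subjects
  modulates R1 and (with opposite sign and depth-decaying coupling) T2*,
  so the R1-vs-T2* anticorrelation is strongest at deep cortical fractions
  and weakens toward the pial surface.
* Depth profiles are linear in depth fraction: R1 decreases and T2*
  increases from the white-matter boundary (0.0) to the pial surface (1.0).
* Inter-subject variation: ROI-level multiplicative log-normal factors plus
  a smooth within-ROI multiplicative Gaussian field, drawn per subject.
* Vein artifacts: a small fraction of vertices carry ground-truth T2*
  depressed below the downstream exclusion threshold.
* An optional curvature-correlated R1 component (configurable coefficient)
  makes curvature residualisation testable.

Noise model: zero-mean additive Gaussian noise on echo magnitudes and on the
R1 measurement — the high-SNR Gaussian approximation of magnitude noise,
which keeps the noiseless fit round trip exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import relaxometry as rx
from . import surface
from .atlas import ROIAtlas
from .errors import InvalidArgumentError
from .mesh import SurfaceMesh

__all__ = ["PARAMETERS", "PopulationParams", "TransformParams",
           "AcquisitionSpec", "GroundTruthMaps", "SubjectSession", "Cohort",
           "synthetic_curvature", "sample_ground_truth", "weighted_transform",
           "simulate_session", "simulate_cohort"]

#: Canonical parameter names, in reporting order.
PARAMETERS = ("R1", "T1w", "T2star", "T2starw", "T1w/T2starw", "R1/T2star")

_CLASS_ORDER = ("heavy", "moderate", "light")


@dataclass(frozen=True)
class TransformParams:
    """Monotone compressive R1 -> T1w map: ``offset + scale * tanh((r1 - center) / width)``.

    ``width`` comparable to the cortical R1 spread makes the transform
    locally expansive around typical cortical values, so a given quantitative
    range is translated into a broader relative range in the weighted image —
    the behaviour that drives the higher variability of weighted maps.
    """

    center: float = 0.51   # s^-1, near the cortical R1 distribution centre
    width: float = 0.12    # s^-1; ~2x the cortical spread: mild saturation
    scale: float = 600.0   # a.u.
    offset: float = 800.0  # a.u.; keeps relative noise amplification ~2


@dataclass(frozen=True)
class PopulationParams:
    """Ground-truth population model.

    Central values are mid-depth class means; 7T cortical gray matter sits
    around R1 ~ 0.5 s^-1 and T2* ~ 0.03 s, with heavily myelinated cortex
    faster-relaxing on both axes.  Spatial spreads are calibrated so the
    depth-averaged R1 distribution has a raw FWHM of the order of 0.05 s^-1
    and T2* of the order of 0.008 s.
    """

    r1_class_mean: dict = field(default_factory=lambda: {
        "heavy": 0.55, "moderate": 0.515, "light": 0.48})   # s^-1
    t2s_class_mean: dict = field(default_factory=lambda: {
        "heavy": 0.026, "moderate": 0.030, "light": 0.034})  # s
    r1_field_sd: float = 0.03       # s^-1, shared within-ROI anatomy
    t2s_field_sd: float = 0.0025    # s
    inter_subject_sd_r1: float = 0.03    # log-normal ROI factor sd
    inter_subject_sd_t2s: float = 0.05   # transversal maps vary more across subjects
    subject_field_sd_r1: float = 0.03    # smooth multiplicative field sd
    subject_field_sd_t2s: float = 0.08
    smoothness_mm: float = 4.0      # FWHM of the spatial random fields
    depth_slope_r1: float = 0.12    # fractional R1 decrease WM -> pial
    depth_slope_t2s: float = 0.08   # fractional T2* increase WM -> pial
    coupling_t2s: float = 0.0015    # s per unit myelin anomaly, at depth 0
    coupling_depth_decay: float = 0.7
    curvature_coeff_r1: float = 0.1  # s^-1 per mm^-1 of signed curvature
    vein_fraction: float = 0.015
    s0_field_sd: float = 0.05
    anatomy_seed: int = 20161118    # shared across subjects

    def validate(self):
        for d in (self.r1_class_mean, self.t2s_class_mean):
            for c in _CLASS_ORDER:
                if d.get(c, 0.0) <= 0:
                    raise InvalidArgumentError(
                        f"central value for class {c!r} must be positive")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition parameters of the two simulated signal sources.

    ``echo_times`` are the 4 GRE echoes (s); ``t1_minutes`` and
    ``gre_minutes`` are the scan durations of the MP2RAGE-like and GRE-like
    acquisitions (8:02 and 8:33 at the defaults).  Ratio parameters charge
    the sum of both source durations.
    """

    echo_times: tuple = tuple(rx.DEFAULT_ECHO_TIMES)
    t1_minutes: float = 8.0 + 2.0 / 60.0
    gre_minutes: float = 8.0 + 33.0 / 60.0
    noise_sd_gre: float = 0.015   # a.u. (ground-truth S0 ~ 1)
    noise_sd_t1: float = 0.005    # s^-1
    transform: TransformParams = TransformParams()
    seed: int = 0

    def __post_init__(self):
        te = np.asarray(self.echo_times)
        if np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise InvalidArgumentError("echo_times must be positive and increasing")
        if self.t1_minutes <= 0 or self.gre_minutes <= 0:
            raise InvalidArgumentError("scan_minutes must be positive")

    def minutes_for(self, parameter: str) -> float:
        if parameter in ("R1", "T1w"):
            return self.t1_minutes
        if parameter in ("T2star", "T2starw"):
            return self.gre_minutes
        return self.t1_minutes + self.gre_minutes


@dataclass
class GroundTruthMaps:
    """Per-subject ground truth: r1_true/t2s_true of shape (n_vertices, 11),
    s0_true (n_vertices,), vein_flag boolean."""

    r1_true: np.ndarray
    t2s_true: np.ndarray
    s0_true: np.ndarray
    vein_flag: np.ndarray


@dataclass
class SubjectSession:
    """One simulated acquisition: raw echoes (n_vertices, 11 depths,
    4 echoes), per-parameter per-depth maps, and depth-averaged maps."""

    subject_id: int
    session_id: int
    echoes: np.ndarray
    maps: dict          # parameter -> (n_vertices, 11)
    maps_avg: dict      # parameter -> (n_vertices,)


@dataclass
class Cohort:
    mesh: SurfaceMesh
    atlas: ROIAtlas
    curvature: np.ndarray
    ground_truths: list   # per subject
    sessions: list        # per subject: list of SubjectSession


def _unit_field(mesh: SurfaceMesh, rng: np.random.Generator,
                fwhm_mm: float) -> np.ndarray:
    """Smooth zero-mean unit-variance Gaussian random field on the mesh."""
    z = rng.standard_normal(mesh.n_vertices)
    f = surface.geodesic_smooth(mesh, z, fwhm_mm)
    sd = f.std()
    if sd == 0:
        return np.zeros_like(f)
    return (f - f.mean()) / sd


def synthetic_curvature(mesh: SurfaceMesh, seed: int,
                        sd: float = 0.1, fwhm_mm: float = 4.0) -> np.ndarray:
    """Synthetic gyral-folding curvature field (mm^-1).

    Icosphere phantoms have constant geometric curvature, so a smooth seeded
    pseudo-curvature field stands in for the gyral/sulcal folding pattern
    that real cortical meshes carry.
    """
    rng = np.random.default_rng(seed)
    return sd * _unit_field(mesh, rng, fwhm_mm)


def sample_ground_truth(mesh: SurfaceMesh, atlas: ROIAtlas,
                        population: PopulationParams, subject_seed: int,
                        curvature: np.ndarray | None = None) -> GroundTruthMaps:
    """Draw one subject's ground-truth maps.

    Shared anatomy (myelin anomaly field, vein placement, S0 profile) is
    seeded by ``population.anatomy_seed`` and identical across subjects;
    ``subject_seed`` drives only the inter-subject effects, so zero
    inter-subject SDs make every subject identical.
    """
    population.validate()
    n = mesh.n_vertices
    depths = surface.DEPTH_FRACTIONS

    # ---- shared anatomy -------------------------------------------------
    rng_a = np.random.default_rng(population.anatomy_seed)
    myelin_anom = _unit_field(mesh, rng_a, population.smoothness_mm)
    t2s_anom = _unit_field(mesh, rng_a, population.smoothness_mm)
    s0_true = 1.0 + population.s0_field_sd * _unit_field(
        mesh, rng_a, population.smoothness_mm)
    vein_flag = rng_a.random(n) < population.vein_fraction
    vein_t2s = rng_a.uniform(0.012, 0.020, size=n)

    classes = np.array([atlas.table[lb].myelin_class for lb in atlas.labels])
    r1_base = np.empty(n)
    t2s_base = np.empty(n)
    for c in _CLASS_ORDER:
        sel = classes == c
        r1_base[sel] = population.r1_class_mean[c]
        t2s_base[sel] = population.t2s_class_mean[c]

    curv = mesh.curvature if curvature is None else np.asarray(curvature)
    r1_mid = (r1_base + population.r1_field_sd * myelin_anom
              + population.curvature_coeff_r1 * (curv - curv.mean()))
    t2s_mid = t2s_base + population.t2s_field_sd * t2s_anom

    # ---- subject effects ------------------------------------------------
    rng_s = np.random.default_rng(subject_seed)
    all_labels = sorted(atlas.table)
    fac_r1 = np.exp(rng_s.normal(0.0, population.inter_subject_sd_r1,
                                 len(all_labels)))
    fac_t2s = np.exp(rng_s.normal(0.0, population.inter_subject_sd_t2s,
                                  len(all_labels)))
    lut = {lb: k for k, lb in enumerate(all_labels)}
    idx = np.array([lut[lb] for lb in atlas.labels])
    r1_mid = r1_mid * fac_r1[idx]
    t2s_mid = t2s_mid * fac_t2s[idx]
    if population.subject_field_sd_r1 > 0:
        r1_mid = r1_mid * np.exp(population.subject_field_sd_r1
                                 * _unit_field(mesh, rng_s, population.smoothness_mm))
    if population.subject_field_sd_t2s > 0:
        t2s_mid = t2s_mid * np.exp(population.subject_field_sd_t2s
                                   * _unit_field(mesh, rng_s, population.smoothness_mm))

    # ---- depth profiles and coupling ------------------------------------
    r1_true = r1_mid[:, None] * (1.0 + population.depth_slope_r1
                                 * (0.5 - depths)[None, :])
    kappa = population.coupling_t2s * (1.0 - population.coupling_depth_decay
                                       * depths)
    t2s_true = ((t2s_mid[:, None] - kappa[None, :] * myelin_anom[:, None])
                * (1.0 + population.depth_slope_t2s * (depths - 0.5)[None, :]))

    t2s_true[vein_flag, :] = vein_t2s[vein_flag, None]

    if np.any(r1_true <= 0) or np.any(t2s_true <= 0):
        raise InvalidArgumentError(
            "population parameters produced non-positive ground truth")
    return GroundTruthMaps(r1_true, t2s_true, s0_true, vein_flag)


def weighted_transform(r1: np.ndarray, params: TransformParams = TransformParams(),
                       bias_field: np.ndarray | None = None) -> np.ndarray:
    """Strictly monotone R1 -> T1w (a.u.) map; see :class:`TransformParams`.

    NaN (unfittable) entries propagate; finite non-positive R1 raises.  An
    optional multiplicative smooth bias field (default off) emulates
    residual receive/transmit bias in the weighted image.
    """
    r1 = np.asarray(r1, dtype=float)
    if np.any(np.isfinite(r1) & (r1 <= 0)):
        raise InvalidArgumentError("r1 must be strictly positive")
    t1w = params.offset + params.scale * np.tanh((r1 - params.center) / params.width)
    if bias_field is not None:
        t1w = t1w * np.asarray(bias_field, dtype=float)
    return t1w


def simulate_session(gt: GroundTruthMaps, acq: AcquisitionSpec,
                     session_seed: int | None = None, *, subject_id: int = 0,
                     session_id: int = 0) -> SubjectSession:
    """Simulate one acquisition session from ground truth.

    Echo signals follow ``S0 * exp(-TE / T2*_true)`` plus Gaussian noise of
    sd ``noise_sd_gre``; the longitudinal measurement is ``R1_true`` plus
    Gaussian noise of sd ``noise_sd_t1``.  All six parameter maps are then
    derived per depth exactly as in the analysis pipeline (log-linear T2*
    fit, echo ratio, weighted transform, ratio maps) and depth-averaged over
    the default 20-80% window.
    """
    if session_seed is None:
        session_seed = acq.seed
    rng = np.random.default_rng(session_seed)
    te = np.asarray(acq.echo_times)
    n, nd = gt.t2s_true.shape

    decay = np.exp(-te[None, None, :] / gt.t2s_true[:, :, None])
    echoes = gt.s0_true[:, None, None] * decay
    if acq.noise_sd_gre > 0:
        echoes = echoes + acq.noise_sd_gre * rng.standard_normal(echoes.shape)

    r1_meas = gt.r1_true.copy()
    if acq.noise_sd_t1 > 0:
        r1_meas = r1_meas + acq.noise_sd_t1 * rng.standard_normal(r1_meas.shape)
    r1_meas[r1_meas <= 0] = np.nan  # magnitude floor; unfittable
    t1w = weighted_transform(r1_meas, acq.transform)

    series = rx.EchoSeries(te, echoes.reshape(n * nd, len(te)))
    fit = rx.fit_t2star(series)
    t2s = fit.t2star.reshape(n, nd)
    t2sw = rx.t2star_weighted(series).reshape(n, nd)
    t2s = np.where(np.isposinf(t2s), np.nan, t2s)  # no-decay vertices unusable
    ratio_w, ratio_q = rx.ratio_maps(t1w, t2sw, r1_meas, t2s)

    maps = {"R1": r1_meas, "T1w": t1w, "T2star": t2s, "T2starw": t2sw,
            "T1w/T2starw": ratio_w, "R1/T2star": ratio_q}
    maps_avg = {p: surface.depth_average(m) for p, m in maps.items()}
    return SubjectSession(subject_id, session_id, echoes, maps, maps_avg)


def simulate_cohort(mesh: SurfaceMesh, atlas: ROIAtlas,
                    population: PopulationParams, acq: AcquisitionSpec,
                    n_subjects: int = 10, n_rescan: int = 3,
                    seed: int = 0,
                    curvature: np.ndarray | None = None) -> Cohort:
    """Simulate the full study design: ``n_subjects`` subjects, the first
    ``n_rescan`` of which have one rescan session each."""
    if not 0 <= n_rescan <= n_subjects:
        raise InvalidArgumentError("need 0 <= n_rescan <= n_subjects")
    rng = np.random.default_rng(seed)
    subj_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    sess_seeds = rng.integers(0, 2**31 - 1, size=(n_subjects, 2))
    if curvature is None:
        curvature = synthetic_curvature(mesh, int(rng.integers(0, 2**31 - 1)))
    gts, sessions = [], []
    for s in range(n_subjects):
        gt = sample_ground_truth(mesh, atlas, population, int(subj_seeds[s]),
                                 curvature=curvature)
        gts.append(gt)
        n_sess = 2 if s < n_rescan else 1
        sessions.append([
            simulate_session(gt, acq, int(sess_seeds[s, k]),
                             subject_id=s, session_id=k)
            for k in range(n_sess)])
    return Cohort(mesh, atlas, curvature, gts, sessions)
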