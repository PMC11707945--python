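"""Synthetic study generator with known ground truth.

No microperimetry/FAF study data are publicly available for this
workflow, so every pipeline stage is exercised on simulated eyes that
emulate the study conditions: ~30 eyes, multifocal GA lesions with
per-eye total area around 6.5 mm², two graders picking on average 3.3
and 4.6 vessel-bifurcation fiducials, and a 4-2 staircase threshold
measurement on the 68-point 10-2 grid.

The generative model per eye:

1. a true SLO→FAF similarity transform (scale near the ratio of the two
   frames' degree-per-pixel factors, small rotation, fovea-anchored
   translation);
2. 1–3 disjoint star-convex GA foci with log-normally distributed areas
   and smooth periodic boundary roughness;
3. a logistic sensitivity field over the true signed margin distance
   (deep scotoma inside the lesion, normal sensitivity outside);
4. per-stimulus 4-2 staircase simulation with a cumulative-normal
   psychometric observer (slope 0 → deterministic observer);
5. per-grader fiducial picks: well-spread source points mapped through
   the true transform with isotropic click jitter added at both ends.

Randomness is hierarchical: each (eye, purpose) pair gets its own
`numpy` generator keyed by the study seed, so e.g. changing a grader's
jitter SD rescales the same underlying click-noise draws rather than
resampling the whole study (common random numbers across noise levels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .exceptions import InvalidGeometryError, InvalidInputError
from .frames import DEFAULT_UM_PER_DEGREE, ImageFrame, degrees_to_pixels
from .grid import DB_MAX, DB_MIN, MPExam, NOT_SEEN_SENTINEL, exam_from_grid, generate_10_2_grid
from .lesions import GAFocus, LesionTracing, SignedDistanceResult, filter_min_area, signed_distances
from .registration import FiducialPairSet, SimilarityTransform

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class LesionModel:
    """Parameters of the star-convex multifocal lesion generator."""

    n_foci_range: tuple[int, int] = (1, 3)
    mean_focus_area_mm2: float = 3.25   # × mean 2 foci ≈ 6.5 mm² per eye
    sd_focus_area_mm2: float = 1.75
    roughness: float = 0.15             # relative radial modulation amplitude
    n_vertices: int = 128
    center_spread_deg: float = 4.0      # foci centers within this radius of the fovea


@dataclass(frozen=True)
class SensitivityFieldModel:
    """Logistic sensitivity profile across the lesion margin."""

    inside_db: float = -5.0    # deep scotoma: below 0 ⇒ brightest stimulus unseen
    outside_db: float = 26.0
    half_width_um: float = 125.0


@dataclass(frozen=True)
class GraderParams:
    """Fiducial-picking behavior of one grader."""

    n_fiducials_mean: float
    n_fiducials_sd: float
    jitter_sd_px: float


@dataclass(frozen=True)
class StaircaseParams:
    enabled: bool = True
    start_db: float = 25.0
    step_coarse_db: float = 4.0
    step_fine_db: float = 2.0
    psychometric_slope_db: float = 1.0  # 0 ⇒ deterministic observer


@dataclass(frozen=True)
class SimulationConfig:
    """Full study recipe; a fixed seed reproduces the study byte-for-byte."""

    n_eyes: int = 30
    seed: int = 0
    lesion: LesionModel = field(default_factory=LesionModel)
    sensitivity: SensitivityFieldModel = field(default_factory=SensitivityFieldModel)
    graders: dict[str, GraderParams] = field(default_factory=lambda: {
        "grader1": GraderParams(3.3, 0.7, 1.5),
        "grader2": GraderParams(4.6, 1.7, 1.5),
    })
    staircase: StaircaseParams = field(default_factory=StaircaseParams)
    um_per_degree: float = DEFAULT_UM_PER_DEGREE
    slo_fov_deg: float = 36.0
    slo_pixel_dims: int = 1024
    faf_fov_deg: float = 30.0
    faf_pixel_dims: int = 768

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise InvalidInputError("n_eyes must be ≥ 1")
        for g in self.graders.values():
            if g.jitter_sd_px < 0 or g.n_fiducials_sd < 0:
                raise InvalidInputError("grader SDs must be ≥ 0")

    @property
    def slo_frame(self) -> ImageFrame:
        return ImageFrame(self.slo_fov_deg, self.slo_pixel_dims, self.um_per_degree, "SLO")

    @property
    def faf_frame(self) -> ImageFrame:
        return ImageFrame(self.faf_fov_deg, self.faf_pixel_dims, self.um_per_degree, "FAF")

    def with_jitter(self, jitter_sd_px: float) -> "SimulationConfig":
        """Same study with every grader's click jitter set to one value."""
        graders = {k: replace(g, jitter_sd_px=jitter_sd_px) for k, g in self.graders.items()}
        return replace(self, graders=graders)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


# ---------------------------------------------------------------------------
# lesions


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - s2 / 2.0, math.sqrt(s2)


def _star_polygon(center_um: np.ndarray, area_mm2: float, model: LesionModel,
                  rng: np.random.Generator, focus_id: str) -> GAFocus:
    base_r = math.sqrt(area_mm2 * 1e6 / math.pi)
    theta = np.linspace(0.0, 2.0 * math.pi, model.n_vertices, endpoint=False)
    if model.roughness > 0:
        harmonics = np.arange(2, 6)
        amp = rng.standard_normal(len(harmonics)) / harmonics
        phase = rng.uniform(0, 2 * math.pi, len(harmonics))
        noise = np.sum(amp[:, None] * np.cos(harmonics[:, None] * theta + phase[:, None]), axis=0)
        rms = float(np.sqrt(np.mean(noise ** 2)))
        if rms > 0:
            noise /= rms
    else:
        noise = np.zeros_like(theta)
    r = base_r * np.clip(1.0 + model.roughness * noise, 0.2, None)
    verts = center_um + np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    return GAFocus(vertices_um=verts, focus_id=focus_id)


def simulate_lesion(config: SimulationConfig, rng: np.random.Generator,
                    eye_id: str = "") -> LesionTracing:
    """Generate 1–3 disjoint star-convex GA foci in FAF μm.

    Per-focus areas are log-normal around the configured mean; boundary
    roughness is smooth low-order periodic noise, so polygons are simple
    by construction but are still validated (bounded resampling, error
    after 100 failures).
    """
    model = config.lesion
    faf = config.faf_frame
    lo, hi = model.n_foci_range
    n_foci = int(rng.integers(lo, hi + 1))
    mu, sigma = _lognormal_params(model.mean_focus_area_mm2, model.sd_focus_area_mm2)
    spread_um = model.center_spread_deg * config.um_per_degree

    # Draw all areas first and place the largest focus first: satellite foci
    # are typically the smaller ones, and big-first placement keeps disjoint
    # multifocal configurations feasible near the fovea.
    areas = sorted((float(rng.lognormal(mu, sigma)) for _ in range(n_foci)), reverse=True)
    main_r = math.sqrt(areas[0] * 1e6 / math.pi)
    foci: list[GAFocus] = []
    for j, area in enumerate(areas):
        for attempt in range(100):
            # satellites sit in a ring beyond the main focus, as in multifocal GA
            base_r = math.sqrt(area * 1e6 / math.pi)
            r_min = 0.0 if j == 0 else 1.3 * main_r + base_r
            r_max = spread_um if j == 0 else r_min + spread_um
            ang = rng.uniform(0, 2 * math.pi)
            rad = math.sqrt(rng.uniform(r_min ** 2, r_max ** 2))
            center = faf.fovea_um + rad * np.array([math.cos(ang), math.sin(ang)])
            try:
                focus = _star_polygon(center, area, model, rng, f"{eye_id}F{j}")
            except InvalidGeometryError:
                continue
            if any(focus.polygon.intersects(f.polygon) for f in foci):
                if attempt >= 30:
                    # last resort: shrink the satellite focus so placement terminates
                    area *= 0.9
                continue
            foci.append(focus)
            break
        else:
            raise InvalidGeometryError(
                f"eye {eye_id}: could not place focus {j} after 100 attempts"
            )
    return LesionTracing(foci=foci, eye_id=eye_id)


# ---------------------------------------------------------------------------
# sensitivity field and staircase


def sensitivity_field(distance_um, config: SimulationConfig) -> np.ndarray | float:
    """True threshold (dB) as a logistic function of signed margin distance.

    Tends to ``inside_db`` deep inside the lesion, ``outside_db`` far
    outside, crossing the midpoint at the margin; monotone non-decreasing
    when ``outside_db ≥ inside_db``.
    """
    f = config.sensitivity
    d = np.asarray(distance_um, dtype=float)
    out = f.inside_db + (f.outside_db - f.inside_db) * expit(d / f.half_width_um)
    return float(out) if np.isscalar(distance_um) else out


def staircase_4_2(true_threshold_db: float, rng: np.random.Generator,
                  params: StaircaseParams = StaircaseParams()) -> tuple[float, bool]:
    """Simulate one 4-2 staircase threshold measurement on the [0, 36] dB scale.

    Protocol: start at 25 dB; 4 dB steps (dimmer after seen, brighter
    after not seen) until the first reversal, then 2 dB steps until the
    second reversal; the estimate is the last level seen. A stimulus
    never seen — including at 0 dB attenuation, the brightest — yields
    the −1 dB sentinel and ``raw_not_seen=True``.

    The observer answers "seen" with probability
    Φ((threshold − level) / slope); slope 0 gives the deterministic
    observer (seen iff level ≤ threshold).
    """
    slope = params.psychometric_slope_db

    def seen(level: float) -> bool:
        if slope <= 0:
            return level <= true_threshold_db
        return bool(rng.uniform() < norm.cdf((true_threshold_db - level) / slope))

    level = params.start_db
    step = params.step_coarse_db
    last_seen: float | None = None
    prev: bool | None = None
    reversals = 0
    for _ in range(64):  # generous safety bound; protocol terminates far earlier
        resp = seen(level)
        if resp:
            last_seen = level
        if prev is not None and resp != prev:
            reversals += 1
            if reversals == 1:
                step = params.step_fine_db
            if reversals >= 2:
                break
        prev = resp
        nxt = level + step if resp else level - step
        nxt = min(max(nxt, DB_MIN), DB_MAX)
        if nxt == level:  # pinned at floor (unseen) or ceiling (seen)
            break
        level = nxt
    if last_seen is None:
        return NOT_SEEN_SENTINEL, True
    return float(last_seen), False


# ---------------------------------------------------------------------------
# graders


def simulate_grader_fiducials(true_transform: SimilarityTransform, config: SimulationConfig,
                              rng: np.random.Generator, grader_id: str,
                              eye_id: str = "") -> FiducialPairSet:
    """One grader's fiducial picks for one eye.

    Source points are spread over the central SLO field with a minimum
    pairwise separation and a collinearity guard; targets are the true
    transform of the sources; isotropic Gaussian click jitter of the
    grader's SD is added independently at both ends (the grader clicks in
    both images). With zero jitter the pairs are exactly consistent.
    """
    g = config.graders[grader_id]
    n = max(3, int(round(rng.normal(g.n_fiducials_mean, g.n_fiducials_sd))))
    dims = config.slo_pixel_dims
    lo, hi = 0.15 * dims, 0.85 * dims
    min_sep = 0.12 * dims

    for _ in range(200):
        pts: list[np.ndarray] = []
        tries = 0
        while len(pts) < n and tries < 500:
            cand = rng.uniform(lo, hi, 2)
            tries += 1
            if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
                pts.append(cand)
        if len(pts) < n:
            continue
        src = np.array(pts)
        sv = np.linalg.svd(src - src.mean(axis=0), compute_uv=False)
        if sv[-1] > 0.02 * sv[0]:  # clearly non-collinear configuration
            break
    else:  # pragma: no cover - the sampler essentially always succeeds
        raise InvalidInputError("could not sample a non-collinear fiducial configuration")

    dst = true_transform.apply(src)
    src = src + g.jitter_sd_px * rng.standard_normal(src.shape)
    dst = dst + g.jitter_sd_px * rng.standard_normal(dst.shape)
    return FiducialPairSet(source_px=src, target_px=dst, grader_id=grader_id, eye_id=eye_id)


# ---------------------------------------------------------------------------
# whole-study simulation


@dataclass
class EyeGroundTruth:
    """Everything needed to recompute an eye's downstream quantities exactly."""

    true_transform: SimilarityTransform
    tracing: LesionTracing
    true_distances: list[SignedDistanceResult]
    true_thresholds_db: np.ndarray
    stimulus_faf_um: np.ndarray


@dataclass
class SimulatedEye:
    eye_id: str
    exam: MPExam
    tracing: LesionTracing
    fiducials: dict[str, FiducialPairSet]
    truth: EyeGroundTruth


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    eyes: list[SimulatedEye]


def _true_transform(config: SimulationConfig, rng: np.random.Generator) -> SimilarityTransform:
    slo, faf = config.slo_frame, config.faf_frame
    base_scale = slo.deg_per_pixel / faf.deg_per_pixel  # ≈ 0.9 for the default frames
    scale = base_scale * math.exp(rng.normal(0.0, 0.02))
    rotation = rng.normal(0.0, math.radians(2.0))
    c, s = math.cos(rotation), math.sin(rotation)
    rot = np.array([[c, -s], [s, c]])
    fovea_target = faf.fovea_px + rng.normal(0.0, 5.0, 2)
    t = fovea_target - scale * rot @ slo.fovea_px
    return SimilarityTransform(scale, rotation, (float(t[0]), float(t[1])))


def simulate_eye(config: SimulationConfig, eye_index: int) -> SimulatedEye:
    """Generate one eye: lesion, true registration, exam, grader fiducials."""
    eye_id = f"eye{eye_index:03d}"
    seed = config.seed
    rng_lesion = _rng(seed, eye_index, 0)
    rng_exam = _rng(seed, eye_index, 1)

    true_t = _true_transform(config, rng_lesion)
    tracing = filter_min_area(simulate_lesion(config, rng_lesion, eye_id))

    grid_deg = generate_10_2_grid()
    slo_px = degrees_to_pixels(grid_deg, config.slo_frame)
    faf_um = true_t.apply(slo_px) * config.faf_frame.um_per_pixel
    dists = signed_distances(faf_um, tracing)
    thresholds = np.asarray(sensitivity_field([d.distance_um for d in dists], config))

    if config.staircase.enabled:
        meas = [staircase_4_2(t, rng_exam, config.staircase) for t in thresholds]
        sens = np.array([m[0] for m in meas])
        not_seen = np.array([m[1] for m in meas])
    else:
        not_seen = thresholds < DB_MIN
        sens = np.where(not_seen, NOT_SEEN_SENTINEL, np.clip(thresholds, DB_MIN, DB_MAX))

    exam = exam_from_grid(eye_id, "baseline", sens, not_seen, config.slo_frame)
    fiducials = {
        gid: simulate_grader_fiducials(true_t, config, _rng(seed, eye_index, 2 + k), gid, eye_id)
        for k, gid in enumerate(sorted(config.graders))
    }
    truth = EyeGroundTruth(true_t, tracing, dists, thresholds, faf_um)
    return SimulatedEye(eye_id, exam, tracing, fiducials, truth)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the full study; deterministic given ``config.seed``."""
    return SimulatedStudy(config, [simulate_eye(config, i) for i in range(config.n_eyes)])
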