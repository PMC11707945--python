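"""End-to-end composition: registration → signed distances → zone metrics →
inter-grader repeatability battery."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError
from .frames import ImageFrame, degrees_to_pixels
from .grid import MPExam
from .lesions import LesionTracing, SignedDistanceResult, ZoneSpec, filter_min_area, \
    signed_distances
from .metrics import CoordinateDifferences, SensitivityAveraging, ZoneMetrics, \
    compute_zone_metrics, stimulus_coordinate_differences
from .registration import FiducialPairSet, FitDiagnostics, SimilarityTransform, fit_similarity
from .repeatability import PairedMeasurements, RepeatabilityReport, analyze_agreement, \
    bland_altman_repeated


@dataclass
class EyeAnalysis:
    """One grader's full analysis of one eye."""

    eye_id: str
    grader_id: str
    transform: SimilarityTransform
    fit: FitDiagnostics
    stimulus_faf_um: np.ndarray  # (68, 2) transformed stimulus centers
    distances: list[SignedDistanceResult]
    zone_metrics: dict[str, ZoneMetrics]  # keyed by zone kind


def register_stimuli(exam: MPExam, fiducials: FiducialPairSet,
                     faf_frame: ImageFrame) -> tuple[SimilarityTransform, FitDiagnostics,
                                                     np.ndarray]:
    """Fit the grader's transform and map stimulus centers into FAF μm."""
    transform, fit = fit_similarity(fiducials)
    slo_px = degrees_to_pixels(exam.positions_deg, exam.slo_frame)
    faf_um = transform.apply(slo_px) * faf_frame.um_per_pixel
    return transform, fit, faf_um


def analyze_eye(
    exam: MPExam,
    tracing: LesionTracing,
    fiducials: FiducialPairSet,
    faf_frame: ImageFrame,
    zones: list[ZoneSpec] | None = None,
    averaging: SensitivityAveraging = SensitivityAveraging.FLOOR_AT_ZERO,
) -> EyeAnalysis:
    """Run one grader's registration and zone analysis for one eye."""
    zones = zones if zones is not None else [ZoneSpec.junctional(), ZoneSpec.perilesional()]
    transform, fit, faf_um = register_stimuli(exam, fiducials, faf_frame)
    tracing = filter_min_area(tracing)
    dists = signed_distances(faf_um, tracing, exam.stimulus_ids)
    zm = {z.kind: compute_zone_metrics(exam, dists, z, averaging) for z in zones}
    return EyeAnalysis(
        eye_id=exam.eye_id, grader_id=fiducials.grader_id, transform=transform,
        fit=fit, stimulus_faf_um=faf_um, distances=dists, zone_metrics=zm,
    )


@dataclass
class RepeatabilityBattery:
    """The full two-grader agreement battery over a set of eyes."""

    mean_sensitivity: RepeatabilityReport          # eye-level, dB
    scotomatous_count: RepeatabilityReport         # eye-level, points
    margin_distance: RepeatabilityReport           # stimulus-level μm, repeated measures
    coordinate_differences: list[CoordinateDifferences]  # one per eye
    mean_coordinate_difference_um: float           # grand mean over per-eye means
    sd_coordinate_difference_um: float
    zone_kind: str
    n_eyes: int


def _paired_eye_metric(a1: list[EyeAnalysis], a2: list[EyeAnalysis], zone_kind: str,
                       extract, units: str) -> PairedMeasurements:
    ids, v1, v2 = [], [], []
    for e1, e2 in zip(a1, a2):
        m1, m2 = e1.zone_metrics[zone_kind], e2.zone_metrics[zone_kind]
        x1, x2 = extract(m1), extract(m2)
        if x1 is None or x2 is None:
            continue  # empty zone for at least one grader: excluded, not imputed
        ids.append(e1.eye_id)
        v1.append(x1)
        v2.append(x2)
    return PairedMeasurements(np.array(ids), np.array(v1, float), np.array(v2, float),
                              units=units)


def repeatability_battery(
    grader1: list[EyeAnalysis],
    grader2: list[EyeAnalysis],
    zone_kind: str = "junctional",
) -> RepeatabilityBattery:
    """Agreement battery between two graders' analyses of the same eyes.

    Eye-level mean zone sensitivity and scotomatous count get the plain
    Bland–Altman + ICC + CoR treatment; stimulus-level margin distances
    (68 per eye) use the repeated-measures Bland–Altman with eye-level
    variance components; stimulus coordinate differences are summarized
    per eye and overall.
    """
    if len(grader1) != len(grader2) or not grader1:
        raise InvalidInputError("need the same non-empty eye list from both graders")
    for e1, e2 in zip(grader1, grader2):
        if e1.eye_id != e2.eye_id:
            raise InvalidInputError(f"eye order mismatch: {e1.eye_id} vs {e2.eye_id}")

    mean_sens = analyze_agreement(_paired_eye_metric(
        grader1, grader2, zone_kind, lambda m: m.mean_sensitivity_db, "dB"))
    scoto = analyze_agreement(_paired_eye_metric(
        grader1, grader2, zone_kind, lambda m: float(m.n_scotomatous_in_zone), "points"))

    ids, v1, v2, clusters = [], [], [], []
    for e1, e2 in zip(grader1, grader2):
        for d1, d2 in zip(e1.distances, e2.distances):
            if d1.stimulus_id != d2.stimulus_id:
                raise InvalidInputError("stimulus order mismatch between graders")
            ids.append(f"{e1.eye_id}:{d1.stimulus_id}")
            v1.append(d1.distance_um)
            v2.append(d2.distance_um)
            clusters.append(e1.eye_id)
    margin = bland_altman_repeated(PairedMeasurements(
        np.array(ids), np.array(v1), np.array(v2), cluster_ids=np.array(clusters),
        units="um"))

    cds = [stimulus_coordinate_differences(e1.stimulus_faf_um, e2.stimulus_faf_um)
           for e1, e2 in zip(grader1, grader2)]
    per_eye_means = np.array([c.mean_um for c in cds])
    return RepeatabilityBattery(
        mean_sensitivity=mean_sens,
        scotomatous_count=scoto,
        margin_distance=margin,
        coordinate_differences=cds,
        mean_coordinate_difference_um=float(np.mean(per_eye_means)),
        sd_coordinate_difference_um=float(np.std(per_eye_means, ddof=1))
        if len(per_eye_means) > 1 else 0.0,
        zone_kind=zone_kind,
        n_eyes=len(grader1),
    )


def analyze_study(study, zones: list[ZoneSpec] | None = None,
                  averaging: SensitivityAveraging = SensitivityAveraging.FLOOR_AT_ZERO,
                  ) -> dict[str, list[EyeAnalysis]]:
    """Run every grader's analysis over a simulated study."""
    faf = study.config.faf_frame
    out: dict[str, list[EyeAnalysis]] = {}
    for gid in sorted(study.config.graders):
        out[gid] = [
            analyze_eye(e.exam, e.tracing, e.fiducials[gid], faf, zones, averaging)
            for e in study.eyes
        ]
    return out
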