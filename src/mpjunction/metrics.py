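"""Zone-restricted visual-function metrics and inter-grader comparison measures.

A stimulus is *scotomatous* when the device records the −1 dB raw
"brightest stimulus not seen" value or when its mapped sensitivity is
below 0 dB. Per-eye zone metrics are the mean sensitivity and the
scotomatous count over the stimuli whose signed margin distance falls in
the zone. Because the averaging convention for unseen points is not
standardized, three are supported — floor the −1 sentinel at 0 dB
(default), average the recorded value as-is, or exclude unseen points —
and the convention used is recorded in every report.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError
from .grid import MPExam, MPStimulus
from .lesions import SignedDistanceResult, ZoneSpec, zone_membership


def classify_scotomatous(s: MPStimulus) -> bool:
    """Scotomatous iff raw not-seen or sensitivity < 0 dB (strict)."""
    return bool(s.raw_not_seen or s.sensitivity_db < 0)


class SensitivityAveraging(str, enum.Enum):
    """How unseen (−1 dB sentinel) points enter the zone mean."""

    FLOOR_AT_ZERO = "floor-at-zero"
    AS_RECORDED = "as-recorded"
    EXCLUDE = "exclude"


@dataclass
class StimulusZoneRecord:
    stimulus_id: int
    distance_um: float
    in_zone: bool
    scotomatous: bool
    sensitivity_db: float
    raw_not_seen: bool


@dataclass
class ZoneMetrics:
    """Per-eye functional summary inside one zone.

    ``mean_sensitivity_db`` is None (and ``empty_zone`` True) when no
    stimulus falls inside the zone — an explicitly reported condition,
    never a silent zero.
    """

    eye_id: str
    zone: ZoneSpec
    n_in_zone: int
    mean_sensitivity_db: float | None
    n_scotomatous_in_zone: int
    per_stimulus: list[StimulusZoneRecord]
    averaging: SensitivityAveraging
    empty_zone: bool


def compute_zone_metrics(
    exam: MPExam,
    distances: list[SignedDistanceResult],
    zone: ZoneSpec,
    averaging: SensitivityAveraging = SensitivityAveraging.FLOOR_AT_ZERO,
) -> ZoneMetrics:
    """Mean sensitivity and scotomatous count over in-zone stimuli."""
    dist_by_id = {d.stimulus_id: d for d in distances}
    missing = [s.stimulus_id for s in exam.stimuli if s.stimulus_id not in dist_by_id]
    if missing:
        raise InvalidInputError(f"no signed distance for stimulus ids {missing}")

    records = []
    for s in exam.stimuli:
        d = dist_by_id[s.stimulus_id]
        records.append(StimulusZoneRecord(
            stimulus_id=s.stimulus_id,
            distance_um=d.distance_um,
            in_zone=zone_membership(d, zone),
            scotomatous=classify_scotomatous(s),
            sensitivity_db=s.sensitivity_db,
            raw_not_seen=s.raw_not_seen,
        ))

    in_zone = [r for r in records if r.in_zone]
    if averaging is SensitivityAveraging.EXCLUDE:
        vals = [r.sensitivity_db for r in in_zone if not r.raw_not_seen]
    elif averaging is SensitivityAveraging.FLOOR_AT_ZERO:
        vals = [max(r.sensitivity_db, 0.0) for r in in_zone]
    else:
        vals = [r.sensitivity_db for r in in_zone]

    mean = float(np.mean(vals)) if vals else None
    return ZoneMetrics(
        eye_id=exam.eye_id,
        zone=zone,
        n_in_zone=len(in_zone),
        mean_sensitivity_db=mean,
        n_scotomatous_in_zone=sum(r.scotomatous for r in in_zone),
        per_stimulus=records,
        averaging=averaging,
        empty_zone=not in_zone,
    )


@dataclass
class CoordinateDifferences:
    """Per-stimulus distances between the two graders' transformed coordinates."""

    per_stimulus_um: np.ndarray  # (n,)
    mean_um: float
    sd_um: float


def stimulus_coordinate_differences(
    g1_points_um: np.ndarray, g2_points_um: np.ndarray
) -> CoordinateDifferences:
    """Euclidean distance per matched stimulus, with per-eye mean and SD.

    Stimuli must be matched by position in the arrays (both graders
    transform the same exam, so correspondence is by stimulus_id, never
    nearest-neighbor).
    """
    a = np.asarray(g1_points_um, dtype=float)
    b = np.asarray(g2_points_um, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 2:
        raise InvalidInputError(
            f"matched (n, 2) arrays required, got {a.shape} and {b.shape}"
        )
    d = np.linalg.norm(a - b, axis=1)
    sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    return CoordinateDifferences(per_stimulus_um=d, mean_um=float(np.mean(d)), sd_um=sd)
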