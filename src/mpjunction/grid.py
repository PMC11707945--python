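"""The 10-2 microperimetry stimulus grid and exam containers.

The rectilinear 10-2 pattern places stimuli on the 2°-spaced odd-integer
lattice (x, y ∈ {±1, ±3, ±5, ±7, ±9} degrees, fovea-centered) and keeps
the points with x² + y² ≤ 82 — the unique symmetric radius cutoff on that
lattice yielding the standard 68-point pattern. Stimuli are analyzed as
2-D center points; the Goldmann III diameter (0.43°) is carried as
metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import ImageFrame

#: Squared-radius cutoff (deg²) selecting the 68-point 10-2 pattern from
#: the odd lattice.
_RADIUS_SQ_CUTOFF = 82

#: Goldmann size III stimulus diameter in degrees (metadata only).
GOLDMANN_III_DIAMETER_DEG = 0.43

#: Device decibel range; −1 is the raw "brightest stimulus not seen" sentinel.
DB_MIN, DB_MAX = 0.0, 36.0
NOT_SEEN_SENTINEL = -1.0


def generate_10_2_grid() -> np.ndarray:
    """Return the 68 stimulus centers of the 10-2 grid, degrees, shape (68, 2).

    Ordering is deterministic row-major from the top-left: rows by
    descending y (degrees, y up), then ascending x within a row.
    """
    odd = np.arange(-9, 10, 2)
    pts = [(x, y) for y in odd[::-1] for x in odd if x * x + y * y <= _RADIUS_SQ_CUTOFF]
    return np.array(pts, dtype=float)


@dataclass
class MPStimulus:
    """One microperimetry stimulus: a test location plus its threshold result."""

    stimulus_id: int
    x_deg: float
    y_deg: float
    sensitivity_db: float
    raw_not_seen: bool
    stimulus_diameter_deg: float = GOLDMANN_III_DIAMETER_DEG


@dataclass
class MPExam:
    """A microperimetry exam: the stimulus collection plus its SLO frame."""

    eye_id: str
    visit: str
    stimuli: list[MPStimulus]
    slo_frame: ImageFrame

    @property
    def positions_deg(self) -> np.ndarray:
        return np.array([[s.x_deg, s.y_deg] for s in self.stimuli])

    @property
    def sensitivities_db(self) -> np.ndarray:
        return np.array([s.sensitivity_db for s in self.stimuli])

    @property
    def raw_not_seen(self) -> np.ndarray:
        return np.array([s.raw_not_seen for s in self.stimuli], dtype=bool)

    @property
    def stimulus_ids(self) -> np.ndarray:
        return np.array([s.stimulus_id for s in self.stimuli])


@dataclass
class ValidationReport:
    """Report-only exam validation outcome."""

    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_exam(exam: MPExam, lattice_tol_deg: float = 0.01) -> ValidationReport:
    """Check an exam against the canonical 10-2 contract; never raises.

    Flags a wrong stimulus count, duplicate ids, positions off the
    canonical lattice beyond ``lattice_tol_deg``, and sensitivities
    outside [−1, 36] dB.
    """
    report = ValidationReport()
    n = len(exam.stimuli)
    if n != 68:
        report.issues.append(f"expected 68 stimuli, found {n}")

    ids = exam.stimulus_ids
    if len(np.unique(ids)) != len(ids):
        dupes = sorted({int(i) for i in ids if np.sum(ids == i) > 1})
        report.issues.append(f"duplicate stimulus_ids: {dupes}")

    grid = generate_10_2_grid()
    for s in exam.stimuli:
        d = np.min(np.hypot(grid[:, 0] - s.x_deg, grid[:, 1] - s.y_deg))
        if d > lattice_tol_deg:
            report.issues.append(
                f"stimulus {s.stimulus_id} at ({s.x_deg}, {s.y_deg})° is "
                f"{d:.3f}° off the canonical 10-2 lattice"
            )
        lo = NOT_SEEN_SENTINEL if s.raw_not_seen else DB_MIN
        if not (lo <= s.sensitivity_db <= DB_MAX) or (
            s.raw_not_seen and s.sensitivity_db != NOT_SEEN_SENTINEL
        ):
            report.issues.append(
                f"stimulus {s.stimulus_id}: sensitivity {s.sensitivity_db} dB outside "
                f"[{DB_MIN:g}, {DB_MAX:g}] (or sentinel mismatch with raw_not_seen)"
            )
    return report


def exam_from_grid(
    eye_id: str,
    visit: str,
    sensitivities_db: np.ndarray,
    raw_not_seen: np.ndarray,
    slo_frame: ImageFrame,
) -> MPExam:
    """Assemble an exam on the canonical grid from measurement vectors."""
    grid = generate_10_2_grid()
    stimuli = [
        MPStimulus(i, float(x), float(y), float(s), bool(ns))
        for i, ((x, y), s, ns) in enumerate(zip(grid, sensitivities_db, raw_not_seen))
    ]
    return MPExam(eye_id=eye_id, visit=visit, stimuli=stimuli, slo_frame=slo_frame)
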