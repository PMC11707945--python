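"""File formats: exams (CSV), lesion tracings (GeoJSON), fiducials (CSV),
transforms and reports (JSON).

All tabular files are UTF-8 delimited text with '.' decimals; tracing
coordinates are stored in FAF pixels with the frame metadata alongside
and converted to μm on load. Report writers embed the run configuration
and package version so every output is self-describing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping

from . import __version__
from .exceptions import InvalidGeometryError, ParseError
from .frames import ImageFrame
from .grid import MPExam, MPStimulus, validate_exam
from .lesions import GAFocus, LesionTracing
from .metrics import SensitivityAveraging
from .registration import FiducialPairSet, SimilarityTransform
from .repeatability import RepeatabilityReport

EXAM_COLUMNS = ["stimulus_id", "x_deg", "y_deg", "sensitivity_db", "raw_not_seen"]
FIDUCIAL_COLUMNS = ["pair_id", "src_x_px", "src_y_px", "dst_x_px", "dst_y_px",
                    "grader_id", "eye_id"]


# ---------------------------------------------------------------------------
# frames


def frame_to_dict(frame: ImageFrame) -> dict:
    return {
        "field_of_view_deg": frame.field_of_view_deg,
        "pixel_dims": int(frame.pixel_dims),
        "um_per_degree": frame.um_per_degree,
        "name": frame.name,
    }


def frame_from_dict(d: dict) -> ImageFrame:
    try:
        return ImageFrame(float(d["field_of_view_deg"]), int(d["pixel_dims"]),
                          float(d.get("um_per_degree", 291.0)), str(d.get("name", "")))
    except KeyError as e:
        raise ParseError(f"frame metadata missing key {e}") from e


# ---------------------------------------------------------------------------
# MP exams


def write_exam(exam: MPExam, path: str | Path) -> None:
    path = Path(path)
    header = [
        f"# eye_id: {exam.eye_id}",
        f"# visit: {exam.visit}",
        f"# slo_frame: {json.dumps(frame_to_dict(exam.slo_frame))}",
    ]
    rows = [
        f"{s.stimulus_id},{s.x_deg:g},{s.y_deg:g},{s.sensitivity_db:g},{int(s.raw_not_seen)}"
        for s in exam.stimuli
    ]
    path.write_text("\n".join(header + [",".join(EXAM_COLUMNS)] + rows) + "\n",
                    encoding="utf-8")


def read_exam(path: str | Path, slo_frame: ImageFrame | None = None) -> MPExam:
    """Load an exam file; surfaces (but does not fail on) validation issues.

    Header comment lines ``# key: value`` carry eye/visit/frame metadata;
    an explicit ``slo_frame`` argument overrides the embedded one.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition(":")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    try:
        df = pd.read_csv(path, skiprows=body_start)
    except Exception as e:
        raise ParseError(f"{path}: unreadable exam table ({e})") from e
    missing = [c for c in EXAM_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in EXAM_COLUMNS:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ParseError(f"{path}: non-numeric value in column {col!r}, row {bad[0] + 1}")
    ids = df["stimulus_id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        dupes = sorted(set(int(i) for i in ids if (ids == i).sum() > 1))
        raise ParseError(f"{path}: duplicate stimulus_ids {dupes}")
    if slo_frame is None:
        if "slo_frame" not in meta:
            raise ParseError(f"{path}: no '# slo_frame:' header and no frame argument")
        slo_frame = frame_from_dict(json.loads(meta["slo_frame"]))
    stimuli = [
        MPStimulus(int(r.stimulus_id), float(r.x_deg), float(r.y_deg),
                   float(r.sensitivity_db), bool(int(r.raw_not_seen)))
        for r in df.itertuples()
    ]
    exam = MPExam(meta.get("eye_id", path.stem), meta.get("visit", ""), stimuli, slo_frame)
    report = validate_exam(exam)
    if not report.ok:
        import logging
        logging.getLogger(__name__).warning("%s: %s", path, "; ".join(report.issues))
    return exam


# ---------------------------------------------------------------------------
# lesion tracings (GeoJSON, FAF pixel coordinates)


def write_tracing(tracing: LesionTracing, path: str | Path, faf_frame: ImageFrame) -> None:
    upp = faf_frame.um_per_pixel
    features = []
    for f in tracing.foci:
        ring_px = (np.vstack([f.vertices_um, f.vertices_um[:1]]) / upp).tolist()
        features.append({
            "type": "Feature",
            "properties": {"focus_id": f.focus_id},
            "geometry": {"type": "Polygon", "coordinates": [ring_px]},
        })
    doc = {
        "type": "FeatureCollection",
        "properties": {
            "eye_id": tracing.eye_id,
            "min_focus_area_mm2": tracing.min_focus_area_mm2,
            "faf_frame": frame_to_dict(faf_frame),
            "coordinate_units": "faf_pixels",
        },
        "features": features,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def read_tracing(path: str | Path) -> tuple[LesionTracing, ImageFrame]:
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}: invalid JSON ({e})") from e
    props = doc.get("properties", {})
    if "faf_frame" not in props:
        raise ParseError(f"{path}: missing faf_frame metadata")
    frame = frame_from_dict(props["faf_frame"])
    upp = frame.um_per_pixel
    foci = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise ParseError(f"{path}: feature {i} is not a Polygon")
        ring = np.asarray(geom["coordinates"][0], dtype=float)
        if len(ring) < 4 or not np.allclose(ring[0], ring[-1]):
            raise ParseError(f"{path}: feature {i}: ring must be closed with ≥ 3 vertices")
        focus_id = str(feat.get("properties", {}).get("focus_id", f"F{i}"))
        try:
            foci.append(GAFocus(vertices_um=ring[:-1] * upp, focus_id=focus_id))
        except InvalidGeometryError as e:
            raise ParseError(f"{path}: feature {i}: {e}") from e
    tracing = LesionTracing(
        foci=foci, eye_id=str(props.get("eye_id", path.stem)),
        min_focus_area_mm2=float(props.get("min_focus_area_mm2", 0.05)),
    )
    return tracing, frame


# ---------------------------------------------------------------------------
# fiducials


def write_fiducials(pairs: FiducialPairSet, path: str | Path) -> None:
    rows = [",".join(FIDUCIAL_COLUMNS)]
    for i, (s, t) in enumerate(zip(pairs.source_px, pairs.target_px)):
        pid = int(pairs.pair_ids[i])
        rows.append(f"{pid},{s[0]:.6f},{s[1]:.6f},{t[0]:.6f},{t[1]:.6f},"
                    f"{pairs.grader_id},{pairs.eye_id}")
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def read_fiducials(path: str | Path) -> FiducialPairSet:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as e:
        raise ParseError(f"{path}: unreadable fiducial table ({e})") from e
    missing = [c for c in FIDUCIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    graders = df["grader_id"].unique()
    eyes = df["eye_id"].unique()
    if len(graders) != 1 or len(eyes) != 1:
        raise ParseError(f"{path}: expected one grader and one eye per file")
    return FiducialPairSet(
        source_px=df[["src_x_px", "src_y_px"]].to_numpy(float),
        target_px=df[["dst_x_px", "dst_y_px"]].to_numpy(float),
        grader_id=str(graders[0]), eye_id=str(eyes[0]),
        pair_ids=df["pair_id"].to_numpy(int),
    )


# ---------------------------------------------------------------------------
# transforms and reports


def write_transform(t: SimilarityTransform, path: str | Path, rmse: float | None = None,
                    source_frame: str = "SLO", target_frame: str = "FAF") -> None:
    doc = {
        "scale": t.scale, "rotation_rad": t.rotation,
        "tx": t.translation[0], "ty": t.translation[1],
        "source_frame": source_frame, "target_frame": target_frame,
        "rmse": rmse, "package_version": __version__,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def read_transform(path: str | Path) -> SimilarityTransform:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return SimilarityTransform(float(doc["scale"]), float(doc["rotation_rad"]),
                               (float(doc["tx"]), float(doc["ty"])))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, SensitivityAveraging):
        return obj.value
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report, path: str | Path, run_config: dict | None = None) -> None:
    """Serialize any analysis dataclass to JSON with provenance attached."""
    doc = {
        "package": "mpjunction",
        "package_version": __version__,
        "run_config": _jsonable(run_config) if run_config else None,
        "report": _jsonable(report),
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# Bland–Altman plot (optional output)


def plot_bland_altman(report: RepeatabilityReport, means, diffs, path: str | Path,
                      title: str = "") -> None:
    """Render the classic Bland–Altman scatter with bias, LOA and LOA CIs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(means, diffs, s=18, color="tab:blue", zorder=3)
    ax.axhline(report.bias, color="tab:blue", ls="--", label=f"bias {report.bias:.2f}")
    for loa, ci in ((report.loa_lower, report.loa_lower_ci),
                    (report.loa_upper, report.loa_upper_ci)):
        ax.axhline(loa, color="tab:red", ls="--")
        if ci is not None:
            ax.axhspan(ci[0], ci[1], color="tab:red", alpha=0.15)
    ax.set_xlabel(f"mean of graders ({report.units})")
    ax.set_ylabel(f"grader 1 − grader 2 ({report.units})")
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
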