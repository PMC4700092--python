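"""File formats and the simulate -> quantify -> analyze pipeline.

Images travel as 16-bit grayscale PNG with a JSON sidecar carrying the
acquisition metadata (time post-injection, duration, pixel size, seed), or
as planar nuclear-medicine DICOM (read-only).  Cohort measurements are tidy
CSV (comma, UTF-8, '.' decimal, header row); analysis output is one results
CSV plus a JSON report.  Every output embeds the seed and a hash of the run
configuration so re-running a configuration reproduces all stochastic
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import phantom
from .analysis import evaluate_margin, exceedance_counts, fit_time_model
from .exceptions import FormatError, StageError, ValidationError
from .quantify import PlanarImage, RoiSet, auto_mediastinal_roi, measure_scan

SIDECAR_REQUIRED = ("time_pi_min",)
SIDECAR_OPTIONAL = {"duration_min": 10.0, "pixel_size_mm": 2.4}
_CSV_FLOAT = "%.10g"


def sidecar_path(image_path: str | Path) -> Path:
    return Path(image_path).with_suffix(".json")


def write_planar_image(path: str | Path, image: PlanarImage) -> Path:
    """Write a frame as 16-bit grayscale PNG plus its JSON sidecar.

    PNG stores integers, so counts must be integer-valued (Poisson frames
    are); noiseless expectation images should be quantified in memory or
    rounded explicitly by the caller.
    """
    path = Path(path)
    counts = image.counts
    if not np.allclose(counts, np.round(counts), atol=0):
        raise FormatError(
            "counts are not integer-valued; 16-bit PNG stores integers "
            "(quantify noiseless frames in memory instead)"
        )
    if counts.max() > np.iinfo(np.uint16).max:
        raise FormatError("counts exceed the 16-bit range")
    iio.imwrite(path, counts.astype(np.uint16), extension=".png")
    meta = {
        "time_pi_min": image.time_min,
        "duration_min": image.duration_min,
        "pixel_size_mm": image.pixel_size_mm,
        "seed": image.meta.get("seed"),
        "noiseless": bool(image.meta.get("noiseless", False)),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_planar_image(path: str | Path) -> PlanarImage:
    """Read a planar frame from PNG+sidecar or planar DICOM."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        return _read_dicom(path)
    try:
        counts = np.asarray(iio.imread(path)).astype(float)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read image {path.name}: {exc}") from exc
    sc = sidecar_path(path)
    if not sc.exists():
        raise FormatError(f"missing JSON sidecar for {path.name}", field="sidecar")
    meta = json.loads(sc.read_text())
    for fld in SIDECAR_REQUIRED:
        if fld not in meta or meta[fld] is None:
            raise FormatError(f"sidecar of {path.name} misses required field {fld!r}", field=fld)
    return PlanarImage(
        counts=counts,
        time_min=float(meta["time_pi_min"]),
        duration_min=float(meta.get("duration_min", SIDECAR_OPTIONAL["duration_min"])),
        pixel_size_mm=float(meta.get("pixel_size_mm", SIDECAR_OPTIONAL["pixel_size_mm"])),
        meta={"seed": meta.get("seed"), "noiseless": meta.get("noiseless", False)},
    )


def _hhmmss_to_min(value: str) -> float:
    value = str(value)
    h, m = int(value[0:2]), int(value[2:4])
    s = float(value[4:]) if len(value) > 4 else 0.0
    return h * 60.0 + m + s / 60.0


def _read_dicom(path: Path) -> PlanarImage:
    import pydicom

    ds = pydicom.dcmread(path)
    counts = ds.pixel_array.astype(float)
    if counts.ndim == 3:  # multi-frame planar: first frame
        counts = counts[0]
    acq = getattr(ds, "AcquisitionTime", None)
    rad_seq = getattr(ds, "RadiopharmaceuticalInformationSequence", None)
    start = getattr(rad_seq[0], "RadiopharmaceuticalStartTime", None) if rad_seq else None
    if acq is None or start is None:
        missing = "AcquisitionTime" if acq is None else "RadiopharmaceuticalStartTime"
        raise FormatError(
            f"DICOM {path.name} misses {missing}; acquisition time post-injection "
            "is required for washout analysis",
            field=missing,
        )
    time_min = _hhmmss_to_min(acq) - _hhmmss_to_min(start)
    if time_min < 0:
        time_min += 24 * 60.0
    duration_ms = getattr(ds, "ActualFrameDuration", None)
    duration_min = float(duration_ms) / 60000.0 if duration_ms else 10.0
    spacing = getattr(ds, "PixelSpacing", [2.4, 2.4])
    return PlanarImage(
        counts=counts,
        time_min=time_min,
        duration_min=duration_min,
        pixel_size_mm=float(spacing[0]),
        meta={"source": "dicom"},
    )


# ---------------------------------------------------------------------------
# cohort tabulation


def tabulate_cohort(
    cohort: phantom.Cohort,
    rois: RoiSet | None = None,
    auto_mediastinum: bool = True,
) -> pd.DataFrame:
    """Quantify every frame of a simulated cohort into a tidy table.

    When ``auto_mediastinum`` is on, the mediastinal rectangle is placed on
    each patient's first late frame from the lung/heart landmarks and
    propagated to that patient's other frames (ROIs are drawn once per
    patient, as in clinical reading).  The heart polygon is the phantom's
    full-disk polygon unless an explicit ROI set is supplied.
    """
    rows = []
    for series in cohort.patients:
        if rois is not None:
            patient_rois = rois
        else:
            if not auto_mediastinum:
                raise ValidationError("either supply rois or enable auto_mediastinum")
            # place on the first late (>= 30 min) frame, else the first frame
            ref_idx = next(
                (i for i, f in enumerate(series.frames) if f.time_min >= 30), 0
            )
            heart_poly = _heart_polygon_for(cohort)
            rect = auto_mediastinal_roi(series.frames[ref_idx], heart_poly)
            patient_rois = RoiSet(heart_polygon=heart_poly, mediastinum_rect=rect)
        for label, frame in zip(series.labels, series.frames):
            m = measure_scan(frame, patient_rois)
            rows.append(
                {
                    "patient_id": series.patient_id,
                    "aetiology": series.aetiology,
                    "time_label": label,
                    "actual_min": frame.time_min,
                    "H": m.heart,
                    "M": m.mediastinum,
                    "hm_ratio": m.hm_ratio,
                }
            )
    return pd.DataFrame(rows)


def _heart_polygon_for(cohort: phantom.Cohort) -> np.ndarray:
    # the cohort shares one geometry; rebuild its default polygon
    return phantom.default_geometry(cohort.patients[0].frames[0].shape[0]).heart_polygon()


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    out_dir: str | Path = "mibg_run"
    seed: int = 0
    n: int = 49
    noise: bool = True
    reference: str = "4h"
    margin: float = 0.10
    calibrate: bool = True
    hm_targets: dict = field(
        default_factory=lambda: {60.0: 1.60, 120.0: 1.56, 180.0: 1.53, 240.0: 1.52}
    )
    images_dir: str | Path | None = None  # ingest mode: read frames instead of simulating
    rois_file: str | Path | None = None
    matrix: int = 256

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in dataclasses.asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _ingest_table(config: RunConfig) -> pd.DataFrame:
    images_dir = Path(config.images_dir)
    paths = sorted(images_dir.glob("*.png")) + sorted(images_dir.glob("*.dcm"))
    if not paths:
        raise StageError(f"quantify: no images in {images_dir}")
    if config.rois_file is None:
        raise StageError("quantify: ingest mode requires an ROI file")
    rois = RoiSet.from_json(config.rois_file)
    rows = []
    for p in paths:
        img = read_planar_image(p)
        m = measure_scan(img, rois)
        pid, _, label = p.stem.partition("_")
        rows.append(
            {
                "patient_id": pid,
                "aetiology": "unknown",
                "time_label": label or phantom._nearest_label(img.time_min),
                "actual_min": img.time_min,
                "H": m.heart,
                "M": m.mediastinum,
                "hm_ratio": m.hm_ratio,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Simulate (or ingest), quantify, and analyze in one reproducible run.

    Writes ``cohort.csv`` (per-scan measurements), ``results.csv`` (one row
    per contrast), and ``report.json`` to ``config.out_dir``; returns the
    report as a dictionary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.images_dir is not None:
        table = _ingest_table(config)
    else:
        try:
            geometry, kinetics = phantom.default_phantom(config.matrix)
            if config.calibrate:
                kinetics = phantom.calibrate_to_hm_targets(
                    config.hm_targets, geometry, kinetics
                ).kinetics
            spec = phantom.CohortSpec(n=config.n, noise=config.noise, seed=config.seed)
            cohort = phantom.simulate_cohort(spec, geometry, kinetics)
        except Exception as exc:
            raise StageError(f"simulate: {exc}") from exc
        try:
            table = tabulate_cohort(cohort)
        except Exception as exc:
            raise StageError(f"quantify: {exc}") from exc

    cohort_csv = out / "cohort.csv"
    table.to_csv(cohort_csv, index=False, float_format=_CSV_FLOAT)

    try:
        late = [lab for lab in table["time_label"].unique() if lab != "early"]
        result = fit_time_model(table, reference=config.reference, include=late)
        margin_eval = evaluate_margin(result, margin=config.margin)
        exceed = exceedance_counts(
            table[table["time_label"].isin(late)],
            reference=config.reference,
            margin=config.margin,
        )
    except Exception as exc:
        raise StageError(f"analyze: {exc}") from exc

    results = result.contrasts.join(margin_eval.table[["exceeds_margin", "ci_contains_margin"]])
    results.to_csv(out / "results.csv", float_format=_CSV_FLOAT)

    report = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_scans": int(len(table)),
        "n_patients": int(table["patient_id"].nunique()),
        "reference": config.reference,
        "margin": config.margin,
        "verdict": margin_eval.verdict,
        "contrasts": {
            lab: {
                "estimate": round(row["estimate"], 10),
                "ci_low": round(row["ci_low"], 10),
                "ci_high": round(row["ci_high"], 10),
                "p": round(row["p"], 10),
                "exceeds_margin": bool(margin_eval.table.loc[lab, "exceeds_margin"]),
                "ci_contains_margin": bool(margin_eval.table.loc[lab, "ci_contains_margin"]),
            }
            for lab, row in result.contrasts.iterrows()
        },
        "exceedance": {
            lab: {
                "n_exceeding": int(row["n_exceeding"]),
                "n_pairs": int(row["n_pairs"]),
                "percent": round(row["percent"], 6),
            }
            for lab, row in exceed.iterrows()
        },
        "variance_components": {
            "patient_intercept": round(result.var_patient, 10),
            "residual": round(result.var_residual, 10),
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
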