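"""Semi-quantification of planar cardiac MIBG images.

Implements the clinical analysis convention: a polygonal cardiac region of
interest (drawn over the myocardium, left-ventricular cavity included) and a
rectangular upper-mediastinal ROI placed from anatomical landmarks (lung
apex, upper cardiac border, medial lung contours).  From the two ROIs the
heart-to-mediastinum (H/M) ratio is the ratio of mean count densities
(counts/pixel), and the washout rate between an early and a late scan is the
percentage loss of background-subtracted myocardial counts after restoring
physical decay of the tracer:

    WR = [(He - Me) - (Hl - Ml) * c] / (He - Me) * 100,
    c  = 2 ** (dt / t_half_physical)

with dt the actual (metadata) time between the two acquisitions.

Coordinate conventions, fixed throughout the package:

* images are indexed ``[row, col]``, 0-based; row 0 is superior and the
  patient's left is image right (anterior view);
* a pixel ``(r, c)`` belongs to a polygon iff its centre ``(r+0.5, c+0.5)``
  is strictly inside under the even-odd rule;
* rectangles are half-open index ranges ``(row_start, row_stop, col_start,
  col_stop)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .exceptions import RoiPlacementError, ValidationError

#: physical half-life of 123-iodine in minutes (13.22 h)
I123_T_HALF_MIN = 793.4


@dataclass
class PlanarImage:
    """A single anterior planar acquisition.

    Parameters
    ----------
    counts
        Square count matrix (non-negative; integer-valued when Poisson
        noise was applied, real-valued for noiseless expectation images).
    time_min
        Acquisition time post-injection in minutes.
    duration_min
        Acquisition duration in minutes.
    pixel_size_mm
        Pixel pitch in millimetres.
    meta
        Free-form provenance (seed, noiseless flag, ...).
    """

    counts: np.ndarray
    time_min: float
    duration_min: float = 10.0
    pixel_size_mm: float = 2.4
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if self.time_min < 0:
            raise ValidationError("acquisition time must be >= 0")
        if self.duration_min <= 0:
            raise ValidationError("acquisition duration must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class RoiSet:
    """Cardiac polygon plus mediastinal rectangle, in pixel coordinates."""

    heart_polygon: np.ndarray  # (k, 2) array of (row, col) vertices
    mediastinum_rect: tuple[int, int, int, int]  # half-open (r0, r1, c0, c1)

    def __post_init__(self):
        self.heart_polygon = np.asarray(self.heart_polygon, dtype=float)
        if self.heart_polygon.ndim != 2 or self.heart_polygon.shape[1] != 2:
            raise ValidationError("heart polygon must be a (k, 2) vertex array")
        if len(self.heart_polygon) < 3:
            raise ValidationError("heart polygon needs at least 3 vertices")
        r0, r1, c0, c1 = self.mediastinum_rect
        if r1 <= r0 or c1 <= c0:
            raise ValidationError("mediastinal rectangle is empty")

    def validate_against(self, shape: tuple[int, int]) -> None:
        r0, r1, c0, c1 = self.mediastinum_rect
        if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
            raise ValidationError("mediastinal rectangle lies outside the image")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "convention": "row-col 0-based; polygon pixel-centre even-odd; rect half-open",
            "heart_polygon": self.heart_polygon.tolist(),
            "mediastinum_rect": list(self.mediastinum_rect),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RoiSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            heart_polygon=np.asarray(payload["heart_polygon"], dtype=float),
            mediastinum_rect=tuple(payload["mediastinum_rect"]),
        )


@dataclass
class ScanMeasurement:
    """Mean count densities and H/M ratio of one scan.

    ``heart``/``mediastinum`` are the He/Hl and Me/Ml quantities of the
    washout formula, depending on whether the scan is early or late.
    """

    heart: float
    mediastinum: float
    time_min: float
    hm_ratio: float = field(init=False)

    def __post_init__(self):
        self.hm_ratio = hm_ratio(self.heart, self.mediastinum)


@dataclass
class WashoutResult:
    """Decay- and background-corrected washout between two scans."""

    wr_percent: float
    decay_correction: float
    delta_min: float
    early: ScanMeasurement
    late: ScanMeasurement


def rasterize_polygon(vertices: Sequence, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centres fall strictly inside a polygon.

    Even-odd (crossing-number) rule on pixel centres ``(r+0.5, c+0.5)``;
    centres exactly on an edge are excluded.  Orientation of the vertex
    list is irrelevant.  Deterministic by construction.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValidationError("polygon must be a (k>=3, 2) vertex array")
    # shoelace area to reject degenerate polygons
    r, c = verts[:, 0], verts[:, 1]
    area2 = np.abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))
    if area2 == 0:
        raise ValidationError("degenerate (zero-area) polygon")

    nrow, ncol = shape
    rr = np.arange(nrow, dtype=float)[:, None] + 0.5
    cc = np.arange(ncol, dtype=float)[None, :] + 0.5

    inside = np.zeros(shape, dtype=bool)
    r1, c1 = verts[:, 0], verts[:, 1]
    r2, c2 = np.roll(r1, -1), np.roll(c1, -1)
    # cast a ray along +col; count strict crossings with half-open edges in row
    for y1, x1, y2, x2 in zip(r1, c1, r2, c2):
        if y1 == y2:
            continue
        crosses = (y1 > rr) != (y2 > rr)  # (nrow, 1)
        x_at = x1 + (rr - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (cc < x_at)
    return inside


def rect_mask(rect: tuple[int, int, int, int], shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of a half-open rectangle."""
    r0, r1, c0, c1 = rect
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = True
    return mask


def mean_count_density(image: PlanarImage, pixels: np.ndarray) -> float:
    """Arithmetic mean of counts over a pixel set (counts/pixel).

    ``pixels`` is a boolean mask of the image grid.  ROIs touching the
    image border are averaged as-is, without padding.
    """
    pixels = np.asarray(pixels, dtype=bool)
    if pixels.shape != image.shape:
        raise ValidationError("pixel mask shape does not match the image")
    n = int(pixels.sum())
    if n == 0:
        raise ValidationError("empty pixel set")
    return float(image.counts[pixels].mean())


def hm_ratio(heart: float, mediastinum: float) -> float:
    """Heart-to-mediastinum ratio of mean count densities."""
    if mediastinum <= 0:
        raise ValidationError("mediastinal mean count density must be > 0")
    return float(heart) / float(mediastinum)


def measure_scan(image: PlanarImage, rois: RoiSet) -> ScanMeasurement:
    """Apply an ROI set to one image and return its measurement."""
    rois.validate_against(image.shape)
    heart_mask = rasterize_polygon(rois.heart_polygon, image.shape)
    if not heart_mask.any():
        raise ValidationError("heart polygon rasterizes to an empty pixel set")
    med_mask = rect_mask(rois.mediastinum_rect, image.shape)
    return ScanMeasurement(
        heart=mean_count_density(image, heart_mask),
        mediastinum=mean_count_density(image, med_mask),
        time_min=image.time_min,
    )


def auto_mediastinal_roi(
    image: PlanarImage,
    heart_polygon: Sequence,
    low_fraction: float = 0.35,
    min_region_px: int = 50,
    smoothing_sigma: float = 1.5,
) -> tuple[int, int, int, int]:
    """Place the upper-mediastinal rectangle from anatomical landmarks.

    The lungs are detected as the two largest connected low-count regions
    (counts below ``low_fraction`` of the 99th-percentile image value,
    4-connectivity) that do not touch the image border (the air around the
    body is also low-count but reaches the border).  The rectangle is then

    * top row: the lung apex (smallest row index of either lung);
    * bottom row: the topmost row of the rasterized heart polygon minus 1
      (the upper cardiac border);
    * columns: the gap between the medial lung contours at the rectangle's
      mid-height, shrunk by a 1-pixel safety margin on each side.

    Counting noise is suppressed with a light Gaussian smoothing
    (``smoothing_sigma`` pixels) before thresholding; the smoothed image is
    used only for landmark detection, never for quantification.

    Raises :class:`RoiPlacementError` when the landmarks cannot be found,
    prompting a manual ROI.
    """
    counts = image.counts
    if smoothing_sigma > 0:
        counts = ndimage.gaussian_filter(counts, smoothing_sigma)
    threshold = low_fraction * np.percentile(counts, 99)
    low = counts < threshold
    if not low.any():
        raise RoiPlacementError("no low-count regions: lungs not detectable")
    # seal thin noise-induced channels between the lungs and the air
    # around the body before labelling
    rr, cc = np.mgrid[-3:4, -3:4]
    footprint = rr**2 + cc**2 <= 9
    low = ~ndimage.binary_closing(~low, structure=footprint)

    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    labels, nlab = ndimage.label(low, structure=structure)
    border_labels = set(np.unique(labels[0, :])) | set(np.unique(labels[-1, :]))
    border_labels |= set(np.unique(labels[:, 0])) | set(np.unique(labels[:, -1]))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, nlab + 1))
    candidates = [
        lab
        for lab in range(1, nlab + 1)
        if lab not in border_labels and sizes[lab - 1] >= min_region_px
    ]
    if len(candidates) < 2:
        raise RoiPlacementError("fewer than two interior low-count regions: lungs not found")
    candidates.sort(key=lambda lab: sizes[lab - 1], reverse=True)
    lung_a, lung_b = candidates[:2]
    # order left/right by column centroid
    com_a = ndimage.center_of_mass(labels == lung_a)
    com_b = ndimage.center_of_mass(labels == lung_b)
    if com_a[1] > com_b[1]:
        lung_a, lung_b = lung_b, lung_a
    left_mask = labels == lung_a
    right_mask = labels == lung_b

    apex_row = int(min(np.argwhere(left_mask)[:, 0].min(), np.argwhere(right_mask)[:, 0].min()))
    heart_mask = rasterize_polygon(heart_polygon, image.shape)
    if not heart_mask.any():
        raise RoiPlacementError("heart polygon rasterizes to an empty pixel set")
    heart_top = int(np.argwhere(heart_mask)[:, 0].min())
    row_stop = heart_top  # bottom row inclusive = heart_top - 1
    if row_stop <= apex_row:
        raise RoiPlacementError("upper cardiac border lies at or above the lung apex")

    mid_row = (apex_row + row_stop - 1) // 2
    left_cols = np.where(left_mask[mid_row])[0]
    right_cols = np.where(right_mask[mid_row])[0]
    if left_cols.size == 0 or right_cols.size == 0:
        raise RoiPlacementError("lungs do not span the rectangle mid-height")
    medial_left = int(left_cols.max())
    medial_right = int(right_cols.min())
    col_start = medial_left + 2  # gap start + 1-pixel margin
    col_stop = medial_right - 1  # half-open; inclusive end = gap end - 1
    if col_stop <= col_start:
        raise RoiPlacementError("medial lung contours leave no mediastinal gap")
    return (apex_row, row_stop, col_start, col_stop)


def washout_rate(
    early: ScanMeasurement,
    late: ScanMeasurement,
    t_half_physical: float = I123_T_HALF_MIN,
) -> WashoutResult:
    """Background-subtracted, decay-corrected washout rate in percent.

    The decay factor ``c = 2**(dt / t_half_physical)`` restores the counts
    the late image lost to physical decay; it multiplies the
    background-subtracted late counts ``(Hl - Ml)``.  ``dt`` uses the
    actual acquisition times attached to the measurements.
    """
    if t_half_physical <= 0:
        raise ValidationError("physical half-life must be > 0")
    dt = late.time_min - early.time_min
    if dt <= 0:
        raise ValidationError("late scan must be acquired after the early scan")
    he_me = early.heart - early.mediastinum
    if he_me <= 0:
        raise ValidationError("He - Me must be > 0 for the washout denominator")
    c = 2.0 ** (dt / t_half_physical)
    wr = ((he_me) - (late.heart - late.mediastinum) * c) / he_me * 100.0
    return WashoutResult(
        wr_percent=float(wr),
        decay_correction=float(c),
        delta_min=float(dt),
        early=early,
        late=late,
    )
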