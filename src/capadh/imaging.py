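"""Extraction of physical coordinates from backlit silhouette frames.

The experimental scene is a dark silhouette (fiber + meniscus + liquid bulk)
against a bright luminescent screen.  This module turns frames into physical
coordinates: the meniscus flank edge points, the flat-baseline height, the
tip contact radius, the fiber tip position, and (bending mode) the angle
between fiber and liquid surface.

Conventions: image row 0 is the top; physical y increases upward with
``y = (n_rows - 1 - row) * pixel_scale``; x = column * pixel_scale.  All
edges are refined to subpixel precision by linear interpolation of the
threshold crossing, which can never move a point by more than one pixel
from its integer detection.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from skimage import feature as _skfeature
from skimage import filters as _skfilters
from skimage import measure as _skmeasure

from .errors import (
    AngleMeasurementError,
    BaselineDetectionError,
    DataError,
    ThresholdingError,
    TrackingLostError,
)

__all__ = [
    "Frame",
    "Silhouette",
    "MeniscusLocation",
    "extract_silhouette",
    "locate_meniscus",
    "locate_fiber_tip",
    "track_tip",
    "measure_bending_angle",
    "load_sequence",
    "read_manual_points",
]


@dataclass
class Frame:
    """One grayscale frame with acquisition metadata."""

    image: np.ndarray
    timestamp: float
    stage_position: float
    pixel_scale: float

    def __post_init__(self):
        self.image = np.asarray(self.image)
        if self.image.ndim != 2 or self.image.size == 0:
            raise DataError("frame raster must be a non-empty 2D array")
        if self.pixel_scale <= 0:
            raise DataError("pixel_scale must be positive")

    @property
    def n_rows(self) -> int:
        return self.image.shape[0]

    @property
    def n_cols(self) -> int:
        return self.image.shape[1]

    def y_of_row(self, row):
        """Physical height (m) of a (possibly fractional) row index."""
        return (self.n_rows - 1 - np.asarray(row, dtype=float)) * self.pixel_scale

    def x_of_col(self, col):
        return np.asarray(col, dtype=float) * self.pixel_scale


@dataclass
class Silhouette:
    """Binary silhouette of a frame plus its ordered boundary contour."""

    mask: np.ndarray
    edge_points: np.ndarray  # (n, 2) physical (x, y), ordered along contour
    threshold: float
    frame: Frame = field(repr=False)


@dataclass
class MeniscusLocation:
    """Meniscus features of one silhouette.

    ``flank_points`` are (x, y) in metres with y relative to the detected
    baseline; empty for a flat surface.  ``connected`` reports whether the
    liquid is attached to the fiber (pre-snap-off).
    """

    flank_points: np.ndarray
    baseline_y: float
    r_tip: float | None
    axis_x: float | None
    connected: bool


def extract_silhouette(frame: Frame, threshold="auto") -> Silhouette:
    """Threshold the backlit frame into a dark-foreground silhouette.

    ``threshold="auto"`` picks Otsu's threshold and raises
    :class:`ThresholdingError` when the histogram is not bimodal enough to
    separate foreground from background (suggesting a fixed threshold).
    """
    img = frame.image.astype(float)
    if threshold == "auto":
        if img.std() < 1e-9:
            raise ThresholdingError(
                "uniform image: no bimodal histogram; pass a fixed threshold"
            )
        thr = float(_skfilters.threshold_otsu(img))
        fg = img < thr
        frac = fg.mean()
        if not 1e-4 < frac < 1 - 1e-4 or (img[~fg].mean() - img[fg].mean()) < 5:
            raise ThresholdingError(
                "histogram not bimodal (foreground/background separation "
                "too weak); pass a fixed threshold"
            )
    else:
        thr = float(threshold)
        fg = img < thr
    contours = _skmeasure.find_contours(img, level=thr)
    if contours:
        longest = max(contours, key=len)
        edge = np.column_stack(
            [frame.x_of_col(longest[:, 1]), frame.y_of_row(longest[:, 0])]
        )
    else:
        edge = np.empty((0, 2))
    return Silhouette(mask=fg, edge_points=edge, threshold=thr, frame=frame)


# -- subpixel crossing helpers ----------------------------------------------


def _cross_down(profile: np.ndarray, idx: int, thr: float) -> float:
    """Subpixel position of the bright->dark crossing between idx-1 and idx."""
    if idx <= 0:
        return float(idx)
    a, b = profile[idx - 1], profile[idx]
    if b == a:
        return float(idx)
    t = (a - thr) / (a - b)
    return idx - 1 + float(np.clip(t, 0.0, 1.0))


def _cross_up(profile: np.ndarray, idx: int, thr: float) -> float:
    """Subpixel position of the dark->bright crossing between idx and idx+1."""
    if idx >= len(profile) - 1:
        return float(idx)
    a, b = profile[idx], profile[idx + 1]
    if b == a:
        return float(idx)
    t = (thr - a) / (b - a)
    return idx + float(np.clip(t, 0.0, 1.0))


def _run_around(maskrow: np.ndarray, col: int):
    """(start, stop) of the contiguous True run containing ``col``, or None."""
    if not maskrow[col]:
        return None
    lo = col
    while lo > 0 and maskrow[lo - 1]:
        lo -= 1
    hi = col
    while hi < len(maskrow) - 1 and maskrow[hi + 1]:
        hi += 1
    return lo, hi


def _bottom_run_top(maskcol: np.ndarray) -> int | None:
    """Top row index of the dark run connected to the bottom of the frame."""
    if not maskcol[-1]:
        return None
    r = len(maskcol) - 1
    while r > 0 and maskcol[r - 1]:
        r -= 1
    return r


def locate_meniscus(sil: Silhouette, baseline_hint: float | None = None
                    ) -> MeniscusLocation:
    """Split the silhouette into baseline, meniscus flanks and tip contact.

    The flat far-field liquid surface (columns away from the axis) gives the
    baseline height; the silhouette width at the fiber--liquid junction gives
    the contact radius r_tip; rows between give the two flank edge points of
    the meniscus meridian, sampled row-wise with subpixel refinement (robust
    for the near-vertical flanks of slender menisci).
    """
    frame = sil.frame
    img = frame.image.astype(float)
    mask = sil.mask
    thr = sil.threshold
    nrows, ncols = mask.shape

    fullcols = np.flatnonzero(mask.all(axis=0))
    connected = fullcols.size > 0
    topcols = np.flatnonzero(mask[0, :])
    axis_cols = fullcols if connected else topcols
    axis_col = int(round(axis_cols.mean())) if axis_cols.size else None

    # ---- fiber width -> contact radius ------------------------------------
    r_tip = None
    junction_row = 0
    if axis_col is not None:
        widths = np.full(nrows, np.nan)
        for r in range(nrows):
            run = _run_around(mask[r], axis_col)
            if run is not None:
                widths[r] = run[1] - run[0] + 1
        top_band = widths[1:max(8, nrows // 40)]
        w_fiber = np.nanmedian(top_band)
        if np.isfinite(w_fiber):
            below = np.flatnonzero(widths > w_fiber + 2.0)
            junction_row = int(below.min()) if below.size else nrows - 1
            halfw = []
            for r in range(1, max(2, junction_row - 1)):
                run = _run_around(mask[r], axis_col)
                if run is None:
                    continue
                left = _cross_down(img[r], run[0], thr)
                right = _cross_up(img[r], run[1], thr)
                halfw.append((right - left) / 2.0)
            if halfw:
                r_tip = float(np.median(halfw)) * frame.pixel_scale

    # ---- baseline from far-field flat segments ----------------------------
    if axis_col is not None:
        # lateral reach of fiber + meniscus: widest dark run around the axis,
        # ignoring bath rows (runs spanning the whole frame width)
        max_half = 0
        for r in range(nrows):
            run = _run_around(mask[r], axis_col)
            if run is not None and not (run[0] == 0 and run[1] == ncols - 1):
                max_half = max(max_half, axis_col - run[0], run[1] - axis_col)
        margin = max_half + 4
        far = np.flatnonzero(
            (np.arange(ncols) < axis_col - margin)
            | (np.arange(ncols) > axis_col + margin)
        )
    else:
        far = np.arange(ncols)
    if far.size < 0.05 * ncols:
        raise BaselineDetectionError(
            "meniscus reaches the frame sides; no far-field flat surface"
        )
    base_rows = []
    for c in far:
        t = _bottom_run_top(mask[:, c])
        if t is not None and t > 0:
            base_rows.append(_cross_down(img[:, c], t, thr))
    if len(base_rows) < 0.05 * ncols:
        raise BaselineDetectionError("no flat liquid surface found in far field")
    base_rows = np.asarray(base_rows)
    base_row = float(np.median(base_rows))
    if float(np.median(np.abs(base_rows - base_row))) > 2.0:
        raise BaselineDetectionError(
            "far-field surface is not flat (spread > 2 px)"
        )
    if baseline_hint is not None:
        hint_row = nrows - 1 - baseline_hint / frame.pixel_scale
        if abs(hint_row - base_row) > 5:
            base_row = hint_row
    baseline_y = float(frame.y_of_row(base_row))

    # ---- meniscus flank edge points, sampled per row ----------------------
    flanks = []
    if connected and axis_col is not None:
        r_tip_px = (r_tip / frame.pixel_scale) if r_tip else 0.0
        for r in range(max(1, junction_row), int(base_row) - 1):
            run = _run_around(mask[r], axis_col)
            if run is None:
                continue
            halfw = (run[1] - run[0] + 1) / 2.0
            if halfw <= r_tip_px + 1.0:
                continue  # still in the prismatic fiber section
            left = _cross_down(img[r], run[0], thr)
            right = _cross_up(img[r], run[1], thr)
            y_rel = float(frame.y_of_row(r)) - baseline_y
            flanks.append((float(frame.x_of_col(left)), y_rel))
            flanks.append((float(frame.x_of_col(right)), y_rel))
    flank_points = np.asarray(flanks) if flanks else np.empty((0, 2))
    axis_x = float(frame.x_of_col(axis_col)) if axis_col is not None else None
    return MeniscusLocation(
        flank_points=flank_points, baseline_y=baseline_y, r_tip=r_tip,
        axis_x=axis_x, connected=connected,
    )


def locate_fiber_tip(sil: Silhouette) -> float:
    """Absolute height (m) of the free fiber tip in a post-snap-off frame,
    from the subpixel bottom edge of the top-connected dark bar."""
    frame = sil.frame
    img = frame.image.astype(float)
    mask = sil.mask
    cols = np.flatnonzero(mask[0, :] & ~mask.all(axis=0))
    if cols.size == 0:
        raise DataError("no free fiber found (frame may be pre-snap-off)")
    # central half of the fiber columns
    lo = np.percentile(cols, 25)
    hi = np.percentile(cols, 75)
    sel = cols[(cols >= lo) & (cols <= hi)]
    rows = []
    for c in sel:
        r = 0
        while r < frame.n_rows - 1 and mask[r + 1, c]:
            r += 1
        rows.append(_cross_up(img[:, c], r, sil.threshold))
    return float(frame.y_of_row(float(np.median(rows))))


def track_tip(frames, roi, *, search_pad: int = 24,
              confidence_floor: float = 0.5) -> np.ndarray:
    """Vertical tip position per frame (m) by normalized cross-correlation.

    A template cut from the first frame at ``roi = (row0, row1, col0, col1)``
    is matched in each frame within a vertically padded search window; the
    correlation peak is refined by quadratic (parabolic) interpolation.
    Raises :class:`TrackingLostError` when the peak falls below the
    confidence floor.
    """
    row0, row1, col0, col1 = roi
    template = frames[0].image.astype(float)[row0:row1, col0:col1]
    if template.size == 0:
        raise DataError("empty tracking ROI")
    out = np.empty(len(frames))
    for i, fr in enumerate(frames):
        img = fr.image.astype(float)
        r0 = max(0, row0 - search_pad)
        r1 = min(fr.n_rows, row1 + search_pad)
        c0 = max(0, col0 - search_pad)
        c1 = min(fr.n_cols, col1 + search_pad)
        corr = _skfeature.match_template(img[r0:r1, c0:c1], template)
        pk = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[pk] < confidence_floor:
            raise TrackingLostError(
                f"correlation peak {corr[pk]:.2f} below confidence floor "
                f"at frame {i}"
            )
        dr = 0.0
        if 0 < pk[0] < corr.shape[0] - 1:
            cm, c_, cp = corr[pk[0] - 1, pk[1]], corr[pk], corr[pk[0] + 1, pk[1]]
            den = cm - 2 * c_ + cp
            if den != 0:
                dr = float(np.clip(0.5 * (cm - cp) / den, -1, 1))
        row_match = r0 + pk[0] + dr
        out[i] = fr.y_of_row(row_match)
    return out


def measure_bending_angle(frame: Frame, fiber_roi, *, threshold="auto",
                          baseline_slope: float = 0.0) -> float:
    """Angle (rad) between the fiber and the liquid surface near the contact.

    Fits a line to the fiber centerline (midpoints of the dark band that is
    not connected to the liquid bulk) within the column window
    ``fiber_roi = (col0, col1)``, and returns its inclination relative to
    the baseline.
    """
    sil = extract_silhouette(frame, threshold)
    img = frame.image.astype(float)
    mask = sil.mask
    col0, col1 = fiber_roi
    cols, mids = [], []
    for c in range(max(0, col0), min(frame.n_cols, col1)):
        colmask = mask[:, c]
        bottom_top = _bottom_run_top(colmask)
        runs = []
        r = 0
        while r < frame.n_rows:
            if colmask[r]:
                lo = r
                while r < frame.n_rows - 1 and colmask[r + 1]:
                    r += 1
                if bottom_top is None or lo < bottom_top - 1:
                    runs.append((lo, r))
            r += 1
        if not runs:
            continue
        lo, hi = max(runs, key=lambda ab: ab[1] - ab[0])
        top = _cross_down(img[:, c], lo, sil.threshold)
        bot = _cross_up(img[:, c], hi, sil.threshold)
        cols.append(c)
        mids.append((top + bot) / 2.0)
    if len(cols) < 5 or np.ptp(cols) < 3:
        raise AngleMeasurementError(
            "fiber centerline not resolvable in the given window"
        )
    cols = np.asarray(cols, dtype=float)
    mids = np.asarray(mids)
    slope_rows = np.polyfit(cols, mids, 1)[0]
    slope_phys = -slope_rows  # rows grow downward
    return abs(float(np.arctan(slope_phys) - np.arctan(baseline_slope)))


# ---------------------------------------------------------------------------
# sequence IO: numbered PNG / multipage TIFF + sidecar YAML
# ---------------------------------------------------------------------------


def load_sequence(path):
    """Load an image sequence with its sidecar YAML.

    ``path`` is a directory containing ``sidecar.yaml`` plus the frame files
    it lists (PNG/TIFF), or a multipage TIFF with a sidecar of the same stem.
    Returns ``(frames, metadata_dict)``.
    """
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        sidecar = path / "sidecar.yaml"
        if not sidecar.exists():
            raise DataError(f"no sidecar.yaml in {path}")
        meta = yaml.safe_load(sidecar.read_text())
        images = [iio.imread(path / f["file"]) for f in meta["frames"]]
    else:
        sidecar = path.with_suffix(".yaml")
        if not sidecar.exists():
            raise DataError(f"no sidecar YAML next to {path}")
        meta = yaml.safe_load(sidecar.read_text())
        stack = iio.imread(path)
        images = [stack[i] for i in range(len(meta["frames"]))]
    scale = float(meta["pixel_scale_m_per_px"])
    frames = [
        Frame(
            image=np.asarray(img),
            timestamp=float(f["timestamp_s"]),
            stage_position=float(f["stage_position_m"]),
            pixel_scale=scale,
        )
        for img, f in zip(images, meta["frames"])
    ]
    return frames, meta


def read_manual_points(path):
    """Read a manually clicked point CSV (frame_index, x_px, y_px, label).

    Returns a dict ``{frame_index: {label: (n, 2) float array}}`` with the
    labels flank / tip / baseline / fiber.
    """
    out: dict = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            label = row["label"].strip()
            if label not in ("flank", "tip", "baseline", "fiber"):
                raise DataError(f"unknown manual-point label {label!r}")
            idx = int(row["frame_index"])
            out.setdefault(idx, {}).setdefault(label, []).append(
                (float(row["x_px"]), float(row["y_px"]))
            )
    return {
        i: {lbl: np.asarray(pts) for lbl, pts in d.items()}
        for i, d in out.items()
    }
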