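"""Whitening-front tracking: registration, subtraction, segmentation, localisation.

Per frame the pipeline
1. registers the first (whitening-free) frame to the current frame with
   single-step DFT-upsampled cross-correlation (rigid, sub-pixel),
2. forms the difference image in reference coordinates (current frame
   warped back by the estimated shift, reference subtracted, negative
   values clipped -- whitening is an intensity *increase*),
3. thresholds the difference and applies a morphological join operator
   (closing by default) with a small disc element,
4. localises the whitening front as the farther-from-notch of the
   top-left / top-right extrema of the top-most mask row, and converts it
   to a crack-extension value.

The raw displacement series is monotonicised with a running maximum: the
damage zone does not heal, so transient dropouts (dimming below the
threshold) must not pull the effective crack length backwards.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import closing as _gray_closing, disk, opening as _gray_opening
from skimage.registration import phase_cross_correlation

from .io_sync import Calibration, FrameSequence, SyncedFrame

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RigidShift:
    """Sub-pixel rigid translation mapping the reference frame onto the current one."""

    dy: float
    dx: float
    peak_corr: float = 1.0


@dataclass
class WhiteningMask:
    """Binary whitening mask plus the segmentation parameters that made it."""

    mask: np.ndarray
    threshold: float
    element_diameter_px: int
    join_operator: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass(frozen=True)
class FrontPoint:
    """Whitening-front pixel and its distance from the initial notch tip."""

    pixel: tuple[int, int]
    displacement_mm: float


@dataclass
class TrackConfig:
    """Tunable parameters of the tracking stage.

    threshold: fixed difference-intensity threshold in (0, 1), or "otsu"
        to compute one global Otsu threshold from the final frame's
        difference image.
    smooth_sigma: Gaussian smoothing (px) applied to difference images
        before segmentation; scalar or (row, col) sigmas -- the default
        smooths more along the front's width (columns) than across its
        advancing edge (rows), pooling evidence laterally without
        blurring the edge position; 0 disables.
    displacement_mode: "vertical" measures crack extension as the
        through-width projection (notch-tip row minus front row), the
        quantity entering a(i) = a0 + da; "euclidean" uses the straight
        pixel distance between front and notch tip.
    roi / reg_window: (row0, row1, col0, col1) half-open rectangles; the
        ROI confines segmentation around the notch, the registration
        window (optional) restricts shift estimation to a region whose
        content does not change (e.g. away from the growing whitening).
    """

    upsample_factor: int = 100
    threshold: Union[float, Literal["otsu"]] = "otsu"
    element_diameter_px: int = 2
    join_operator: Literal["closing", "opening"] = "closing"
    min_area_px: int = 5
    smooth_sigma: Union[float, tuple[float, float]] = (0.7, 1.4)
    displacement_mode: Literal["vertical", "euclidean"] = "vertical"
    roi: Optional[tuple[int, int, int, int]] = None
    reg_window: Optional[tuple[int, int, int, int]] = None
    keep_differences: bool = False


@dataclass
class FrontTrajectory:
    """Per retained frame: front point, synced mechanics, raw and monotone da."""

    front_px: np.ndarray  # (n, 2) float, NaN where no front
    da_raw_mm: np.ndarray  # NaN where no front
    da_mono_mm: np.ndarray  # running maximum of raw (NaN -> hold)
    synced: list[SyncedFrame]
    shifts: list[RigidShift]
    calibration: Calibration
    notch_tip_px: tuple[int, int]
    config: Optional[TrackConfig] = None
    threshold_used: Optional[float] = None
    differences: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.da_raw_mm)
        if not (len(self.da_mono_mm) == n == len(self.front_px) == len(self.synced)):
            raise ValueError("trajectory arrays must share one length")

    def __len__(self) -> int:
        return len(self.da_raw_mm)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_idx": [s.frame_idx for s in self.synced],
                "t_s": [s.t_s for s in self.synced],
                "force_N": [s.force_N for s in self.synced],
                "disp_mm": [s.disp_mm for s in self.synced],
                "front_row": self.front_px[:, 0],
                "front_col": self.front_px[:, 1],
                "da_raw_mm": self.da_raw_mm,
                "da_mono_mm": self.da_mono_mm,
                "peak_corr": [s.peak_corr for s in self.shifts],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(
        cls, path, calibration: Calibration, notch_tip_px: tuple[int, int]
    ) -> "FrontTrajectory":
        """Rehydrate a trajectory from its CSV export (shifts not preserved)."""
        df = pd.read_csv(path)
        synced = [
            SyncedFrame(
                frame_idx=int(r.frame_idx),
                t_s=float(r.t_s),
                force_N=float(r.force_N),
                disp_mm=float(r.disp_mm),
                synced=bool(np.isfinite(r.force_N)),
            )
            for r in df.itertuples()
        ]
        return cls(
            front_px=df[["front_row", "front_col"]].to_numpy(dtype=float),
            da_raw_mm=df["da_raw_mm"].to_numpy(dtype=float),
            da_mono_mm=df["da_mono_mm"].to_numpy(dtype=float),
            synced=synced,
            shifts=[RigidShift(0.0, 0.0, float(p)) for p in df["peak_corr"]],
            calibration=calibration,
            notch_tip_px=tuple(notch_tip_px),
        )


def register_pair(
    reference: np.ndarray, current: np.ndarray, upsample_factor: int = 100
) -> RigidShift:
    """Estimate the rigid shift mapping ``reference`` onto ``current``.

    Single-step DFT-upsampled cross-correlation; the translation is
    resolved to within 1/upsample_factor px without deforming the image.
    """
    reference = np.asarray(reference, dtype=float)
    current = np.asarray(current, dtype=float)
    if reference.shape != current.shape:
        raise ValueError("frames must share one shape")
    if upsample_factor < 1:
        raise ValueError("upsample_factor must be >= 1")
    if reference.std() == 0 or current.std() == 0:
        raise ValueError("no texture to register (zero-variance image)")
    # returns the shift moving `current` back onto `reference`, i.e. -(ref->cur)
    shift, _, _ = phase_cross_correlation(
        reference, current, upsample_factor=upsample_factor, normalization=None
    )
    dy, dx = float(-shift[0]), float(-shift[1])
    aligned = ndi.shift(current, (-dy, -dx), order=1, mode="nearest")
    my, mx = int(math.ceil(abs(dy))) + 1, int(math.ceil(abs(dx))) + 1
    core = (slice(my, reference.shape[0] - my), slice(mx, reference.shape[1] - mx))
    a, b = reference[core].ravel(), aligned[core].ravel()
    denom = a.std() * b.std()
    peak_corr = float(np.corrcoef(a, b)[0, 1]) if denom > 0 else 0.0
    return RigidShift(dy=dy, dx=dx, peak_corr=max(0.0, peak_corr))


def difference_image(
    reference: np.ndarray, current: np.ndarray, shift: RigidShift
) -> np.ndarray:
    """Shift-compensated difference, clipped to intensity increases.

    The current frame is resampled back by the estimated shift so the
    difference lives in reference coordinates (the notch tip stays
    fixed); for a rigid shift this is equivalent to resampling the
    reference forward.  Border pixels the resampling could not fill are
    zeroed.
    """
    reference = np.asarray(reference, dtype=float)
    current = np.asarray(current, dtype=float)
    if reference.shape != current.shape:
        raise ValueError("frames must share one shape")
    if not (np.isfinite(shift.dy) and np.isfinite(shift.dx)):
        raise ValueError("non-finite shift")
    if shift.dy == 0 and shift.dx == 0:
        aligned = current
    else:
        aligned = ndi.shift(current, (-shift.dy, -shift.dx), order=1, mode="nearest")
    diff = np.clip(aligned - reference, 0.0, None)
    h, w = diff.shape
    my = int(math.ceil(abs(shift.dy)))
    mx = int(math.ceil(abs(shift.dx)))
    if my:
        if shift.dy > 0:
            diff[h - my :, :] = 0.0
        else:
            diff[:my, :] = 0.0
    if mx:
        if shift.dx > 0:
            diff[:, w - mx :] = 0.0
        else:
            diff[:, :mx] = 0.0
    return diff


def _join_element(diameter_px: int) -> np.ndarray:
    if diameter_px < 1:
        raise ValueError("element diameter must be >= 1")
    return disk(max(1, round(diameter_px / 2)))


def apply_join_operator(
    mask: np.ndarray, element_diameter_px: int = 2, join_operator: str = "closing"
) -> np.ndarray:
    """Morphological closing (join regions / fill small dark islands) or opening."""
    footprint = _join_element(element_diameter_px)
    mask = np.asarray(mask, dtype=bool)
    if join_operator not in ("closing", "opening"):
        raise ValueError(f"unknown join operator {join_operator!r}")
    # pad with background so the result equals morphology on the infinite
    # plane (no whitening outside the ROI); naive border handling would
    # hallucinate mask rows at the ROI edge under closing
    pad = max(footprint.shape)
    padded = np.pad(mask, pad, constant_values=False)
    op = _gray_closing if join_operator == "closing" else _gray_opening
    out = op(padded, footprint).astype(bool)
    return out[pad:-pad, pad:-pad]


def segment_whitening(
    difference: np.ndarray,
    threshold: float,
    element_diameter_px: int = 2,
    join_operator: str = "closing",
    min_area_px: int = 0,
) -> WhiteningMask:
    """Threshold the difference image and join neighbouring whitening regions.

    The mask is ``difference >= threshold`` followed by the configured
    morphological operator with a disc element; components smaller than
    ``min_area_px`` pixels are discarded.  An empty mask is a valid
    output (no whitening yet).
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    mask = np.asarray(difference, dtype=float) >= threshold
    mask = apply_join_operator(mask, element_diameter_px, join_operator)
    if min_area_px > 1 and mask.any():
        labels, n = label(mask, connectivity=1, return_num=True)
        sizes = np.bincount(labels.ravel())
        small = np.nonzero(sizes < min_area_px)[0]
        if len(small):
            mask = mask & ~np.isin(labels, small[small > 0])
    return WhiteningMask(
        mask=mask,
        threshold=float(threshold),
        element_diameter_px=int(element_diameter_px),
        join_operator=join_operator,
    )


def select_whitening_region(mask: np.ndarray) -> np.ndarray:
    """Largest 4-connected component of the mask (the whitening region).

    Supra-threshold noise specks elsewhere in the ROI must not hijack the
    top-most-pixel front definition; the damage zone is one region once
    the dark islands are closed.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask
    labels, n = label(mask, connectivity=1, return_num=True)
    if n == 1:
        return mask
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(sizes)) + 1)


def locate_front(
    mask: Union[np.ndarray, WhiteningMask],
    notch_tip_px: tuple[int, int],
    calibration: Calibration,
    displacement_mode: str = "vertical",
) -> Optional[FrontPoint]:
    """Whitening-front pixel and crack-extension value from a mask.

    The front is the farther-from-notch of the left-most and right-most
    pixels of the top-most (minimum-row) mask row; ties resolve to the
    top-left pixel.  Displacement converts to mm via the calibration,
    either as the vertical (through-width) projection or as the Euclidean
    pixel distance, floored at 0.  Returns None for an empty mask.
    """
    m = mask.mask if isinstance(mask, WhiteningMask) else np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(m)
    if rows.size == 0:
        return None
    r_top = int(rows.min())
    top_cols = cols[rows == r_top]
    left = (r_top, int(top_cols.min()))
    right = (r_top, int(top_cols.max()))
    tr, tc = notch_tip_px
    d_left = math.hypot(left[0] - tr, left[1] - tc)
    d_right = math.hypot(right[0] - tr, right[1] - tc)
    front = left if d_left >= d_right else right
    if displacement_mode == "vertical":
        disp_px = max(0.0, float(tr - front[0]))
    elif displacement_mode == "euclidean":
        disp_px = max(d_left, d_right)
    else:
        raise ValueError(f"unknown displacement mode {displacement_mode!r}")
    return FrontPoint(pixel=front, displacement_mm=disp_px * calibration.mm_per_pixel)


def _crop(img: np.ndarray, rect: Optional[tuple[int, int, int, int]]) -> np.ndarray:
    if rect is None:
        return img
    r0, r1, c0, c1 = rect
    return img[r0:r1, c0:c1]


def track(
    frames: FrameSequence,
    synced: Sequence[SyncedFrame],
    notch_tip_px: tuple[int, int],
    calibration: Calibration,
    config: Optional[TrackConfig] = None,
) -> FrontTrajectory:
    """Run the whitening-front tracking algorithm over a frame sequence.

    The first retained frame (no whitening yet) is the registration
    reference.  Frames that fail registration are flagged and carried as
    having no front.
    """
    cfg = config or TrackConfig()
    if len(synced) != len(frames):
        raise ValueError("synced records must match the frame sequence")
    ref = frames.frames[0]
    n = len(frames)
    roi = cfg.roi
    if roi is not None:
        r0, r1, c0, c1 = roi
        if not (0 <= r0 < r1 <= ref.shape[0] and 0 <= c0 < c1 <= ref.shape[1]):
            raise ValueError(f"ROI {roi} outside the frame")
        if not (r0 <= notch_tip_px[0] < r1 and c0 <= notch_tip_px[1] < c1):
            raise ValueError("notch tip must lie inside the ROI")

    shifts: list[RigidShift] = []
    diffs = np.empty((n,) + _crop(ref, roi).shape, dtype=float)
    failed = np.zeros(n, dtype=bool)
    ref_reg = _crop(ref, cfg.reg_window)
    for i, frame in enumerate(frames.frames):
        if i == 0:
            shifts.append(RigidShift(0.0, 0.0, 1.0))
        else:
            try:
                shifts.append(
                    register_pair(ref_reg, _crop(frame, cfg.reg_window),
                                  cfg.upsample_factor)
                )
            except ValueError as exc:
                logger.warning("frame %d failed registration: %s", i, exc)
                shifts.append(RigidShift(math.nan, math.nan, 0.0))
                failed[i] = True
                diffs[i] = 0.0
                continue
        diff = difference_image(ref, frame, shifts[i])
        if np.any(np.asarray(cfg.smooth_sigma) > 0):
            diff = ndi.gaussian_filter(diff, cfg.smooth_sigma)
        diffs[i] = _crop(diff, roi)

    if cfg.threshold == "otsu":
        last_ok = np.nonzero(~failed)[0][-1]
        final = diffs[last_ok]
        if final.max() <= final.min():
            logger.warning("flat final difference image; no whitening detectable")
            thr = math.inf
        else:
            thr = float(threshold_otsu(final))
            thr = min(max(thr, 1e-9), 1 - 1e-9)
    else:
        thr = float(cfg.threshold)

    tip_local = (
        notch_tip_px
        if roi is None
        else (notch_tip_px[0] - roi[0], notch_tip_px[1] - roi[2])
    )
    front_px = np.full((n, 2), math.nan)
    da_raw = np.full(n, math.nan)
    for i in range(n):
        if failed[i] or not math.isfinite(thr):
            continue
        wm = segment_whitening(
            diffs[i], thr, cfg.element_diameter_px, cfg.join_operator, cfg.min_area_px
        )
        region = select_whitening_region(wm.mask)
        fp = locate_front(region, tip_local, calibration, cfg.displacement_mode)
        if fp is None:
            continue
        r, c = fp.pixel
        if roi is not None:
            r, c = r + roi[0], c + roi[2]
        front_px[i] = (r, c)
        da_raw[i] = fp.displacement_mm

    da_mono = np.empty(n)
    running = 0.0
    for i in range(n):
        if math.isfinite(da_raw[i]):
            running = max(running, da_raw[i])
        da_mono[i] = running

    return FrontTrajectory(
        front_px=front_px,
        da_raw_mm=da_raw,
        da_mono_mm=da_mono,
        synced=list(synced),
        shifts=shifts,
        calibration=calibration,
        notch_tip_px=tuple(notch_tip_px),
        config=cfg,
        threshold_used=thr if math.isfinite(thr) else None,
        differences=diffs if cfg.keep_differences else None,
    )


def export_difference_frames(
    trajectory: FrontTrajectory, out_dir: Union[str, Path]
) -> list[Path]:
    """Write the difference images as 16-bit PNGs for visual QC."""
    import imageio.v3 as iio

    if trajectory.differences is None:
        raise ValueError("trajectory was tracked without keep_differences=True")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    peak = float(trajectory.differences.max()) or 1.0
    for i, d in enumerate(trajectory.differences):
        arr = np.clip(d / peak, 0, 1)
        p = out_dir / f"diff_{i:05d}.png"
        iio.imwrite(p, (arr * 65535).astype(np.uint16))
        paths.append(p)
    return paths
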