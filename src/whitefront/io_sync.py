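"""Frame loading, pixel calibration, preprocessing and mechanics synchronisation.

Frames are handled as floating grayscale intensities in [0, 1], row 0 at
the image top; the crack propagates upward (toward decreasing row).  The
mechanics channels (time, force, load-line displacement) are columns of
one acquisition record; frames are synchronised by elapsed time,
``t = original_index / fps``, with force/displacement linearly
interpolated at the frame times over the shared sample index.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: luminance weights for colour -> gray conversion (ITU-R BT.709, as scikit-image)
_LUMA = np.array([0.2125, 0.7154, 0.0721])

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


@dataclass
class FrameSequence:
    """Ordered grayscale frames with subsampling bookkeeping.

    frames : (n, h, w) float array in [0, 1]
    fps : capture frame rate of the *original* video
    stride : subsampling factor (1 of every ``stride`` captured frames kept)
    original_index : per retained frame, its 0-based index in the capture
    """

    frames: np.ndarray
    fps: float
    stride: int = 1
    original_index: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or len(self.frames) == 0:
            raise ValueError("frames must be a non-empty (n, h, w) stack")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.original_index is None:
            self.original_index = np.arange(len(self.frames)) * self.stride
        self.original_index = np.asarray(self.original_index, dtype=int)
        if len(self.original_index) != len(self.frames):
            raise ValueError("original_index length must match frame count")
        step = np.diff(self.original_index)
        if len(step) and (np.any(step != self.stride)):
            raise ValueError("original_index must increase with step = stride")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times_s(self) -> np.ndarray:
        """Elapsed capture time of each retained frame (s)."""
        return self.original_index / self.fps


@dataclass(frozen=True)
class Calibration:
    """Pixel-size calibration from the known support span.

    ``mm_per_pixel = span_mm / |left_support - right_support|`` (Euclidean
    pixel distance).  Support coordinates are (row, col).
    """

    mm_per_pixel: float
    left_support_px: Optional[tuple[float, float]] = None
    right_support_px: Optional[tuple[float, float]] = None
    span_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")


@dataclass
class MechChannels:
    """Force / time / displacement columns of one tester acquisition."""

    time_s: np.ndarray
    force_N: np.ndarray
    disp_mm: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force_N = np.asarray(self.force_N, dtype=float)
        self.disp_mm = np.asarray(self.disp_mm, dtype=float)
        n = len(self.time_s)
        if len(self.force_N) != n or len(self.disp_mm) != n or n == 0:
            raise ValueError("time, force and displacement must have equal nonzero length")
        if np.any(np.diff(self.time_s) < 0):
            raise ValueError("time_s must be non-decreasing")

    @classmethod
    def from_csv(cls, path) -> "MechChannels":
        df = pd.read_csv(path)
        missing = {"time_s", "force_N", "disp_mm"} - set(df.columns)
        if missing:
            raise ValueError(f"mechanics CSV missing columns: {sorted(missing)}")
        return cls(df["time_s"].to_numpy(), df["force_N"].to_numpy(),
                   df["disp_mm"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_s": self.time_s, "force_N": self.force_N, "disp_mm": self.disp_mm}
        ).to_csv(path, index=False, float_format="%.10g")


@dataclass(frozen=True)
class SyncedFrame:
    """A retained frame with its interpolated mechanics state."""

    frame_idx: int
    t_s: float
    force_N: float
    disp_mm: float
    synced: bool = True


def _to_float_gray(img: np.ndarray) -> np.ndarray:
    """Convert an image to single-channel floating intensities in [0, 1]."""
    arr = np.asarray(img)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[..., :3]
        arr = arr.astype(float) @ _LUMA
        was_int = np.issubdtype(np.asarray(img).dtype, np.integer)
        if was_int:
            arr = arr / np.iinfo(np.asarray(img).dtype).max
        return np.clip(arr, 0.0, 1.0)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return np.clip(arr.astype(float), 0.0, 1.0)


def _natural_key(p: Path):
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", p.name)]


def load_frames(
    source: Union[str, Path, np.ndarray, Sequence[np.ndarray]],
    stride: int = 15,
    fps: float = 60.0,
) -> FrameSequence:
    """Load a video file, an image-sequence directory, or an array stack.

    Retains one in every ``stride`` captured frames (the first frame is
    always retained), converting everything to grayscale float in [0, 1].
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.is_dir():
            files = sorted(
                (p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES),
                key=_natural_key,
            )
            if not files:
                raise ValueError(f"no image files found in {path}")
            raw = [iio.imread(f) for f in files]
        elif path.is_file():
            try:
                raw = list(iio.imiter(path))
            except Exception as exc:  # pragma: no cover - container support varies
                raise ValueError(f"cannot decode video container {path}: {exc}") from exc
            if not raw:
                raise ValueError(f"empty video {path}")
        else:
            raise ValueError(f"unreadable source: {path}")
    else:
        raw = [np.asarray(f) for f in source]
        if not raw:
            raise ValueError("empty frame sequence")
    frames = [_to_float_gray(f) for f in raw]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes: {sorted(shapes)}")
    kept = frames[::stride]
    original_index = np.arange(0, len(frames), stride)
    return FrameSequence(
        frames=np.stack(kept), fps=fps, stride=stride, original_index=original_index
    )


def calibrate(
    left_support_px: tuple[float, float],
    right_support_px: tuple[float, float],
    span_mm: float,
    frame: Optional[np.ndarray] = None,
) -> Calibration:
    """Pixel-size calibration from the two support contact points.

    The support span is a known physical distance; dividing it by the
    Euclidean pixel distance between the support points gives mm/px
    independent of the camera-to-sample distance.
    """
    if span_mm <= 0:
        raise ValueError("span_mm must be positive")
    lp = np.asarray(left_support_px, dtype=float)
    rp = np.asarray(right_support_px, dtype=float)
    dist = float(np.hypot(*(rp - lp)))
    if dist == 0:
        raise ValueError("degenerate calibration: support points coincide")
    if frame is not None:
        h, w = np.asarray(frame).shape[:2]
        for p in (lp, rp):
            if not (0 <= p[0] < h and 0 <= p[1] < w):
                raise ValueError(f"support point {tuple(p)} outside the frame")
    return Calibration(
        mm_per_pixel=span_mm / dist,
        left_support_px=tuple(lp),
        right_support_px=tuple(rp),
        span_mm=span_mm,
    )


def preprocess(
    fseq: FrameSequence,
    gamma: float = 1.0,
    window_percentiles: tuple[float, float] = (1.0, 99.0),
) -> FrameSequence:
    """Percentile windowing and gamma correction, per frame.

    Each frame is affinely rescaled so its ``window_percentiles``
    intensities map to [0, 1] (clipped), then raised to ``gamma``.
    Constant-intensity frames come back as zeros with a warning.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    p_lo, p_hi = window_percentiles
    if not (0 <= p_lo < p_hi <= 100):
        raise ValueError("window percentiles must satisfy 0 <= lo < hi <= 100")
    out = np.empty_like(fseq.frames)
    for i, frame in enumerate(fseq.frames):
        lo, hi = np.percentile(frame, [p_lo, p_hi])
        if hi <= lo:
            logger.warning("frame %d has a degenerate intensity window; zeroed", i)
            out[i] = 0.0
            continue
        out[i] = np.clip((frame - lo) / (hi - lo), 0.0, 1.0) ** gamma
    return FrameSequence(
        frames=out,
        fps=fseq.fps,
        stride=fseq.stride,
        original_index=fseq.original_index.copy(),
    )


def sync_frames(fseq: FrameSequence, mech: MechChannels) -> list[SyncedFrame]:
    """Associate each retained frame with its force and displacement.

    Frame elapsed time is ``original_index / fps`` (frame X of a 60 fps
    capture occurred at X/60 s); force and displacement are linearly
    interpolated at that time.  Frames beyond the end of the mechanics
    record are flagged unsynced (and excluded from R-curve assembly).
    """
    times = fseq.times_s
    t_end = float(mech.time_s[-1])
    out: list[SyncedFrame] = []
    n_unsynced = 0
    for idx, t in enumerate(times):
        if t > t_end + 1e-12:
            out.append(SyncedFrame(idx, float(t), math.nan, math.nan, synced=False))
            n_unsynced += 1
            continue
        f = float(np.interp(t, mech.time_s, mech.force_N))
        d = float(np.interp(t, mech.time_s, mech.disp_mm))
        out.append(SyncedFrame(idx, float(t), f, d, synced=True))
    if n_unsynced:
        logger.warning(
            "%d frame(s) beyond the mechanics record were flagged unsynced", n_unsynced
        )
    return out
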