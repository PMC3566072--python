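"""Association between whitening-front propagation and crack-tip propagation.

The crack tip, where visible, is annotated manually: per frame and per
observer repetition, a start (pre-notch) and end (crack tip) pixel pair.
Repetitions are aggregated to a per-frame mean and standard deviation of
the crack extension, and the front/crack association is quantified with
Pearson's correlation coefficient plus the front-minus-crack lag
statistics (the whitening front runs a roughly constant few hundred
micrometres ahead of the crack tip).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .io_sync import Calibration

ANNOTATION_COLUMNS = [
    "frame_idx",
    "repetition",
    "start_row",
    "start_col",
    "end_row",
    "end_col",
]


@dataclass
class CrackAnnotationSet:
    """Repeated manual crack-extension measurements, aggregated per frame."""

    frame_idx: np.ndarray
    da_crack_mm: np.ndarray  # (n_frames, n_repetitions)
    mean_mm: np.ndarray
    sd_mm: np.ndarray

    @property
    def n_repetitions(self) -> int:
        return self.da_crack_mm.shape[1]


def aggregate_annotations(
    annotations: Union[pd.DataFrame, str, Path],
    calibration: Calibration,
) -> CrackAnnotationSet:
    """Aggregate repeated crack annotations into per-frame mean and sd.

    ``annotations`` is a table (or CSV path) with columns frame_idx,
    repetition, start_row/col (the pre-notch) and end_row/col (the crack
    tip); the crack extension of one repetition is the Euclidean pixel
    distance between the two points times the pixel size.  All
    repetitions must cover the same frames.
    """
    if not isinstance(annotations, pd.DataFrame):
        annotations = pd.read_csv(annotations)
    missing = set(ANNOTATION_COLUMNS) - set(annotations.columns)
    if missing:
        raise ValueError(f"annotations missing columns: {sorted(missing)}")
    df = annotations.copy()
    df["da_mm"] = (
        np.hypot(df.end_row - df.start_row, df.end_col - df.start_col)
        * calibration.mm_per_pixel
    )
    pivot = df.pivot_table(index="frame_idx", columns="repetition", values="da_mm")
    if pivot.isna().any().any():
        raise ValueError("repetitions cover mismatched frame sets")
    values = pivot.to_numpy()
    sd = values.std(axis=1, ddof=1) if values.shape[1] >= 2 else np.full(len(values), math.nan)
    return CrackAnnotationSet(
        frame_idx=pivot.index.to_numpy(),
        da_crack_mm=values,
        mean_mm=values.mean(axis=1),
        sd_mm=sd,
    )


@dataclass
class CorrelationReport:
    """Pearson association and lag statistics between front and crack series."""

    r: float
    p: float
    n: int
    lag_mean_mm: float
    lag_sd_mm: float
    note: Optional[str] = None

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "r": None if math.isnan(self.r) else self.r,
                    "p": None if math.isnan(self.p) else self.p,
                    "n": self.n,
                    "lag_mean_mm": self.lag_mean_mm,
                    "lag_sd_mm": self.lag_sd_mm,
                    "note": self.note,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )


def front_crack_correlation(
    front_da_mm: Sequence[float], crack_da_mm: Sequence[float]
) -> CorrelationReport:
    """Pearson r (exact t-transform p, n-2 dof) and front-crack lag stats.

    The lag is the per-frame front-minus-crack offset; for a damage zone
    of constant extent it is constant, so its mean estimates the process
    zone length and its sd the tracking/annotation noise.
    """
    front = np.asarray(front_da_mm, dtype=float)
    crack = np.asarray(crack_da_mm, dtype=float)
    if front.shape != crack.shape or front.ndim != 1:
        raise ValueError("paired series of equal length required")
    ok = np.isfinite(front) & np.isfinite(crack)
    front, crack = front[ok], crack[ok]
    n = len(front)
    if n < 3:
        raise ValueError("need at least 3 paired samples")
    lag = front - crack
    lag_mean = float(lag.mean())
    lag_sd = float(lag.std(ddof=1))
    if front.std() == 0 or crack.std() == 0:
        return CorrelationReport(
            r=math.nan, p=math.nan, n=n, lag_mean_mm=lag_mean, lag_sd_mm=lag_sd,
            note="undefined correlation: zero-variance series",
        )
    res = stats.pearsonr(front, crack)
    return CorrelationReport(
        r=float(res.statistic), p=float(res.pvalue), n=n,
        lag_mean_mm=lag_mean, lag_sd_mm=lag_sd,
    )
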