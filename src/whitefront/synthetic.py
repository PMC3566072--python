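"""Ground-truth video and mechanics generator for pipeline testing.

Phenomenological forward model of a three-point-bend fracture video of a
small notched specimen: a textured specimen band on a dark background, a
bright stress-whitening halo nucleating at the notch tip and growing
toward the top surface along a prescribed monotone schedule, an optional
darker crack line lagging the front by a constant offset, per-frame
rigid jitter and Gaussian sensor noise.  The force--displacement record
is linear until the frame where the front reaches the top surface, then
softens exponentially to near-zero load (displacement-controlled, no
instability fracture).

The emitted ground truth is *self-measured*: the generator renders the
halo as a crisp pixel-aligned region from the pixel-quantised front
schedule and then locates the front on its own noise-free halo layer
(threshold = amplitude/2) with the same localiser the pipeline uses, so
"render then measure" returns the truth exactly, lateral halo extent
included.  The reference resistance curve is forward-computed from the
truth with the fracture module's own equations.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.special import ndtr

from . import fracture
from .fracture import RCurve, SpecimenGeometry
from .io_sync import Calibration, FrameSequence, MechChannels, SyncedFrame, sync_frames
from .tracking import FrontTrajectory, RigidShift, locate_front

logger = logging.getLogger(__name__)


@dataclass
class ScenarioParams:
    """All knobs of one synthetic fracture-test scenario.

    Image quantities in px, mechanics in mm/N/s; the defaults emulate a
    miniature human SE(B) test (B = W = 0.9 mm, a0 = 0.3 mm, 6.15 mm
    span, 12 GPa, 0.01 mm/s loading, 60 fps) viewed as a 128 x 128 px
    region of interest at 10 um/px.
    """

    geometry: SpecimenGeometry = field(
        default_factory=lambda: SpecimenGeometry(B=0.9, W=0.9, a0=0.3, S=6.15, nu=0.33)
    )
    image_shape: tuple[int, int] = (128, 128)
    mm_per_pixel: float = 0.01
    fps: float = 60.0
    n_frames: int = 100
    onset_frame: int = 5
    breakthrough_frame: int = 70
    crack_lag_mm: Optional[float] = 0.35  # None -> drawn once from [0.3, 0.4]
    crack_visible: bool = False
    crack_darkening: float = 0.3
    halo_amplitude: float = 0.25
    halo_tip_halfwidth_px: int = 2
    halo_base_halfwidth_px: int = 4
    halo_tail_px: int = 3
    jitter_sd_px: float = 0.3
    noise_sd: float = 0.025
    edge_blur_px: float = 0.7  # optical (PSF-like) softness of scene edges
    loading_rate_mm_s: float = 0.01
    softening_tau_s: float = 0.15
    E_MPa: float = 12000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.halo_amplitude != 0 and self.halo_amplitude <= self.noise_sd:
            raise ValueError("halo amplitude must exceed the noise sd (or be 0: no whitening)")
        if not (0 < self.onset_frame <= self.breakthrough_frame < self.n_frames):
            raise ValueError("need 0 < onset_frame <= breakthrough_frame < n_frames")
        if self.crack_lag_mm is not None and self.crack_lag_mm < 0:
            raise ValueError("crack lag must be non-negative")
        if self.jitter_sd_px < 0 or self.noise_sd < 0:
            raise ValueError("jitter and noise sd must be non-negative")

    # --- derived image layout -------------------------------------------------
    @property
    def width_px(self) -> int:
        return int(round(self.geometry.W / self.mm_per_pixel))

    @property
    def a0_px(self) -> int:
        return int(round(self.geometry.a0 / self.mm_per_pixel))

    @property
    def top_row(self) -> int:
        return (self.image_shape[0] - self.width_px) // 2

    @property
    def bottom_row(self) -> int:
        return self.top_row + self.width_px - 1

    @property
    def notch_col(self) -> int:
        return self.image_shape[1] // 2

    @property
    def notch_tip_px(self) -> tuple[int, int]:
        return (self.bottom_row - self.a0_px, self.notch_col)

    @property
    def ligament_px(self) -> int:
        return int(round((self.geometry.W - self.geometry.a0) / self.mm_per_pixel))

    @property
    def calibration(self) -> Calibration:
        return Calibration(mm_per_pixel=self.mm_per_pixel)

    def roi(self, margin_cols: int = 16) -> tuple[int, int, int, int]:
        """Rectangular ROI around the notch and crack path (half-open).

        The top is clamped to the specimen's top surface: whitening cannot
        exist above the sample, and mask pixels there would only ever be
        noise or edge ghosts.
        """
        h, w = self.image_shape
        return (
            self.top_row,
            min(h, self.bottom_row + 3),
            max(0, self.notch_col - margin_cols),
            min(w, self.notch_col + margin_cols + 1),
        )

    def reg_window(self) -> Optional[tuple[int, int, int, int]]:
        """Registration window over textured specimen away from the whitening."""
        c1 = self.notch_col - 20
        if c1 - 2 < 16:
            return None
        return (self.top_row, self.bottom_row + 1, 2, c1)


def rat_tibia_scenario(**overrides) -> ScenarioParams:
    """Preset emulating a whole rat tibia test: visible crack line, drawn lag."""
    defaults = dict(crack_visible=True, crack_lag_mm=None)
    defaults.update(overrides)
    return ScenarioParams(**defaults)


@dataclass
class GroundTruth:
    """Per-frame truth emitted alongside the rendered video."""

    da_true_mm: np.ndarray  # pixel-quantised front extension (mm)
    front_px: np.ndarray  # (n, 2) float, NaN before whitening onset
    da_crack_mm: np.ndarray
    schedule_px: np.ndarray  # continuous front schedule before quantisation
    shifts: np.ndarray  # (n, 2) applied rigid jitter (dy, dx)
    mech: MechChannels
    m_true: float  # N/mm slope of the linear branch
    lag_mm: float
    divergence_frame: int
    params: ScenarioParams

    def synced_frames(self, frames: FrameSequence) -> list[SyncedFrame]:
        return sync_frames(frames, self.mech)

    def truth_trajectory(self, frames: FrameSequence) -> FrontTrajectory:
        """The trajectory an ideal tracker would produce (truth, monotonicised)."""
        n = len(self.da_true_mm)
        da_raw = np.where(np.isfinite(self.front_px[:, 0]), self.da_true_mm, np.nan)
        mono = np.maximum.accumulate(np.where(np.isfinite(da_raw), da_raw, 0.0))
        return FrontTrajectory(
            front_px=self.front_px.copy(),
            da_raw_mm=da_raw,
            da_mono_mm=mono,
            synced=self.synced_frames(frames),
            shifts=[RigidShift(dy, dx, 1.0) for dy, dx in self.shifts],
            calibration=self.params.calibration,
            notch_tip_px=self.params.notch_tip_px,
        )

    def reference_rcurve(self, frames: FrameSequence, eta: float = 1.9) -> RCurve:
        """Resistance curve forward-computed from the truth (the 5 recovery target)."""
        traj = self.truth_trajectory(frames)
        force = np.array([s.force_N for s in traj.synced if s.synced])
        disp = np.array([s.disp_mm for s in traj.synced if s.synced])
        E, fit = fracture.modulus_from_record(force, disp, self.params.geometry)
        return fracture.build_rcurve(
            traj, self.params.geometry, E, eta=eta, m=fit.m,
            metadata={"source": "ground-truth forward model"},
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_idx": np.arange(len(self.da_true_mm)),
                "da_true_mm": self.da_true_mm,
                "front_row": self.front_px[:, 0],
                "front_col": self.front_px[:, 1],
                "da_crack_mm": self.da_crack_mm,
                "schedule_px": self.schedule_px,
                "jitter_dy": self.shifts[:, 0],
                "jitter_dx": self.shifts[:, 1],
            }
        )


def _front_schedule_px(params: ScenarioParams) -> np.ndarray:
    """Continuous monotone front schedule in px, clipped at the ligament."""
    t = np.arange(params.n_frames, dtype=float)
    lig = float(params.ligament_px)
    ramp = (t - params.onset_frame) / max(1, params.breakthrough_frame - params.onset_frame)
    sched = np.clip(ramp, 0.0, 1.0) * lig
    sched[t < params.onset_frame] = np.nan  # no whitening yet
    if np.nanmax(sched) > lig + 1e-9:  # pragma: no cover - clip guards above
        warnings.warn("front schedule exceeds the ligament; clipped", stacklevel=2)
        sched = np.minimum(sched, lig)
    return sched


def _halo_layer(
    params: ScenarioParams, k_px: int, rr: np.ndarray, cc: np.ndarray
) -> np.ndarray:
    """Halo profile (0..1) for front height k_px, at continuous coordinates.

    Narrow at the advancing front, widening toward the notch, with a
    short tail below the tip into the notch mouth.  Edges are steep but
    analytic (sigma ~0.35 px) and pixel-centred, so the support of
    ``layer >= 1/2`` on the integer grid is exactly the intended crisp
    pixel set while rendering stays shift-covariant at sub-pixel jitter.
    """
    tip_r, tip_c = params.notch_tip_px
    front_row = max(params.top_row, tip_r - k_px)
    sig = 0.35
    bottom = min(params.bottom_row, tip_r + params.halo_tail_px)
    vert = ndtr((rr - (front_row - 0.5)) / sig) * ndtr(((bottom + 0.5) - rr) / sig)
    hw = np.clip(
        params.halo_tip_halfwidth_px + (rr - front_row) / 2.0,
        params.halo_tip_halfwidth_px,
        params.halo_base_halfwidth_px,
    )
    lat = ndtr((hw + 0.5 - np.abs(cc - tip_c)) / sig)
    return vert * lat


def _halo_truth_mask(params: ScenarioParams, k_px: int) -> np.ndarray:
    """Noise-free halo support on the pixel grid (layer >= 1/2, zero jitter)."""
    h, w = params.image_shape
    rr, cc = np.meshgrid(
        np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij"
    )
    return _halo_layer(params, k_px, rr, cc) >= 0.5


def _crack_layer(
    params: ScenarioParams, crack_k_px: int, rr: np.ndarray, cc: np.ndarray
) -> np.ndarray:
    """Thin dark crack line from the notch tip up to the lagging crack tip."""
    tip_r, tip_c = params.notch_tip_px
    sig = 0.35
    vert = ndtr((rr - (tip_r - crack_k_px - 0.5)) / sig) * ndtr(
        ((tip_r + 0.5) - rr) / sig
    )
    lat = np.exp(-0.5 * ((cc - tip_c) / 0.5) ** 2)
    return vert * lat


def _base_scene(params: ScenarioParams, rng: np.random.Generator):
    """Smooth texture field plus analytic (antialiasable) geometry pieces."""
    h, w = params.image_shape
    field_ = rng.normal(size=(h, w))
    field_ = ndi.gaussian_filter(field_, 1.5, mode="wrap")
    field_ *= 0.08 / field_.std()
    return field_


def _render_frame(
    params: ScenarioParams,
    tex_field: np.ndarray,
    k_px: Optional[int],
    crack_k_px: int,
    jitter: tuple[float, float],
    noise: Optional[np.ndarray],
) -> np.ndarray:
    """Compose one frame: everything sampled at scene coords shifted by jitter."""
    h, w = params.image_shape
    jy, jx = jitter
    rr, cc = np.meshgrid(
        np.arange(h, dtype=float) - jy, np.arange(w, dtype=float) - jx, indexing="ij"
    )
    tex = ndi.map_coordinates(tex_field, [rr, cc], order=3, mode="reflect")
    top_edge = params.top_row - 0.5
    bot_edge = params.bottom_row + 0.5
    # smooth (PSF-like) edges: crisp scene edges would lose intensity under
    # the sub-pixel resampling chain and leave registration-residual ghosts
    sig = max(params.edge_blur_px, 1e-6)
    cov = ndtr((rr - top_edge) / sig) * ndtr((bot_edge - rr) / sig)
    base = 0.05 + cov * (0.35 + tex)
    # notch slot: narrow dark line from the bottom face up to the tip
    tip_r, tip_c = params.notch_tip_px
    slot = (
        np.exp(-0.5 * ((cc - tip_c) / max(0.6, sig)) ** 2)
        * ndtr((rr - (tip_r + 0.5)) / sig)
        * cov
    )
    base -= 0.3 * slot
    if k_px is not None:
        base = base + params.halo_amplitude * _halo_layer(params, k_px, rr, cc)
        if params.crack_visible and crack_k_px >= 1:
            base = base - params.crack_darkening * _crack_layer(params, crack_k_px, rr, cc)
    if noise is not None:
        base = base + noise
    return np.clip(base, 0.0, 1.0)


def synth_mechanics(params: ScenarioParams) -> MechChannels:
    """Force/time/displacement record consistent with the front schedule.

    Displacement ramps at the loading rate; force is exactly linear
    (slope = the notched-beam flexural prediction from E and geometry)
    until the front reaches the top surface, then decays exponentially --
    stable, displacement-controlled softening.  Sampled at the capture
    frame times so interpolation at frames is exact at the knots.
    """
    n = params.n_frames + 10
    t = np.arange(n, dtype=float) / params.fps
    d = params.loading_rate_mm_s * t
    g = params.geometry
    m = 4.0 * params.E_MPa * g.B * (g.W - g.a0) ** 3 / g.S**3
    t_div = params.breakthrough_frame / params.fps
    f = m * d
    soft = t > t_div + 1e-12
    f_div = m * params.loading_rate_mm_s * t_div
    f[soft] = f_div * np.exp(-(t[soft] - t_div) / params.softening_tau_s)
    return MechChannels(time_s=t, force_N=f, disp_mm=d)


def synth_video(params: ScenarioParams) -> tuple[FrameSequence, GroundTruth]:
    """Render the scenario and emit frames plus self-measured ground truth."""
    rng = np.random.default_rng(params.seed)
    tex_field = _base_scene(params, rng)
    lag_mm = params.crack_lag_mm
    if lag_mm is None:
        lag_mm = float(rng.uniform(0.3, 0.4))
    lag_px = int(round(lag_mm / params.mm_per_pixel))

    n = params.n_frames
    jitter = rng.normal(0.0, params.jitter_sd_px, size=(n, 2))
    jitter[0] = 0.0

    sched = _front_schedule_px(params)
    h, w = params.image_shape
    frames = np.empty((n, h, w))
    front_px = np.full((n, 2), math.nan)
    da_true = np.zeros(n)
    da_crack = np.zeros(n)
    calib = params.calibration
    amp = params.halo_amplitude

    for i in range(n):
        if math.isnan(sched[i]):
            k = None
            crack_k = 0
        else:
            k = int(round(sched[i]))
            crack_k = max(0, k - lag_px)
            # truth measured from the rendered halo itself: thresholding the
            # noise-free layer at amplitude/2 selects exactly this support
            fp = locate_front(
                _halo_truth_mask(params, k),
                params.notch_tip_px,
                calib,
                displacement_mode="vertical",
            )
            front_px[i] = fp.pixel
            da_true[i] = fp.displacement_mm
            da_crack[i] = max(0.0, da_true[i] - lag_mm) if crack_k > 0 else 0.0
        noise = (
            rng.normal(0.0, params.noise_sd, size=(h, w)) if params.noise_sd > 0 else None
        )
        frames[i] = _render_frame(params, tex_field, k, crack_k, tuple(jitter[i]), noise)

    mech = synth_mechanics(params)
    g = params.geometry
    m_true = 4.0 * params.E_MPa * g.B * (g.W - g.a0) ** 3 / g.S**3
    gt = GroundTruth(
        da_true_mm=da_true,
        front_px=front_px,
        da_crack_mm=da_crack,
        schedule_px=sched,
        shifts=jitter,
        mech=mech,
        m_true=m_true,
        lag_mm=lag_mm,
        divergence_frame=params.breakthrough_frame,
        params=params,
    )
    fseq = FrameSequence(frames=frames, fps=params.fps, stride=1)
    return fseq, gt


def write_scenario(out_dir, fseq: FrameSequence, gt: GroundTruth) -> Path:
    """Write frames/ (16-bit PNG), mech.csv, truth.csv and scenario.json."""
    out_dir = Path(out_dir)
    frames_dir = out_dir / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(fseq.frames):
        iio.imwrite(
            frames_dir / f"frame_{i:05d}.png",
            np.round(frame * 65535).astype(np.uint16),
        )
    gt.mech.to_csv(out_dir / "mech.csv")
    gt.to_dataframe().to_csv(out_dir / "truth.csv", index=False, float_format="%.10g")
    p = gt.params
    scenario = {
        "geometry": asdict(p.geometry),
        "mm_per_pixel": p.mm_per_pixel,
        "fps": p.fps,
        "stride": 1,
        "n_frames": p.n_frames,
        "notch_tip_px": list(p.notch_tip_px),
        "roi": list(p.roi()),
        "reg_window": list(p.reg_window()) if p.reg_window() else None,
        "E_MPa": p.E_MPa,
        "m_true_N_per_mm": gt.m_true,
        "crack_lag_mm": gt.lag_mm,
        "divergence_frame": gt.divergence_frame,
        "seed": p.seed,
        "crack_visible": p.crack_visible,
        "halo_amplitude": p.halo_amplitude,
        "noise_sd": p.noise_sd,
        "jitter_sd_px": p.jitter_sd_px,
    }
    (out_dir / "scenario.json").write_text(
        json.dumps(scenario, indent=2, sort_keys=True) + "\n"
    )
    return out_dir
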