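"""Nonlinear fracture-mechanics computation for SE(B) specimens.

Implements the J-integral decomposition used to build crack-extension
resistance curves from a load--displacement record and a crack (whitening
front) extension series:

* ``J = J_el + J_pl`` with ``J_el = K^2 (1 - nu^2) / E`` and
  ``J_pl = eta * A_pl / (B * b0)`` (ASTM E1820 basic procedure for
  single-edge notched bending, ``eta = 1.9``),
* the SE(B) stress-intensity factor ``K = F S / (B W^1.5) * f(a/W)`` with
  the standard E1820 geometry polynomial ``f``,
* the effective stress intensity ``K_eff = sqrt(J E / (1 - nu^2))``,
* the flexural modulus of a notched three-point-bend beam,
  ``E_f = S^3 m / (4 B (W - a0)^3)``, optionally corrected for the
  notch-induced stiffness bias via a :class:`~whitefront.notch_fe.NotchCorrectionModel`.

Unit conventions: all lengths in mm, forces in N.  Then moduli are in
N/mm^2 (MPa), J values in N/mm (identically kJ/m^2) and stress
intensities are converted from N*mm^-1.5 to MPa*sqrt(m) via the exact
factor sqrt(1/1000).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .notch_fe import NotchCorrectionModel
    from .tracking import FrontTrajectory

logger = logging.getLogger(__name__)

#: exact conversion, 1 N*mm^-1.5 == 1 MPa*sqrt(mm) == sqrt(1e-3) MPa*sqrt(m)
MPA_SQRT_M_PER_N_MM15 = math.sqrt(1.0e-3)


@dataclass(frozen=True)
class SpecimenGeometry:
    """SE(B) specimen geometry (all lengths in mm).

    B : thickness; W : width (height in the bending direction);
    a0 : initial notch length; S : support span; nu : Poisson ratio.
    """

    B: float
    W: float
    a0: float
    S: float
    nu: float = 0.33

    def __post_init__(self) -> None:
        if not (self.B > 0 and self.W > 0 and self.S > 0):
            raise ValueError("B, W and S must be positive")
        if not (0 <= self.a0 < self.W):
            raise ValueError(f"a0 must lie in [0, W); got a0={self.a0}, W={self.W}")
        if not (0 < self.nu < 0.5):
            raise ValueError(f"Poisson ratio must lie in (0, 0.5); got {self.nu}")

    @property
    def b0(self) -> float:
        """Initial un-cracked ligament length W - a0 (mm)."""
        return self.W - self.a0

    def with_notch(self, a0: float) -> "SpecimenGeometry":
        return replace(self, a0=a0)


@dataclass(frozen=True)
class LinearFit:
    """Slope of the linear part of a load--displacement curve."""

    m: float  # N/mm
    window_fractions: tuple[float, float]
    r2: float
    n_points: int
    intercept: float = 0.0


def fit_linear_slope(
    force: np.ndarray,
    disp: np.ndarray,
    window_fractions: tuple[float, float] = (0.10, 0.50),
) -> LinearFit:
    """Least-squares slope of the linear part of the load-displacement curve.

    The window selects the samples whose force lies between the given
    fractions of the peak force (default 10--50%), restricted to the
    rising branch (samples before the peak).
    """
    force = np.asarray(force, dtype=float)
    disp = np.asarray(disp, dtype=float)
    if force.shape != disp.shape or force.ndim != 1:
        raise ValueError("force and disp must be 1-D arrays of equal length")
    if not np.any(force > 0):
        raise ValueError("degenerate record: no positive force samples")
    lo, hi = window_fractions
    if not (0 <= lo < hi <= 1):
        raise ValueError("window fractions must satisfy 0 <= lo < hi <= 1")
    peak_idx = int(np.argmax(force))
    fpk = force[peak_idx]
    sel = np.zeros_like(force, dtype=bool)
    sel[: peak_idx + 1] = True
    sel &= (force >= lo * fpk) & (force <= hi * fpk)
    if sel.sum() < 5:
        raise ValueError(
            f"too few samples in the linear-fit window ({int(sel.sum())} < 5)"
        )
    coeffs, res = np.polyfit(disp[sel], force[sel], 1, full=True)[:2]
    m, c = float(coeffs[0]), float(coeffs[1])
    if m <= 0:
        raise ValueError(f"non-positive load-displacement slope ({m:.4g} N/mm)")
    ss_tot = float(np.sum((force[sel] - force[sel].mean()) ** 2))
    ss_res = float(res[0]) if len(res) else 0.0
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if r2 < 0.99:
        warnings.warn(
            f"linear fit r2={r2:.4f} < 0.99: load-displacement record may not "
            "have a clean linear range",
            stacklevel=2,
        )
    return LinearFit(m=m, window_fractions=(lo, hi), r2=r2,
                     n_points=int(sel.sum()), intercept=c)


def flexural_modulus(m: float, geometry: SpecimenGeometry) -> float:
    """Apparent flexural modulus of the notched beam, N/mm^2.

    ``E_f = S^3 m / (4 B (W - a0)^3)`` -- the three-point-bend flexural
    relation evaluated with the notched in-plane width.  With a0 = 0 this
    is the standard un-notched beam formula.
    """
    if m <= 0:
        raise ValueError("slope m must be positive")
    b = geometry.W - geometry.a0
    return geometry.S**3 * m / (4.0 * geometry.B * b**3)


def correct_modulus(
    E_f_measured: float,
    a0: float,
    model: Optional["NotchCorrectionModel"] = None,
) -> float:
    """Correct the apparent (notched-beam) modulus for the notch bias.

    Returns the modulus an un-notched bend test of the same material would
    have measured.  Without a correction model the value is passed through
    unchanged with a loud warning.
    """
    if model is None:
        warnings.warn(
            "no notch-correction model supplied: returning the apparent "
            "flexural modulus unchanged (notched-beam values overestimate E)",
            stacklevel=2,
        )
        return E_f_measured
    return model.correct(E_f_measured, a0)


def seb_geometry_factor(a_over_W: float | np.ndarray) -> float | np.ndarray:
    """ASTM E1820 SE(B) geometry polynomial f(a/W).

    ``f(x) = 3 sqrt(x) [1.99 - x(1-x)(2.15 - 3.93 x + 2.7 x^2)]
    / [2 (1 + 2x)(1 - x)^1.5]`` for a span-to-width ratio S/W = 4
    loading; the span enters K separately through the F*S prefactor.
    """
    x = np.asarray(a_over_W, dtype=float)
    if np.any((x <= 0) | (x >= 1)):
        raise ValueError("a/W must lie strictly in (0, 1)")
    num = 3.0 * np.sqrt(x) * (1.99 - x * (1.0 - x) * (2.15 - 3.93 * x + 2.7 * x**2))
    den = 2.0 * (1.0 + 2.0 * x) * (1.0 - x) ** 1.5
    out = num / den
    return float(out) if np.isscalar(a_over_W) else out


def stress_intensity(
    F: float, geometry: SpecimenGeometry, a: float, si_units: bool = True
) -> float:
    """SE(B) stress-intensity factor K for load F (N) and crack length a (mm).

    Returns MPa*sqrt(m) by default, or N*mm^-1.5 with ``si_units=False``.
    """
    if F < 0:
        raise ValueError("force must be non-negative")
    x = a / geometry.W
    if not (0 < x < 1):
        raise ValueError(f"a/W={x:.4g} outside (0, 1)")
    if F == 0:
        return 0.0
    k_nmm = F * geometry.S / (geometry.B * geometry.W**1.5) * seb_geometry_factor(x)
    return k_nmm * MPA_SQRT_M_PER_N_MM15 if si_units else k_nmm


def plastic_area(
    force: np.ndarray, disp: np.ndarray, m: float, i: Optional[int] = None
) -> float:
    """Area under force vs plastic load-line displacement up to sample i.

    Plastic displacement is the compliance-subtracted ``d_pl = d - F/m``;
    the area is the trapezoidal integral of F over d_pl, floored at 0.
    """
    if m <= 0:
        raise ValueError("slope m must be positive")
    force = np.asarray(force, dtype=float)
    disp = np.asarray(disp, dtype=float)
    if i is None:
        i = len(force) - 1
    f = force[: i + 1]
    d_pl = disp[: i + 1] - f / m
    if len(f) < 2:
        return 0.0
    return max(0.0, float(np.trapezoid(f, d_pl)))


@dataclass(frozen=True)
class JPoint:
    J_el: float
    J_pl: float

    @property
    def J(self) -> float:
        return self.J_el + self.J_pl


def j_point(
    force: np.ndarray,
    disp: np.ndarray,
    i: int,
    m: float,
    geometry: SpecimenGeometry,
    a_i: float,
    E: float,
    eta: float = 1.9,
) -> JPoint:
    """Elastic and plastic J components at load-displacement sample i.

    ``J_el = K(F_i, a_i)^2 (1 - nu^2) / E`` (plane strain) and
    ``J_pl = eta A_pl(i) / (B b0)`` with b0 the initial ligament.
    Result in N/mm == kJ/m^2.
    """
    if E <= 0:
        raise ValueError("modulus E must be positive")
    b0 = geometry.b0
    if b0 <= 0:
        raise ValueError("initial ligament b0 = W - a0 must be positive")
    k_nmm = stress_intensity(float(force[i]), geometry, a_i, si_units=False)
    j_el = k_nmm**2 * (1.0 - geometry.nu**2) / E
    a_pl = plastic_area(force, disp, m, i)
    j_pl = eta * a_pl / (geometry.B * b0)
    return JPoint(J_el=j_el, J_pl=j_pl)


def k_eff(J: float, E: float, nu: float) -> float:
    """Effective stress intensity from J: sqrt(J E / (1 - nu^2)), MPa*sqrt(m).

    J in kJ/m^2 (== N/mm), E in MPa.
    """
    if J < 0 or E < 0:
        raise ValueError("J and E must be non-negative")
    return math.sqrt(J * E / (1.0 - nu**2)) * MPA_SQRT_M_PER_N_MM15


@dataclass(frozen=True)
class RCurvePoint:
    """One point of the crack-extension resistance curve."""

    frame_idx: int
    t_s: float
    force_N: float
    disp_mm: float
    da_mm: float
    a_mm: float
    J_el: float
    J_pl: float
    K_eff: float

    @property
    def J(self) -> float:
        return self.J_el + self.J_pl


@dataclass
class RCurve:
    """Ordered resistance-curve points with the inputs that produced them."""

    points: list[RCurvePoint]
    geometry: SpecimenGeometry
    E: float
    eta: float
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.points)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_idx": [p.frame_idx for p in self.points],
                "t_s": [p.t_s for p in self.points],
                "force_N": [p.force_N for p in self.points],
                "disp_mm": [p.disp_mm for p in self.points],
                "da_mm": [p.da_mm for p in self.points],
                "a_mm": [p.a_mm for p in self.points],
                "Jel_kJm2": [p.J_el for p in self.points],
                "Jpl_kJm2": [p.J_pl for p in self.points],
                "J_kJm2": [p.J for p in self.points],
                "Keff_MPa_sqrt_m": [p.K_eff for p in self.points],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def modulus_from_record(
    force: np.ndarray,
    disp: np.ndarray,
    geometry: SpecimenGeometry,
    model: Optional["NotchCorrectionModel"] = None,
    window_fractions: tuple[float, float] = (0.10, 0.50),
) -> tuple[float, LinearFit]:
    """Fit the linear slope, convert to flexural modulus, apply notch correction."""
    fit = fit_linear_slope(force, disp, window_fractions)
    e_f = flexural_modulus(fit.m, geometry)
    with warnings.catch_warnings():
        if model is None:  # pass-through already logged by caller's choice
            warnings.simplefilter("ignore")
        e = correct_modulus(e_f, geometry.a0, model)
    return e, fit


def build_rcurve(
    trajectory: "FrontTrajectory",
    geometry: SpecimenGeometry,
    E: float,
    eta: float = 1.9,
    m: Optional[float] = None,
    metadata: Optional[dict] = None,
    stop_at_peak: bool = True,
) -> RCurve:
    """Assemble the resistance curve from a tracked whitening-front trajectory.

    Uses the monotonicised front displacement as crack extension,
    ``a_i = a0 + da_i`` (the whitening front acts as the effective crack
    tip); points with ``a_i >= W`` (front at or beyond the top surface)
    are truncated with a warning, unsynced frames are skipped.  By
    default the curve terminates at peak load: failure coincides with the
    whitening front reaching the top surface, and the softening branch
    beyond it is no longer a crack-growth resistance measurement
    (``stop_at_peak=False`` keeps every frame with positive force).
    """
    synced = trajectory.synced
    frames = [s for s in synced if s.synced]
    if not frames:
        return RCurve(points=[], geometry=geometry, E=E, eta=eta,
                      metadata=metadata or {})
    force = np.array([s.force_N for s in frames])
    disp = np.array([s.disp_mm for s in frames])
    if m is None:
        m = fit_linear_slope(force, disp).m
    da = trajectory.da_mono_mm
    points: list[RCurvePoint] = []
    n_truncated = 0
    j_peak = int(np.argmax(force)) if stop_at_peak else len(frames) - 1
    for j, s in enumerate(frames):
        if j > j_peak:
            break
        da_j = float(da[s.frame_idx])
        if not (da_j > 0 or s.force_N > 0):
            continue
        a_j = geometry.a0 + da_j
        if a_j >= geometry.W - 1e-9:
            n_truncated += 1
            continue
        jp = j_point(force, disp, j, m, geometry, a_j, E, eta)
        points.append(
            RCurvePoint(
                frame_idx=s.frame_idx,
                t_s=s.t_s,
                force_N=s.force_N,
                disp_mm=s.disp_mm,
                da_mm=da_j,
                a_mm=a_j,
                J_el=jp.J_el,
                J_pl=jp.J_pl,
                K_eff=k_eff(jp.J, E, geometry.nu),
            )
        )
    if n_truncated:
        logger.warning(
            "truncated %d point(s) with a_i >= W (whitening front at the top surface)",
            n_truncated,
        )
    meta = dict(metadata or {})
    meta.update({"m_N_per_mm": m, "n_truncated": n_truncated})
    return RCurve(points=points, geometry=geometry, E=E, eta=eta, metadata=meta)
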