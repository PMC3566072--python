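"""Plane-stress FE model of the notched three-point-bend test.

Regenerates the notched-beam modulus-correction relationship: a
linear-elastic beam of width W and span S is meshed with fully integrated
4-node bilinear plane-stress quadrilaterals, with the notch realised as a
zero-width slot (duplicated nodes) of depth a0 at midspan bottom.  The
supports and the loading roller are replaced by short pinned / prescribed
nodal patches: contact adds no first-order information for a stiffness
ratio, while *single*-node constraints would make the compliance
log-divergent under refinement.

Solving the displacement-driven bend test for several notch lengths
yields the apparent stiffness m(a0); converting each with the notched
flexural formula gives apparent moduli whose ratio to the un-notched
value is fitted by a second-order polynomial -- the correction the
fracture module applies to measured flexural moduli.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .fracture import SpecimenGeometry, flexural_modulus

logger = logging.getLogger(__name__)

_GAUSS = 1.0 / np.sqrt(3.0)
_GAUSS_PTS = [(-_GAUSS, -_GAUSS), (_GAUSS, -_GAUSS), (_GAUSS, _GAUSS), (-_GAUSS, _GAUSS)]


@dataclass
class QuadMesh:
    """Structured 4-node quadrilateral mesh of the bend specimen.

    nodes : (n, 2) coordinates (x along the span, y through the width), mm
    elements : (m, 4) connectivity, counter-clockwise
    node_sets : named boundary node index arrays (left_support,
        right_support, load)
    """

    nodes: np.ndarray
    elements: np.ndarray
    node_sets: dict[str, np.ndarray]
    a0: float

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=int)
        areas = self.element_areas()
        if np.any(areas <= 0):
            raise ValueError("mesh contains degenerate (non-positive-area) elements")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_areas(self) -> np.ndarray:
        x = self.nodes[self.elements, 0]
        y = self.nodes[self.elements, 1]
        return 0.5 * np.abs(
            (x[:, 0] * y[:, 1] - x[:, 1] * y[:, 0])
            + (x[:, 1] * y[:, 2] - x[:, 2] * y[:, 1])
            + (x[:, 2] * y[:, 3] - x[:, 3] * y[:, 2])
            + (x[:, 3] * y[:, 0] - x[:, 0] * y[:, 3])
        )

    def to_csv(self, nodes_path, elements_path) -> None:
        pd.DataFrame(self.nodes, columns=["x_mm", "y_mm"]).to_csv(
            nodes_path, index=True, index_label="node", float_format="%.10g"
        )
        pd.DataFrame(self.elements, columns=["n0", "n1", "n2", "n3"]).to_csv(
            elements_path, index=True, index_label="element"
        )


def _segment(x0: float, x1: float, size: float) -> np.ndarray:
    n = max(1, int(round((x1 - x0) / size)))
    return np.linspace(x0, x1, n + 1)


def mesh_beam(
    geometry: SpecimenGeometry,
    a0: Optional[float] = None,
    elem_size_fine: float = 0.075,
    elem_size_coarse: float = 0.2,
    fine_halfwidth: float = 0.9,
    support_halfwidth: float = 0.0,
    load_halfwidth: float = 0.075,
) -> QuadMesh:
    """Structured quad mesh of the beam span with a midspan bottom slot.

    Fine elements in a band around the load point / notch, coarse
    elsewhere; the slot of depth ``a0`` is created by duplicating the
    midspan node column below the notch tip, leaving the notch faces
    traction-free.  Supports are single corner nodes by default
    (``support_halfwidth`` widens them): a roller must leave the section
    free to rotate, so pinning a patch would stiffen the beam spuriously.
    """
    a0 = geometry.a0 if a0 is None else a0
    W, S = geometry.W, geometry.S
    if not (0 <= a0 < W):
        raise ValueError(f"a0 must lie in [0, W); got {a0}")
    if elem_size_fine <= 0 or elem_size_coarse <= 0:
        raise ValueError("element sizes must be positive")
    if elem_size_fine > W or elem_size_coarse > W:
        raise ValueError("element size exceeds the specimen width")

    mid = S / 2.0
    fhw = min(fine_halfwidth, mid)
    n_half = max(2, int(round(fhw / elem_size_fine)))
    x_mid = np.linspace(mid - fhw, mid + fhw, 2 * n_half + 1)
    x_left = _segment(0.0, mid - fhw, elem_size_coarse) if mid - fhw > 0 else np.array([0.0])
    x_right = _segment(mid + fhw, S, elem_size_coarse) if mid + fhw < S else np.array([S])
    x = np.unique(np.concatenate([x_left, x_mid, x_right]))

    if a0 > 0:
        y = np.unique(
            np.concatenate([_segment(0.0, a0, elem_size_fine),
                            _segment(a0, W, elem_size_fine)])
        )
    else:
        y = _segment(0.0, W, elem_size_fine)

    nx, ny = len(x), len(y)
    xv, yv = np.meshgrid(x, y, indexing="ij")
    nodes = np.column_stack([xv.ravel(), yv.ravel()])

    def nid(ix: int, iy: int) -> int:
        return ix * ny + iy

    elems = []
    for ix in range(nx - 1):
        for iy in range(ny - 1):
            elems.append([nid(ix, iy), nid(ix + 1, iy), nid(ix + 1, iy + 1), nid(ix, iy + 1)])
    elems = np.array(elems, dtype=int)

    # zero-width slot: duplicate midspan nodes strictly below the notch tip,
    # rewire elements on the right of the cut to the duplicates
    if a0 > 0:
        icx = int(np.argmin(np.abs(x - mid)))
        if abs(x[icx] - mid) > 1e-9:
            raise RuntimeError("mesh has no node column at midspan")
        cut_iy = np.nonzero(y < a0 - 1e-12)[0]
        dup_ids = {}
        extra = []
        for iy in cut_iy:
            dup_ids[nid(icx, iy)] = len(nodes) + len(extra)
            extra.append(nodes[nid(icx, iy)])
        if extra:
            nodes = np.vstack([nodes, np.array(extra)])
        elem_col = np.repeat(np.arange(nx - 1), ny - 1)
        right_side = elem_col >= icx
        for e in np.nonzero(right_side)[0]:
            for k in range(4):
                if elems[e, k] in dup_ids:
                    elems[e, k] = dup_ids[elems[e, k]]

    tol = 1e-9
    bottom = np.abs(nodes[:, 1]) < tol
    top = np.abs(nodes[:, 1] - W) < tol
    node_sets = {
        "left_support": np.nonzero(bottom & (nodes[:, 0] <= support_halfwidth + tol))[0],
        "right_support": np.nonzero(bottom & (nodes[:, 0] >= S - support_halfwidth - tol))[0],
        "load": np.nonzero(top & (np.abs(nodes[:, 0] - mid) <= load_halfwidth + tol))[0],
    }
    for name, ids in node_sets.items():
        if len(ids) == 0:
            raise RuntimeError(f"empty node set {name}")
    mesh = QuadMesh(nodes=nodes, elements=elems, node_sets=node_sets, a0=a0)
    logger.debug("meshed beam a0=%.3g: %d elements, %d nodes", a0, mesh.n_elements, mesh.n_nodes)
    return mesh


def _assemble_stiffness(mesh: QuadMesh, E: float, nu: float, thickness: float) -> sparse.csr_matrix:
    """Global stiffness, fully integrated (2x2 Gauss) plane-stress Q4."""
    D = (E / (1.0 - nu**2)) * np.array(
        [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]]
    )
    coords = mesh.nodes[mesh.elements]  # (m, 4, 2)
    m = mesh.n_elements
    ke = np.zeros((m, 8, 8))
    for xi, eta in _GAUSS_PTS:
        dn = 0.25 * np.array(
            [
                [-(1 - eta), -(1 - xi)],
                [(1 - eta), -(1 + xi)],
                [(1 + eta), (1 + xi)],
                [-(1 + eta), (1 - xi)],
            ]
        )  # (4, 2) d(N)/d(xi, eta)
        J = np.einsum("ak,mai->mki", dn, coords)  # (m, 2, 2)
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        invJ = np.empty_like(J)
        invJ[:, 0, 0] = J[:, 1, 1]
        invJ[:, 0, 1] = -J[:, 0, 1]
        invJ[:, 1, 0] = -J[:, 1, 0]
        invJ[:, 1, 1] = J[:, 0, 0]
        invJ /= detJ[:, None, None]
        dN = np.einsum("mij,aj->mai", invJ, dn)  # (m, 4, 2) d(N)/d(x, y)
        B = np.zeros((m, 3, 8))
        B[:, 0, 0::2] = dN[:, :, 0]
        B[:, 1, 1::2] = dN[:, :, 1]
        B[:, 2, 0::2] = dN[:, :, 1]
        B[:, 2, 1::2] = dN[:, :, 0]
        ke += np.einsum("mki,kl,mlj,m->mij", B, D, B, detJ) * thickness

    dof = np.empty((m, 8), dtype=int)
    dof[:, 0::2] = 2 * mesh.elements
    dof[:, 1::2] = 2 * mesh.elements + 1
    rows = np.repeat(dof, 8, axis=1).ravel()
    cols = np.tile(dof, (1, 8)).ravel()
    n_dof = 2 * mesh.n_nodes
    K = sparse.coo_matrix((ke.ravel(), (rows, cols)), shape=(n_dof, n_dof))
    return K.tocsr()


@dataclass(frozen=True)
class BendSolution:
    """Displacement-driven bend solve: stiffness and reaction bookkeeping."""

    m: float  # reaction force per unit prescribed displacement, N/mm
    reaction_N: float
    prescribed_mm: float
    left_reaction_N: float
    right_reaction_N: float
    u: np.ndarray  # (n_nodes, 2) displacement field


def solve_bend(
    mesh: QuadMesh,
    E: float,
    nu: float,
    thickness: float,
    prescribed_displacement: float = 1e-3,
) -> BendSolution:
    """Linear plane-stress solve of the displacement-driven bend test.

    Support patches are pinned vertically (left patch also horizontally,
    removing the rigid-body mode); the midspan top patch is displaced
    downward by ``prescribed_displacement``.  The apparent stiffness is
    the total vertical reaction on the loading patch per unit prescribed
    displacement.
    """
    if E <= 0 or prescribed_displacement <= 0:
        raise ValueError("E and prescribed displacement must be positive")
    K = _assemble_stiffness(mesh, E, nu, thickness)
    n_dof = 2 * mesh.n_nodes
    fixed: dict[int, float] = {}
    for n in mesh.node_sets["left_support"]:
        fixed[2 * n + 1] = 0.0
        fixed[2 * n] = 0.0
    for n in mesh.node_sets["right_support"]:
        fixed[2 * n + 1] = 0.0
    for n in mesh.node_sets["load"]:
        fixed[2 * n + 1] = -prescribed_displacement
    fixed_idx = np.array(sorted(fixed), dtype=int)
    fixed_val = np.array([fixed[i] for i in fixed_idx])
    free = np.setdiff1d(np.arange(n_dof), fixed_idx)

    rhs = -K[free][:, fixed_idx] @ fixed_val
    K_ff = K[free][:, free]
    with warnings.catch_warnings():
        warnings.simplefilter("error", sparse.linalg.MatrixRankWarning)
        try:
            u_free = spsolve(K_ff.tocsc(), rhs)
        except Exception as exc:
            raise ValueError(f"singular system (insufficient constraints?): {exc}") from exc
    if not np.all(np.isfinite(u_free)):
        raise ValueError("singular system: solve produced non-finite displacements")

    u = np.zeros(n_dof)
    u[free] = u_free
    u[fixed_idx] = fixed_val
    forces = K @ u
    load_dofs = 2 * np.asarray(mesh.node_sets["load"]) + 1
    reaction = float(-np.sum(forces[load_dofs]))  # downward prescribed -> positive load
    left = float(np.sum(forces[2 * np.asarray(mesh.node_sets["left_support"]) + 1]))
    right = float(np.sum(forces[2 * np.asarray(mesh.node_sets["right_support"]) + 1]))
    return BendSolution(
        m=reaction / prescribed_displacement,
        reaction_N=reaction,
        prescribed_mm=prescribed_displacement,
        left_reaction_N=left,
        right_reaction_N=right,
        u=u.reshape(-1, 2),
    )


def calibrate_E(
    m_exp: float,
    geometry: SpecimenGeometry,
    a0: float,
    E_trial: float = 12000.0,
    **mesh_kwargs,
) -> float:
    """Young's modulus reproducing a measured stiffness m (one-step, by linearity)."""
    if m_exp <= 0:
        raise ValueError("measured stiffness must be positive")
    mesh = mesh_beam(geometry, a0, **mesh_kwargs)
    m_trial = solve_bend(mesh, E_trial, geometry.nu, geometry.B).m
    return E_trial * m_exp / m_trial


@dataclass
class NotchCorrectionModel:
    """Second-order polynomial notch correction for measured flexural moduli.

    ``ratio(a0) = 1 + c1 a0 + c2 a0^2`` multiplies the measured notched
    flexural modulus to recover the modulus an un-notched bend test would
    have measured; ratio(0) = 1 by construction and the ratio is <= 1
    over the fitted range (the notched-width formula overestimates E).
    """

    coeffs: tuple[float, float, float]  # (1, c1, c2)
    a0_range: tuple[float, float]
    r2: float
    reference_modulus: Optional[float] = None  # apparent un-notched modulus of the fit

    def ratio(self, a0: float | np.ndarray) -> float | np.ndarray:
        c0, c1, c2 = self.coeffs
        return c0 + c1 * np.asarray(a0, dtype=float) + c2 * np.asarray(a0, dtype=float) ** 2

    def correct(self, E_f_measured: float, a0: float) -> float:
        lo, hi = self.a0_range
        if not (lo <= a0 <= hi):
            warnings.warn(
                f"extrapolating correction: a0={a0:.4g} outside fitted range "
                f"[{lo:.4g}, {hi:.4g}]",
                stacklevel=2,
            )
        return float(self.ratio(a0)) * E_f_measured

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "coeffs": list(self.coeffs),
                    "a0_range": list(self.a0_range),
                    "r2": self.r2,
                    "reference_modulus": self.reference_modulus,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path) -> "NotchCorrectionModel":
        d = json.loads(Path(path).read_text())
        return cls(
            coeffs=tuple(d["coeffs"]),
            a0_range=tuple(d["a0_range"]),
            r2=d["r2"],
            reference_modulus=d.get("reference_modulus"),
        )


def fit_correction(
    a0_values: Sequence[float],
    slopes: Sequence[float],
    geometry: SpecimenGeometry,
) -> NotchCorrectionModel:
    """Fit the quadratic notch-correction polynomial from stiffnesses m(a0).

    Each slope converts to an apparent flexural modulus with the notched
    formula; the correction factor g(a0) = E_f_app(0) / E_f_app(a0) is
    fitted by ``1 + c1 a0 + c2 a0^2`` (anchored at g(0) = 1).
    Requires >= 3 distinct notch lengths including a0 = 0.
    """
    a0s = np.asarray(a0_values, dtype=float)
    ms = np.asarray(slopes, dtype=float)
    if len(a0s) != len(ms):
        raise ValueError("a0_values and slopes must have equal length")
    if len(a0s) < 3:
        raise ValueError("need at least 3 notch-length points")
    if not np.any(np.isclose(a0s, 0.0)):
        raise ValueError("the un-notched case a0 = 0 must be included")
    e_app = np.array(
        [flexural_modulus(m, geometry.with_notch(a)) for a, m in zip(a0s, ms)]
    )
    e0 = float(np.mean(e_app[np.isclose(a0s, 0.0)]))
    g = e0 / e_app
    basis = np.column_stack([a0s, a0s**2])
    coef, *_ = np.linalg.lstsq(basis, g - 1.0, rcond=None)
    pred = 1.0 + basis @ coef
    ss_res = float(np.sum((g - pred) ** 2))
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return NotchCorrectionModel(
        coeffs=(1.0, float(coef[0]), float(coef[1])),
        a0_range=(float(a0s.min()), float(a0s.max())),
        r2=r2,
        reference_modulus=e0,
    )


def build_correction_model(
    geometry: SpecimenGeometry,
    a0_values: Sequence[float] = (0.0, 0.075, 0.15, 0.3),
    E: float = 12000.0,
    prescribed_displacement: float = 1e-3,
    **mesh_kwargs,
) -> tuple[NotchCorrectionModel, dict[float, float]]:
    """Run the FE study over the notch lengths and fit the correction model."""
    slopes: dict[float, float] = {}
    for a0 in a0_values:
        mesh = mesh_beam(geometry, a0, **mesh_kwargs)
        slopes[a0] = solve_bend(
            mesh, E, geometry.nu, geometry.B, prescribed_displacement
        ).m
    model = fit_correction(list(slopes), list(slopes.values()), geometry)
    return model, slopes
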