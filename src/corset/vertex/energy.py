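"""Tissue potential energy and its analytic gradient.

    w = sum_lateral_faces A  +  sum_cells alpha_c * P_apical,c^2
        + (psi / 2) * sum_cells (v_c - 1)^2

with the effective lateral surface tension as the energy unit (each lateral
face counted once), apical contractility ``alpha`` acting on the squared
perimeter of every cell's apical polygon — the standard vertex-model
contractility of an apical actomyosin ring, whose inward pull weakens as
the ring shortens, which is what stabilizes narrow-tube equilibria and
makes ``alpha`` dimensionless — and a soft quadratic penalty on deviations
of the cell volume from the preferred unit volume.  Apical faces carry no
area term (they are openings into the rachis) and basal faces carry no term
(they are fixed on the basement membrane).  Lengths are measured in units
of the basal (gonad) radius and volumes in units of the construction-time
cell volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..exceptions import ParameterError
from .mesh import TubeMesh

__all__ = ["EnergyParams", "tissue_energy", "energy_and_grad"]

_GUARD_ENERGY = 1.0e8  # returned when the configuration is degenerate


@dataclass
class EnergyParams:
    """Dimensionless energy coefficients.

    ``lateral_tension`` and the preferred volume are the model's units and
    stay fixed at 1; ``alpha`` and ``psi`` are the two free parameters.
    """

    alpha: float
    psi: float
    lateral_tension: float = 1.0
    preferred_volume: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ParameterError("alpha must be non-negative")
        if self.psi <= 0:
            raise ParameterError("psi must be positive")
        if self.lateral_tension != 1.0 or self.preferred_volume != 1.0:
            raise ParameterError("lateral tension and preferred volume are the model units (1)")


def _cell_alphas(mesh: TubeMesh, params: EnergyParams, alpha_per_cell):
    if alpha_per_cell is None:
        return np.full(mesh.n_cells, params.alpha)
    alpha_per_cell = np.asarray(alpha_per_cell, dtype=float)
    if np.any(alpha_per_cell < 0):
        raise ParameterError("per-cell alpha must be non-negative")
    return alpha_per_cell


def energy_and_grad(
    verts: np.ndarray,
    mesh: TubeMesh,
    params: EnergyParams,
    alpha_per_cell=None,
    want_grad: bool = True,
):
    """Energy and (optionally) its gradient with respect to all vertices.

    Returns ``(w, grad, info)``; ``grad`` is ``None`` when ``want_grad`` is
    False.  Degenerate configurations (near-zero cell volume or an apical
    vertex pulled almost onto the axis) trigger the inversion guard: a large
    constant energy is returned so that a line search rejects the step, and
    ``info["guard"]`` is set.
    """
    period = mesh.period
    nv = verts.shape[0]

    def gather(idx, shift):
        pp = verts[idx].copy()
        pp[..., 2] += shift.astype(float) * period
        return pp

    info: dict = {}

    # --- volumes (also used by the inversion guard) ---
    pt = gather(mesh.vol_tris, mesh.vol_shifts)  # (Nt, 3, 3)
    q_cross_r = np.cross(pt[:, 1], pt[:, 2])
    dets = np.einsum("ti,ti->t", pt[:, 0], q_cross_r)
    vol = np.bincount(mesh.vol_cells, weights=dets, minlength=mesh.n_cells)
    vol = vol / (6.0 * mesh.cell_volume0)
    info["volumes"] = vol

    apical_r = np.hypot(verts[mesh.free][:, 0], verts[mesh.free][:, 1])
    if vol.min() < 0.02 or apical_r.min() < 0.02 * mesh.basal_radius:
        info["guard"] = True
        g = np.zeros_like(verts) if want_grad else None
        return _GUARD_ENERGY, g, info
    info["guard"] = False

    # --- lateral face areas ---
    pl = gather(mesh.lateral_faces, mesh.lateral_shifts)  # (Nf, 4, 3)
    tri_sets = ((pl[:, 0], pl[:, 1], pl[:, 2]), (pl[:, 0], pl[:, 2], pl[:, 3]))
    e_lat = 0.0
    lat_grads = []
    for p, q, r in tri_sets:
        n = np.cross(q - p, r - p)
        nn = np.linalg.norm(n, axis=1)
        e_lat += 0.5 * nn.sum()
        if want_grad:
            nhat = n / np.maximum(nn, 1e-30)[:, None]
            gp = 0.5 * np.cross(q - r, nhat)
            gq = 0.5 * np.cross(r - p, nhat)
            gr = 0.5 * np.cross(p - q, nhat)
            lat_grads.append((gp, gq, gr))
    info["lateral_area"] = e_lat

    # --- apical contractility: alpha_c * P_c^2 ---
    alpha_c = _cell_alphas(mesh, params, alpha_per_cell)
    pe = gather(mesh.apical_edges, mesh.apical_edge_shifts)  # (Ne, 2, 3)
    d = pe[:, 1] - pe[:, 0]
    lengths = np.linalg.norm(d, axis=1)
    per_cell = np.zeros(mesh.n_cells)
    np.add.at(per_cell, mesh.apical_edge_cells[:, 0], lengths)
    np.add.at(per_cell, mesh.apical_edge_cells[:, 1], lengths)
    e_per = float((alpha_c * per_cell**2).sum())
    info["apical_perimeters"] = per_cell

    # --- compressibility ---
    dv = vol - 1.0
    e_vol = float(0.5 * params.psi * (dv**2).sum())

    w = params.lateral_tension * e_lat + e_per + e_vol
    if not want_grad:
        return w, None, info

    grad = np.zeros_like(verts)
    # scatter lateral-area gradients (triangles (0,1,2) and (0,2,3) per quad)
    corners = ((0, 1, 2), (0, 2, 3))
    for (i0, i1, i2), (gp, gq, gr) in zip(corners, lat_grads):
        np.add.at(grad, mesh.lateral_faces[:, i0], params.lateral_tension * gp)
        np.add.at(grad, mesh.lateral_faces[:, i1], params.lateral_tension * gq)
        np.add.at(grad, mesh.lateral_faces[:, i2], params.lateral_tension * gr)

    # contractility gradients: dE/dL_e = 2 alpha_c P_c summed over the two
    # incident cells of each shared apical edge
    ap_c = 2.0 * alpha_c * per_cell
    w_e = ap_c[mesh.apical_edge_cells[:, 0]] + ap_c[mesh.apical_edge_cells[:, 1]]
    dhat = d / np.maximum(lengths, 1e-30)[:, None]
    np.add.at(grad, mesh.apical_edges[:, 1], w_e[:, None] * dhat)
    np.add.at(grad, mesh.apical_edges[:, 0], -w_e[:, None] * dhat)

    # volume gradients: d(det)/dp = q x r, /dq = r x p, /dr = p x q
    coeff = (params.psi * dv)[mesh.vol_cells] / (6.0 * mesh.cell_volume0)
    np.add.at(grad, mesh.vol_tris[:, 0], coeff[:, None] * q_cross_r)
    np.add.at(grad, mesh.vol_tris[:, 1], coeff[:, None] * np.cross(pt[:, 2], pt[:, 0]))
    np.add.at(grad, mesh.vol_tris[:, 2], coeff[:, None] * np.cross(pt[:, 0], pt[:, 1]))

    return w, grad, info


def tissue_energy(
    mesh: TubeMesh,
    params: EnergyParams,
    alpha_per_cell=None,
) -> float:
    """Total tissue energy of the current mesh configuration."""
    w, _, info = energy_and_grad(mesh.verts, mesh, params, alpha_per_cell,
                                 want_grad=False)
    if info["guard"]:
        bad = int(np.argmin(info["volumes"]))
        raise ParameterError(
            f"degenerate configuration: cell {bad} has volume "
            f"{info['volumes'][bad]:.3g}"
        )
    return float(w)
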