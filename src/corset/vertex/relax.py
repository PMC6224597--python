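"""Quasi-static relaxation of the tube to its energy minimum.

Only apical vertices move (the basal surface adheres to the basement
membrane); equilibrium is declared when the residual force on every free
vertex drops below ``force_tol``.  The minimizer is L-BFGS with the analytic
gradient; an inversion guard rejects steps that collapse a cell or pull the
apical surface onto the axis, so a run into the collapsed regime terminates
flagged rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ..exceptions import ParameterError
from .energy import EnergyParams, energy_and_grad
from .mesh import TubeMesh

__all__ = ["TubeMorphology", "EquilibriumResult", "ModulationSpec",
           "relax", "relax_modulated", "measure_morphology", "residual_force"]


@dataclass
class TubeMorphology:
    """Shape descriptors of a (relaxed) tube configuration."""

    d_r: float  # rachis diameter = 2 x mean apical radial coordinate
    d_g: float  # gonad diameter = 2 x basal radius
    mean_height: float
    mean_apical_perimeter: float
    r_profile: np.ndarray = field(repr=False)  # per-ring mean apical radius
    z_profile: np.ndarray = field(repr=False)  # per-ring mean centroid z

    @property
    def ratio(self) -> float:
        return self.d_r / self.d_g

    @property
    def pearling_amplitude(self) -> float:
        """(max - min) / mean of the axial rachis-radius profile."""
        r = self.r_profile
        return float((r.max() - r.min()) / r.mean())


@dataclass
class EquilibriumResult:
    """Outcome of one energy minimization."""

    mesh: TubeMesh
    energy: float
    iterations: int
    max_force: float
    morphology: TubeMorphology
    converged: bool
    energy_trace: np.ndarray = field(repr=False)
    flags: list = field(default_factory=list)
    params: EnergyParams | None = None

    def summary(self) -> str:
        m = self.morphology
        lines = [
            "Vertex-model equilibrium",
            f"  converged             {self.converged}",
            f"  energy w              {self.energy:12.6f}",
            f"  iterations            {self.iterations:6d}",
            f"  max residual force    {self.max_force:12.3e}",
            f"  d_r/d_g               {m.ratio:12.4f}",
            f"  mean cell height      {m.mean_height:12.4f}",
            f"  mean apical perimeter {m.mean_apical_perimeter:12.4f}",
        ]
        if self.flags:
            lines.append("  flags: " + ", ".join(self.flags))
        return "\n".join(lines)


@dataclass
class ModulationSpec:
    """Axially modulated apical contractility alpha(z) = base + amp sin(2πz/λ + phase)."""

    base: float
    amplitude: float
    wavelength: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.base - abs(self.amplitude) < 0:
            raise ParameterError("modulation amplitude exceeds the base alpha")

    def alpha_of_z(self, z) -> np.ndarray:
        return self.base + self.amplitude * np.sin(
            2.0 * np.pi * np.asarray(z) / self.wavelength + self.phase
        )


def measure_morphology(mesh: TubeMesh) -> TubeMorphology:
    apical = mesh.verts[mesh.free]
    r_ap = np.hypot(apical[:, 0], apical[:, 1])
    d_r = 2.0 * float(r_ap.mean())
    d_g = 2.0 * mesh.basal_radius

    cents = mesh.apical_centroids()
    cent_r = np.hypot(cents[:, 0], cents[:, 1])
    heights = mesh.basal_radius - cent_r

    pe = mesh.gather(mesh.apical_edges, mesh.apical_edge_shifts)
    lengths = np.linalg.norm(pe[:, 1] - pe[:, 0], axis=1)
    per = np.zeros(mesh.n_cells)
    np.add.at(per, mesh.apical_edge_cells[:, 0], lengths)
    np.add.at(per, mesh.apical_edge_cells[:, 1], lengths)

    n_rings = mesh.n_axial
    r_prof = np.zeros(n_rings)
    z_prof = np.zeros(n_rings)
    for j in range(n_rings):
        sel = mesh.cell_ring == j
        r_prof[j] = float(cent_r[sel].mean())
        z_prof[j] = float(np.mean(mesh.cell_z0[sel]))
    return TubeMorphology(
        d_r=d_r, d_g=d_g, mean_height=float(heights.mean()),
        mean_apical_perimeter=float(per.mean()),
        r_profile=r_prof, z_profile=z_prof,
    )


def residual_force(mesh: TubeMesh, params: EnergyParams, alpha_per_cell=None) -> float:
    """Max per-vertex force magnitude over the free vertices."""
    _, g, info = energy_and_grad(mesh.verts, mesh, params, alpha_per_cell)
    if info["guard"]:
        return np.inf
    return float(np.linalg.norm(g[mesh.free], axis=1).max())


def relax(
    mesh: TubeMesh,
    params: EnergyParams,
    force_tol: float = 1e-6,
    max_iters: int = 20000,
    alpha_per_cell=None,
) -> EquilibriumResult:
    """Minimize the tissue energy over the free (apical) vertex coordinates."""
    free_idx = np.nonzero(mesh.free)[0]
    verts = mesh.verts.copy()
    trace: list = []

    def fun(x):
        verts[free_idx] = x.reshape(-1, 3)
        w, g, info = energy_and_grad(verts, mesh, params, alpha_per_cell)
        return w, g[free_idx].ravel()

    def cb(xk):
        verts[free_idx] = xk.reshape(-1, 3)
        w, _, _ = energy_and_grad(verts, mesh, params, alpha_per_cell,
                                  want_grad=False)
        trace.append(w)

    x0 = mesh.verts[free_idx].ravel()
    res = minimize(
        fun, x0, jac=True, method="L-BFGS-B", callback=cb,
        options=dict(maxiter=max_iters, maxfun=2 * max_iters,
                     ftol=1e-16, gtol=0.25 * force_tol, maxcor=30),
    )
    verts[free_idx] = res.x.reshape(-1, 3)
    out = mesh.with_verts(verts)
    w, g, info = energy_and_grad(verts, out, params, alpha_per_cell)
    flags = []
    if info["guard"]:
        flags.append("inversion guard hit")
        max_force = np.inf
    else:
        max_force = float(np.linalg.norm(g[out.free], axis=1).max())
    converged = (not info["guard"]) and max_force < force_tol
    if not converged and "inversion guard hit" not in flags:
        flags.append("not converged")
    return EquilibriumResult(
        mesh=out, energy=float(w), iterations=int(res.nit),
        max_force=max_force, morphology=measure_morphology(out),
        converged=converged, energy_trace=np.asarray(trace), flags=flags,
        params=params,
    )


def relax_modulated(
    mesh: TubeMesh,
    params: EnergyParams,
    mod: ModulationSpec,
    force_tol: float = 1e-6,
    max_iters: int = 20000,
):
    """Relax with axially modulated contractility.

    Each cell's alpha is assigned from its construction apical-centroid z.
    Returns ``(EquilibriumResult, pearling_amplitude)``.
    """
    alpha_c = mod.alpha_of_z(mesh.cell_z0)
    res = relax(mesh, params, force_tol=force_tol, max_iters=max_iters,
                alpha_per_cell=alpha_c)
    return res, res.morphology.pearling_amplitude
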