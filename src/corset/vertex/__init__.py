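"""3D vertex model of the gonadal tube."""

from __future__ import annotations

import json

import numpy as np

from .calibrate import calibrate_alpha_wt
from .energy import EnergyParams, energy_and_grad, tissue_energy
from .mesh import TubeMesh, build_tube
from .phase import PhaseDiagram, phase_diagram
from .relax import (
    EquilibriumResult,
    ModulationSpec,
    TubeMorphology,
    measure_morphology,
    relax,
    relax_modulated,
    residual_force,
)

__all__ = [
    "EnergyParams", "TubeMesh", "TubeMorphology", "EquilibriumResult",
    "ModulationSpec", "PhaseDiagram", "TubeModel",
    "build_tube", "tissue_energy", "energy_and_grad", "relax",
    "relax_modulated", "calibrate_alpha_wt", "phase_diagram",
    "measure_morphology", "residual_force", "save_mesh_json",
]


class TubeModel:
    """Model-object facade over the vertex-model tube.

    Builds the periodic mesh once; :meth:`relax` returns an
    :class:`EquilibriumResult` (estimates + diagnostics + ``summary()``).
    """

    def __init__(self, n_circ: int = 10, n_axial: int = 16,
                 target_ratio: float = 0.56, seed: int | None = None):
        self.mesh = build_tube(n_circ=n_circ, n_axial=n_axial,
                               target_ratio=target_ratio, seed=seed)

    def relax(self, alpha: float, psi: float, force_tol: float = 1e-6,
              **kw) -> EquilibriumResult:
        return relax(self.mesh, EnergyParams(alpha=alpha, psi=psi),
                     force_tol=force_tol, **kw)

    def relax_modulated(self, mod: ModulationSpec, psi: float,
                        force_tol: float = 1e-6):
        return relax_modulated(self.mesh, EnergyParams(alpha=mod.base, psi=psi),
                               mod, force_tol=force_tol)

    def calibrate(self, psi: float = 0.38, target_ratio: float = 0.56,
                  bracket: tuple = (0.05, 0.5), **kw) -> float:
        return calibrate_alpha_wt(psi=psi, target_ratio=target_ratio,
                                  bracket=bracket, mesh=self.mesh, **kw)


def save_mesh_json(mesh: TubeMesh, path) -> None:
    """Snapshot the mesh (vertices + cell polygons) as JSON."""
    out = dict(
        n_circ=mesh.n_circ, n_axial=mesh.n_axial, period=mesh.period,
        basal_radius=mesh.basal_radius,
        vertices=np.round(mesh.verts, 9).tolist(),
        apical_polys=mesh.apical_polys.tolist(),
        basal_polys=mesh.basal_polys.tolist(),
    )
    with open(path, "w") as fh:
        json.dump(out, fh)
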