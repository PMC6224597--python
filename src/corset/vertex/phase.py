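"""Morphological phase diagram over (alpha/alpha_WT, psi).

Every grid point is a full relaxation; continuation seeds each point from
its row neighbor's equilibrium to follow one branch of minimal-energy
solutions (``from-wide`` sweeps alpha upward starting in the wide-tube
regime, ``from-narrow`` sweeps downward from the narrow regime).  Points are
labeled *wide* when the equilibrium d_r/d_g exceeds the wild-type ratio and
*narrow* otherwise, and isolines of fixed d_r/d_g are extracted by linear
interpolation along each psi row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import calibrate_alpha_wt
from .energy import EnergyParams
from .mesh import build_tube
from .relax import relax

__all__ = ["PhaseDiagram", "phase_diagram"]


@dataclass
class PhaseDiagram:
    table: pd.DataFrame  # alpha_rel, psi, alpha, ratio, energy, converged, regime
    alpha_wt: float
    wt_ratio: float
    calibration_psi: float
    meta: dict = field(default_factory=dict)

    def row(self, psi: float) -> pd.DataFrame:
        sel = np.isclose(self.table["psi"], psi)
        return self.table[sel].sort_values("alpha_rel")

    def isoline(self, target_ratio: float) -> pd.DataFrame:
        """alpha/alpha_WT at which each psi row crosses ``target_ratio``."""
        rows = []
        for psi in sorted(self.table["psi"].unique()):
            r = self.row(psi)
            r = r[r["converged"]]
            a = r["alpha_rel"].to_numpy()
            y = r["ratio"].to_numpy() - target_ratio
            crossings = []
            for i in range(len(y) - 1):
                if y[i] == 0.0:
                    crossings.append(float(a[i]))
                elif y[i] * y[i + 1] < 0:
                    frac = y[i] / (y[i] - y[i + 1])
                    crossings.append(float(a[i] + frac * (a[i + 1] - a[i])))
            if len(y) and y[-1] == 0.0:
                crossings.append(float(a[-1]))
            for c in crossings:
                rows.append(dict(psi=float(psi), alpha_rel=c,
                                 target=target_ratio,
                                 n_crossings=len(crossings)))
        return pd.DataFrame(rows, columns=["psi", "alpha_rel", "target", "n_crossings"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def plot(self, ax=None, isolines=(0.75, 0.56, 0.41)):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        piv = self.table.pivot(index="psi", columns="alpha_rel", values="ratio")
        im = ax.pcolormesh(piv.columns, piv.index, piv.values, shading="nearest")
        plt.colorbar(im, ax=ax, label=r"$d_r/d_g$")
        for tgt in isolines:
            iso = self.isoline(tgt)
            if len(iso):
                ax.plot(iso["alpha_rel"], iso["psi"], "w--", lw=1)
        ax.set_xlabel(r"$\alpha/\alpha_{WT}$")
        ax.set_ylabel(r"$\psi$")
        return ax


DEFAULT_ALPHA_REL = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.2)
DEFAULT_PSI = (0.30, 0.34, 0.38, 0.42, 0.46, 0.50)


def phase_diagram(
    alpha_rel_grid=DEFAULT_ALPHA_REL,
    psi_grid=DEFAULT_PSI,
    alpha_wt: float | None = None,
    wt_ratio: float = 0.56,
    calibration_psi: float = 0.38,
    continuation: str = "from-wide",
    n_circ: int = 10,
    n_axial: int = 16,
    force_tol: float = 1e-6,
    fold_refine: int = 3,
) -> PhaseDiagram:
    """Relax the tube on a grid of (alpha/alpha_WT, psi).

    Past a critical contractility the narrow branch folds and the tube
    collapses; after the first unconverged point of a row, up to
    ``fold_refine`` bisection steps in alpha are inserted so the row's last
    equilibria approach the fold (needed to bracket the narrowest isoline).
    """
    if continuation not in ("from-wide", "from-narrow"):
        raise ValueError("continuation must be 'from-wide' or 'from-narrow'")
    alpha_rel_grid = np.asarray(sorted(alpha_rel_grid), dtype=float)
    psi_grid = np.asarray(sorted(psi_grid), dtype=float)
    if alpha_wt is None:
        alpha_wt = calibrate_alpha_wt(
            psi=calibration_psi, target_ratio=wt_ratio,
            n_circ=n_circ, n_axial=n_axial, force_tol=force_tol,
        )
    mesh0 = build_tube(n_circ=n_circ, n_axial=n_axial, target_ratio=wt_ratio)
    order = alpha_rel_grid if continuation == "from-wide" else alpha_rel_grid[::-1]
    rows = []
    for psi in psi_grid:
        mesh = mesh0  # each row restarts from the construction geometry
        last_ok = None  # last converged alpha_rel of this row

        def _one(a_rel, mesh):
            res = relax(mesh, EnergyParams(alpha=float(a_rel * alpha_wt),
                                           psi=float(psi)),
                        force_tol=force_tol)
            rows.append(dict(
                alpha_rel=float(a_rel), psi=float(psi),
                alpha=float(a_rel * alpha_wt),
                ratio=res.morphology.ratio if res.converged else np.nan,
                energy=res.energy if res.converged else np.nan,
                converged=bool(res.converged),
                regime=("wide" if res.converged and res.morphology.ratio > wt_ratio
                        else "narrow" if res.converged else "unconverged"),
            ))
            return res

        for a_rel in order:
            res = _one(a_rel, mesh)
            if res.converged:
                mesh = res.mesh
                last_ok = a_rel
            elif last_ok is not None and a_rel > last_ok:
                lo, hi = last_ok, a_rel
                for _ in range(fold_refine):
                    mid = 0.5 * (lo + hi)
                    r2 = _one(mid, mesh)
                    if r2.converged:
                        mesh = r2.mesh
                        lo = mid
                    else:
                        hi = mid
                break  # rest of the row is past the fold
    table = pd.DataFrame(rows).sort_values(["psi", "alpha_rel"]).reset_index(drop=True)
    return PhaseDiagram(
        table=table, alpha_wt=float(alpha_wt), wt_ratio=wt_ratio,
        calibration_psi=calibration_psi,
        meta=dict(continuation=continuation, n_circ=n_circ, n_axial=n_axial),
    )
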