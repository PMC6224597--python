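"""Calibration of the wild-type apical contractility.

The wild-type contractility ``alpha_WT`` is defined by the balance of radial
forces that puts the equilibrium rachis-to-gonad diameter ratio at the
experimentally measured wild-type value (0.56): a bisection on alpha, with a
full relaxation at every trial value.
"""

from __future__ import annotations

import numpy as np

from ..exceptions import CalibrationError
from .energy import EnergyParams
from .mesh import TubeMesh, build_tube
from .relax import relax

__all__ = ["calibrate_alpha_wt"]


def calibrate_alpha_wt(
    psi: float = 0.38,
    target_ratio: float = 0.56,
    bracket: tuple = (0.05, 0.5),
    n_circ: int = 10,
    n_axial: int = 16,
    mesh: TubeMesh | None = None,
    ratio_tol: float = 0.005,
    alpha_tol: float = 5e-4,
    force_tol: float = 1e-6,
) -> float:
    """Bisect alpha until the relaxed equilibrium hits ``target_ratio``.

    The equilibrium ratio is decreasing in alpha, so ``g(alpha) = ratio -
    target`` must change sign over the bracket; otherwise a
    :class:`CalibrationError` reports the endpoint ratios.
    """
    if mesh is None:
        mesh = build_tube(n_circ=n_circ, n_axial=n_axial, target_ratio=target_ratio)

    def g(alpha):
        res = relax(mesh, EnergyParams(alpha=alpha, psi=psi), force_tol=force_tol)
        if not res.converged:
            # past the collapse fold: no tubular equilibrium, which can only
            # happen on the narrow (high-alpha) side -> count as below target
            return -target_ratio
        return res.morphology.ratio - target_ratio

    lo, hi = bracket
    g_lo, g_hi = g(lo), g(hi)
    if np.sign(g_lo) == np.sign(g_hi):
        raise CalibrationError(
            "target ratio not bracketed: "
            f"ratio({lo:g}) = {g_lo + target_ratio:.4f}, "
            f"ratio({hi:g}) = {g_hi + target_ratio:.4f}"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        g_mid = g(mid)
        if abs(g_mid) < ratio_tol and (hi - lo) < 2.0 * alpha_tol:
            return mid
        if np.sign(g_mid) == np.sign(g_lo):
            lo, g_lo = mid, g_mid
        else:
            hi, g_hi = mid, g_mid
        if (hi - lo) < alpha_tol and abs(g_mid) < ratio_tol:
            return mid
    return 0.5 * (lo + hi)
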