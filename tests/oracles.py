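"""Independent oracle implementations used to cross-check the package.

Everything here is written from first principles (loops, no shared code
paths with ``corset``) so that agreement is evidence, not tautology.
"""

import numpy as np


def brute_force_energy(mesh, alpha, psi, alpha_per_cell=None):
    """Tissue energy by plain per-cell loops.

    Re-implements w = sum(lateral areas, each face once) +
    sum_c alpha_c P_c^2 + (psi/2) sum_c (v_c - 1)^2 from the mesh tables,
    gathering coordinates and triangulating faces independently.
    """
    period = mesh.period

    def pos(idx, shift):
        p = np.array(mesh.verts[idx], dtype=float)
        p[2] += shift * period
        return p

    def tri_area(p, q, r):
        return 0.5 * np.linalg.norm(np.cross(q - p, r - p))

    # lateral faces, once each
    e_lat = 0.0
    for f in range(mesh.lateral_faces.shape[0]):
        quad = [pos(mesh.lateral_faces[f, k], mesh.lateral_shifts[f, k])
                for k in range(4)]
        e_lat += tri_area(quad[0], quad[1], quad[2])
        e_lat += tri_area(quad[0], quad[2], quad[3])

    # per-cell apical perimeter from the polygon loop
    n_cells = mesh.n_cells
    alphas = (np.full(n_cells, alpha) if alpha_per_cell is None
              else np.asarray(alpha_per_cell, dtype=float))
    e_ap = 0.0
    for c in range(n_cells):
        poly = [pos(mesh.apical_polys[c, k], mesh.apical_shifts[c, k])
                for k in range(6)]
        per = sum(np.linalg.norm(poly[(k + 1) % 6] - poly[k]) for k in range(6))
        e_ap += alphas[c] * per**2

    # per-cell volume by divergence theorem over the same triangulation
    vols = np.zeros(n_cells)
    for t in range(mesh.vol_tris.shape[0]):
        p, q, r = (pos(mesh.vol_tris[t, k], mesh.vol_shifts[t, k])
                   for k in range(3))
        vols[mesh.vol_cells[t]] += np.dot(p, np.cross(q, r)) / 6.0
    vols = vols / mesh.cell_volume0
    e_vol = 0.5 * psi * np.sum((vols - 1.0) ** 2)
    return e_lat + e_ap + e_vol


def single_exponential(t, linf, a, tau, t0):
    """Plain single-exponential relaxation evaluator."""
    return linf - a * np.exp(-(np.asarray(t) - t0) / tau)


def ramanujan_perimeter(a, b):
    """Ramanujan's second approximation to the ellipse perimeter."""
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h)))


def frap_recovery(t, P, k):
    return P * (1.0 - np.exp(-k * np.asarray(t)))
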