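"""Periodic hexagonal-prism mesh of the gonadal tube.

Cells are hexagonal prisms between two coaxial cylindrical surfaces: the
basal (outer) polygon of every cell is fixed on the gonad surface and the
apical (inner) polygon, opening into the rachis, is free.  Rings of
``n_circ`` cells are stacked along the tube axis with a half-pitch offset on
alternating rings, giving the honeycomb topology in which every apical
vertex is shared by exactly three cells.  The axial direction is periodic.

Nondimensionalization: the basal cylinder radius is the unit of length and
the construction-time cell volume is the unit of volume, so every cell has
volume exactly 1 at the initial geometry and the preferred volume is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..exceptions import ParameterError, TopologyError

__all__ = ["TubeMesh", "build_tube"]


@dataclass
class TubeMesh:
    """Vertex-model state: coordinates, topology and gather tables.

    All index arrays are paired with ``*_shift`` arrays holding the axial
    periodic image (-1, 0, +1); a vertex gathered with shift ``s`` lives at
    ``verts[idx] + (0, 0, s * period)``.
    """

    verts: np.ndarray  # (Nv, 3)
    free: np.ndarray  # (Nv,) bool, True for movable (apical) vertices
    n_circ: int
    n_axial: int
    period: float  # axial period length
    basal_radius: float
    cell_volume0: float  # construction cell volume = volume unit

    # per-cell polygons: (n_cells, 6) vertex indices + shifts
    basal_polys: np.ndarray
    basal_shifts: np.ndarray
    apical_polys: np.ndarray
    apical_shifts: np.ndarray
    cell_ring: np.ndarray  # (n_cells,) ring index of each cell

    # unique lateral faces (b1, b2, a2, a1): (n_faces, 4) + shifts
    lateral_faces: np.ndarray
    lateral_shifts: np.ndarray

    # unique apical edges: (n_edges, 2) + shifts + the two incident cells
    apical_edges: np.ndarray
    apical_edge_shifts: np.ndarray
    apical_edge_cells: np.ndarray  # (n_edges, 2)

    # volume triangulation: (n_tris, 3) + shifts + owning cell
    vol_tris: np.ndarray
    vol_shifts: np.ndarray
    vol_cells: np.ndarray

    cell_z0: np.ndarray = field(default=None)  # construction apical-centroid z

    @property
    def n_cells(self) -> int:
        return self.basal_polys.shape[0]

    @property
    def n_verts(self) -> int:
        return self.verts.shape[0]

    @property
    def apical_mask(self) -> np.ndarray:
        return self.free

    def gather(self, idx, shift) -> np.ndarray:
        p = self.verts[idx].copy()
        p[..., 2] += shift * self.period
        return p

    def with_verts(self, verts: np.ndarray) -> "TubeMesh":
        return replace(self, verts=np.asarray(verts, dtype=float))

    def translated(self, dz: float) -> "TubeMesh":
        """Axially translated copy (periodicity lives in the shift tables,
        so coordinates are not wrapped)."""
        v = self.verts.copy()
        v[:, 2] = v[:, 2] + dz
        return self.with_verts(v)

    def rotated(self, angle: float) -> "TubeMesh":
        """Copy rotated rigidly about the tube axis."""
        c, s = np.cos(angle), np.sin(angle)
        v = self.verts.copy()
        x, y = v[:, 0].copy(), v[:, 1].copy()
        v[:, 0] = c * x - s * y
        v[:, 1] = s * x + c * y
        return self.with_verts(v)

    def cell_volumes(self) -> np.ndarray:
        """Signed cell volumes in units of the construction volume."""
        p = self.gather(self.vol_tris, self.vol_shifts)  # (Nt, 3, 3)
        dets = np.einsum("ti,ti->t", p[:, 0], np.cross(p[:, 1], p[:, 2]))
        vol = np.bincount(self.vol_cells, weights=dets, minlength=self.n_cells) / 6.0
        return vol / self.cell_volume0

    def apical_centroids(self) -> np.ndarray:
        return self.gather(self.apical_polys, self.apical_shifts).mean(axis=1)

    def apical_vertex_count(self) -> np.ndarray:
        """Number of incident cells per apical vertex (topology check)."""
        counts = np.zeros(self.n_verts, dtype=int)
        np.add.at(counts, self.apical_polys.ravel(), 1)
        return counts[self.free]


def _vid(surface, j, i, t, n_circ, n_axial):
    nb = 2 * n_circ * n_axial
    return surface * nb + (j * n_circ + i) * 2 + t


def build_tube(
    n_circ: int = 10,
    n_axial: int = 16,
    target_ratio: float = 0.56,
    seed: int | None = None,
    jitter: float = 0.1,
    pitch_factor: float = 1.0,
) -> TubeMesh:
    """Build the periodic tube mesh at a chosen apical/basal radius ratio.

    The basal radius is 1; the axial ring pitch makes the basal hexagons
    regular in the unrolled plane, and the apical surface starts at radius
    ``target_ratio`` with every cell volume equal to 1 volume unit.  With a
    ``seed``, apical vertices are jittered tangentially by ``jitter`` x the
    lattice pitch (disordered-packing variant).
    """
    if n_circ % 2 != 0:
        raise TopologyError("n_circ must be even for the offset rings to wrap")
    if n_axial % 2 != 0 or n_axial < 4:
        raise TopologyError("n_axial must be even and at least 4")
    if not 0.05 < target_ratio < 0.95:
        raise ParameterError("target_ratio must lie in (0.05, 0.95)")

    R = 1.0
    a = 2.0 * np.pi * R / n_circ  # circumferential pitch (arc length)
    # axial ring pitch: regular hexagons in the unrolled basal plane by
    # default; pitch_factor < 1 shortens cells axially (e.g. regular at the
    # apical surface for pitch_factor = target_ratio)
    p = pitch_factor * np.sqrt(3.0) / 2.0 * a
    period = n_axial * p
    nb = 2 * n_circ * n_axial

    # vertex positions: N (t=0) and S (t=1) lattice nodes of each cell
    verts = np.zeros((2 * nb, 3))
    for j in range(n_axial):
        for i in range(n_circ):
            u = (i + 0.5 * (j % 2)) * a
            theta = u / R
            zc = j * p
            for t, dz in ((0, 2.0 * p / 3.0), (1, -2.0 * p / 3.0)):
                for surf, rad in ((0, R), (1, target_ratio * R)):
                    v = _vid(surf, j, i, t, n_circ, n_axial)
                    verts[v] = (rad * np.cos(theta), rad * np.sin(theta), zc + dz)

    free = np.zeros(2 * nb, dtype=bool)
    free[nb:] = True

    n_cells = n_circ * n_axial
    basal_polys = np.zeros((n_cells, 6), dtype=np.int64)
    basal_shifts = np.zeros((n_cells, 6), dtype=np.int8)
    cell_ring = np.zeros(n_cells, dtype=np.int64)

    for j in range(n_axial):
        up, s_up = (j + 1) % n_axial, (1 if j == n_axial - 1 else 0)
        dn, s_dn = (j - 1) % n_axial, (-1 if j == 0 else 0)
        for i in range(n_circ):
            c = j * n_circ + i
            cell_ring[c] = j
            li = (i - 1 + (j % 2)) % n_circ  # left neighbor column
            ri = (i + (j % 2)) % n_circ  # right neighbor column
            # CCW in the unrolled (u, z) plane -> outward basal normal
            nodes = [
                (j, i, 0, 0),  # N
                (up, li, 1, s_up),  # upper-left S
                (dn, li, 0, s_dn),  # lower-left N
                (j, i, 1, 0),  # S
                (dn, ri, 0, s_dn),  # lower-right N
                (up, ri, 1, s_up),  # upper-right S
            ]
            for k, (jj, ii, tt, ss) in enumerate(nodes):
                basal_polys[c, k] = _vid(0, jj, ii, tt, n_circ, n_axial)
                basal_shifts[c, k] = ss

    apical_polys = basal_polys + nb
    apical_shifts = basal_shifts.copy()

    # unique lateral faces and apical edges (each hexagon edge shared by 2 cells)
    seen = {}
    lat_faces, lat_shifts = [], []
    edge_idx, edge_shifts, edge_cells = [], [], []
    for c in range(n_cells):
        for k in range(6):
            k2 = (k + 1) % 6
            b1, b2 = basal_polys[c, k], basal_polys[c, k2]
            s1, s2 = int(basal_shifts[c, k]), int(basal_shifts[c, k2])
            key = (b1, b2, s2 - s1) if b1 < b2 else (b2, b1, s1 - s2)
            if key in seen:
                edge_cells[seen[key]][1] = c
                continue
            seen[key] = len(lat_faces)
            lat_faces.append([b1, b2, b2 + nb, b1 + nb])
            lat_shifts.append([s1, s2, s2, s1])
            edge_idx.append([b1 + nb, b2 + nb])
            edge_shifts.append([s1, s2])
            edge_cells.append([c, c])
    lateral_faces = np.asarray(lat_faces, dtype=np.int64)
    lateral_shifts = np.asarray(lat_shifts, dtype=np.int8)
    apical_edges = np.asarray(edge_idx, dtype=np.int64)
    apical_edge_shifts = np.asarray(edge_shifts, dtype=np.int8)
    apical_edge_cells = np.asarray(edge_cells, dtype=np.int64)

    # closed-surface triangulation per cell for divergence-theorem volumes
    tris, tshifts, tcells = [], [], []
    for c in range(n_cells):
        bp, bs = basal_polys[c], basal_shifts[c]
        ap, asf = apical_polys[c], apical_shifts[c]
        for k in range(1, 5):  # basal fan, outward (+r) normal
            tris.append([bp[0], bp[k], bp[k + 1]])
            tshifts.append([bs[0], bs[k], bs[k + 1]])
            tcells.append(c)
        rp, rs = ap[::-1], asf[::-1]  # apical fan, outward (-r) normal
        for k in range(1, 5):
            tris.append([rp[0], rp[k], rp[k + 1]])
            tshifts.append([rs[0], rs[k], rs[k + 1]])
            tcells.append(c)
        for k in range(6):  # lateral quads, outward of the prism
            k2 = (k + 1) % 6
            quad = [bp[k2], bp[k], ap[k], ap[k2]]
            qs = [bs[k2], bs[k], asf[k], asf[k2]]
            tris.append([quad[0], quad[1], quad[2]])
            tshifts.append([qs[0], qs[1], qs[2]])
            tcells.append(c)
            tris.append([quad[0], quad[2], quad[3]])
            tshifts.append([qs[0], qs[2], qs[3]])
            tcells.append(c)
    vol_tris = np.asarray(tris, dtype=np.int64)
    vol_shifts = np.asarray(tshifts, dtype=np.int8)
    vol_cells = np.asarray(tcells, dtype=np.int64)

    mesh = TubeMesh(
        verts=verts, free=free, n_circ=n_circ, n_axial=n_axial, period=period,
        basal_radius=R, cell_volume0=1.0,
        basal_polys=basal_polys, basal_shifts=basal_shifts,
        apical_polys=apical_polys, apical_shifts=apical_shifts,
        cell_ring=cell_ring,
        lateral_faces=lateral_faces, lateral_shifts=lateral_shifts,
        apical_edges=apical_edges, apical_edge_shifts=apical_edge_shifts,
        apical_edge_cells=apical_edge_cells,
        vol_tris=vol_tris, vol_shifts=vol_shifts, vol_cells=vol_cells,
    )
    # set the volume unit so each construction cell has volume exactly 1
    raw = mesh.cell_volumes() * mesh.cell_volume0
    v0 = float(raw.mean())
    if v0 <= 0:
        raise TopologyError("construction volumes are non-positive")
    mesh.cell_volume0 = v0
    mesh.cell_z0 = mesh.apical_centroids()[:, 2].copy()

    if seed is not None and jitter > 0:
        rng = np.random.default_rng(seed)
        amp = jitter * min(a, p) * target_ratio
        d = rng.uniform(-amp, amp, (nb, 3))
        verts2 = mesh.verts.copy()
        verts2[nb:] += d
        mesh = mesh.with_verts(verts2)
        mesh.cell_z0 = mesh.apical_centroids()[:, 2].copy()
    return mesh
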