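"""Synthetic two-channel image stacks of the gonadal tube.

The tube is rendered as a straight cylinder along the image x axis: the
membrane channel carries the outer basal shell and T-shaped radial
partitions between germ cells, and the corset channel carries the inner
actomyosin tube with one circular bridge opening per cell, brightened on the
rim around each opening (where ANI-2-like signal is enriched in vivo).
Cells are laid out as angular sectors x axial columns with a half-sector
offset on alternating columns.  Per-cell heights and bridge radii are
configurable; the ground truth records ``d_r = d_g - 2*mean(height)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ..exceptions import ParameterError
from ..morphometrics import ImageStack
from .base import GroundTruth


@dataclass
class SyntheticTubeTruth:
    heights: np.ndarray  # (n_axial, n_circ) µm
    bridge_radii: np.ndarray  # (n_axial, n_circ) µm
    d_r: float  # µm, = d_g - 2*mean(height)
    d_g: float  # µm
    voxel: float  # µm/px
    n_circ: int
    n_axial: int
    top_slices: slice  # recommended projection range for bridge analysis
    mid_slice: int


def _per_cell(value, n_axial, n_circ, name):
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full((n_axial, n_circ), float(arr))
    elif arr.shape != (n_axial, n_circ):
        arr = np.broadcast_to(arr, (n_axial, n_circ)).copy()
    if np.any(arr <= 0):
        raise ParameterError(f"all {name} must be positive")
    return arr


def corset_surface_mask(truth: "SyntheticTubeTruth") -> np.ndarray:
    """Unrolled (circumference x axis) boolean mask of the corset surface.

    True where corset signal lies, False inside the bridge openings; every
    cell contributes exactly one opening, so labeling the complement counts
    ``n_circ * n_axial`` holes.
    """
    voxel = truth.voxel
    r_cell = (0.5 * truth.d_g - truth.heights) / voxel  # (n_axial, n_circ) px
    r_m = float(r_cell.mean())
    dphi = 2.0 * np.pi / truth.n_circ
    p_ax = max(int(round(r_m * dphi)), 4)
    nu = int(round(2.0 * np.pi * r_m))
    nx = truth.n_axial * p_ax
    uu, xx = np.mgrid[:nu, :nx].astype(float)
    mask = np.ones((nu, nx), dtype=bool)
    for j in range(truth.n_axial):
        off = 0.5 * dphi * (j % 2)
        for s in range(truth.n_circ):
            u_c = (off + (s + 0.5) * dphi) / (2.0 * np.pi) * nu
            x_c = (j + 0.5) * p_ax
            du = np.abs(uu - u_c)
            du = np.minimum(du, nu - du)  # periodic circumference
            hole = np.hypot(du, xx - x_c) < truth.bridge_radii[j, s] / voxel
            mask[hole] = False
    return mask


def gen_tube_stack(
    n_circ: int = 12,
    n_axial: int = 8,
    heights=5.5,
    bridge_radii=1.5,
    d_g: float = 25.0,
    voxel: float = 0.25,
    noise_sd: float = 0.0,
    psf_sigma: float = 0.0,
    seed: int | None = None,
    shell_um: float = 0.4,
    rim_um: float = 0.5,
):
    """Render a two-channel tube stack plus its ground truth.

    ``heights`` and ``bridge_radii`` may be scalars or (n_axial, n_circ)
    arrays in µm.  Returns ``(ImageStack, SyntheticTubeTruth, GroundTruth)``.
    """
    if not 8 <= n_circ <= 16:
        raise ParameterError("n_circ must lie in [8, 16]")
    h = _per_cell(heights, n_axial, n_circ, "heights")
    br = _per_cell(bridge_radii, n_axial, n_circ, "bridge radii")
    if d_g - 2.0 * h.max() <= 0:
        raise ParameterError("cell heights exceed the gonad radius")

    r_g = 0.5 * d_g / voxel  # px
    r_cell = r_g - h / voxel  # (n_axial, n_circ) px, inner (apical) radius
    r_mean = float(r_cell.mean())
    dphi = 2.0 * np.pi / n_circ
    # geometric feasibility: the opening must fit within its cell's apex
    pitch_circ = r_cell * dphi * voxel
    p_ax = max(int(round(r_mean * dphi)), 4)  # axial pitch, px
    pitch_ax = p_ax * voxel
    if np.any(2.0 * br >= np.minimum(pitch_circ, pitch_ax)):
        raise ParameterError("bridge opening larger than the cell apex")

    margin = max(int(round(6 * voxel / voxel)), 8)
    nyz = 2 * int(np.ceil(r_g)) + 2 * margin
    cy = cz = nyz / 2.0 - 0.5
    nx = n_axial * p_ax
    tsh = max(shell_um / voxel / 2.0, 0.8)  # shell half-thickness, px
    rim = rim_um / voxel  # rim width, px

    zz, yy = np.mgrid[:nyz, :nyz].astype(float)
    rho = np.hypot(zz - cz, yy - cy)
    phi = np.arctan2(zz - cz, yy - cy)  # (-pi, pi]

    corset = np.zeros((nyz, nyz, nx), dtype=np.float32)
    membrane = np.zeros((nyz, nyz, nx), dtype=np.float32)

    # basal shell (membrane channel), independent of x
    shell = (np.abs(rho - r_g) < tsh).astype(np.float32)
    membrane += shell[:, :, None]

    for j in range(n_axial):
        xs = slice(j * p_ax, (j + 1) * p_ax)
        x_local = np.arange(j * p_ax, (j + 1) * p_ax, dtype=float)
        off = 0.5 * dphi * (j % 2)
        sector = np.floor((phi - off) / dphi).astype(int) % n_circ
        phi_c = off + (sector + 0.5) * dphi
        dph = np.angle(np.exp(1j * (phi - phi_c)))
        r_c = r_cell[j, sector]  # (nyz, nyz)
        hole_r = br[j, sector] / voxel

        on_shell = np.abs(rho - r_c) < tsh  # (nyz, nyz)
        # on-surface distance to the cell's bridge center
        x_c = (j + 0.5) * p_ax
        ds_circ = (r_c * dph)[:, :, None]
        ds_ax = (x_local - x_c)[None, None, :]
        s = np.hypot(ds_circ, ds_ax)  # (nyz, nyz, p_ax)
        inside_hole = s < hole_r[:, :, None]
        on_rim = (s >= hole_r[:, :, None]) & (s < (hole_r[:, :, None] + rim))
        base = on_shell[:, :, None] & ~inside_hole
        corset[:, :, xs] += 0.5 * base + 0.5 * (base & on_rim)

        # membrane: radial partitions at sector boundaries, apical->basal,
        # plus the tangential cap near the apical end (the T crossbar)
        near_boundary = np.abs(r_c * (np.abs(dph) - 0.5 * dphi)) < tsh
        radial_wall = near_boundary & (rho >= r_c - tsh) & (rho <= r_g)
        membrane[:, :, xs] += radial_wall[:, :, None].astype(np.float32)
        cap = (np.abs(rho - r_c) < tsh) & (np.abs(dph) > 0.5 * dphi - 2.0 * tsh / np.maximum(r_c, 1))
        membrane[:, :, xs] += 0.5 * cap[:, :, None].astype(np.float32)

    # axial partition walls between cell columns (annular disks)
    annulus = (rho <= r_g) & (rho >= r_cell.min() - tsh)
    for j in range(1, n_axial):
        xw = j * p_ax
        membrane[:, :, max(xw - 1, 0):xw + 1] += 0.5 * annulus[:, :, None].astype(np.float32)

    membrane = np.clip(membrane, 0, 1.2)
    corset = np.clip(corset, 0, 1.0)

    rng = np.random.default_rng(seed)
    data = np.stack([membrane, corset], axis=1)  # (nz, 2, ny, nx)
    if psf_sigma > 0:
        for c in range(2):
            data[:, c] = gaussian_filter(data[:, c], psf_sigma)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, data.shape).astype(np.float32)

    stack = ImageStack(data=data, voxel_xy=voxel, voxel_z=voxel,
                       channels={"membrane": 0, "corset": 1})
    d_r = d_g - 2.0 * float(h.mean())
    z_top = int(round(cz + r_mean))
    truth = SyntheticTubeTruth(
        heights=h, bridge_radii=br, d_r=d_r, d_g=d_g, voxel=voxel,
        n_circ=n_circ, n_axial=n_axial,
        top_slices=slice(max(z_top - 2, 0), min(z_top + 1, nyz)),
        mid_slice=int(round(cz)),
    )
    gt = GroundTruth(
        kind="tube_stack",
        params=dict(n_circ=n_circ, n_axial=n_axial, d_g=d_g, d_r=d_r,
                    voxel=voxel, mean_height=float(h.mean()),
                    mean_bridge_radius=float(br.mean()),
                    noise_sd=noise_sd, psf_sigma=psf_sigma),
        seed=seed,
    )
    return stack, truth, gt
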