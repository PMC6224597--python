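"""Synthetic speckle movies for PIV validation.

The frame is split into two horizontal bands.  The top band holds
"structure" speckles that move only with the whole-gonad drift; the rest of
the frame holds cytoplasmic speckles advected by flow + drift.  Particles
wrap periodically within their own band, so each band keeps a constant
particle density.  Speckles are rendered as Gaussian spots (bilinear splat
followed by a Gaussian PSF blur) plus additive Gaussian noise.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from ..exceptions import ParameterError
from ..piv import FrameSequence
from .base import GroundTruth


def _splat(img, pos, amp):
    """Bilinear splat of unit impulses at float positions (y, x)."""
    ny, nx = img.shape
    y, x = pos[:, 0], pos[:, 1]
    y0 = np.floor(y).astype(int)
    x0 = np.floor(x).astype(int)
    fy, fx = y - y0, x - x0
    for dy, dx, w in (
        (0, 0, (1 - fy) * (1 - fx)),
        (0, 1, (1 - fy) * fx),
        (1, 0, fy * (1 - fx)),
        (1, 1, fy * fx),
    ):
        np.add.at(img, ((y0 + dy) % ny, (x0 + dx) % nx), amp * w)


def gen_speckle_movie(
    nx: int = 128,
    ny: int = 128,
    n_frames: int = 100,
    dt: float = 2.0,
    density: float = 0.02,
    flow: tuple = (4.71, 0.0),
    drift: tuple = (0.0, 0.0),
    px_size: float = 0.2,
    psf_sigma: float = 1.5,
    noise_sd: float = 0.02,
    seed: int | None = None,
    structure_rows: int | None = None,
):
    """Generate a speckle movie advected by ``flow`` + ``drift`` (µm/min).

    ``flow`` applies only inside the cytoplasmic band; the structure band
    (top ``structure_rows`` rows, default ny//4) moves with ``drift`` alone.
    Returns ``(FrameSequence, GroundTruth)``; the sequence carries its PIV
    ``roi`` and the ``structure_mask`` for drift estimation.
    """
    if density <= 0:
        raise ParameterError("density must be positive")
    if psf_sigma < 0 or noise_sd < 0:
        raise ParameterError("psf_sigma and noise_sd must be non-negative")
    h_s = structure_rows if structure_rows is not None else ny // 4
    if not 0 < h_s < ny:
        raise ParameterError("structure band must leave room for the flow band")

    warnings_list = []
    per_window = density * 32 * 32
    if per_window < 5:
        warnings_list.append(
            f"mean particles per 32x32 window = {per_window:.2f} < 5; "
            "PIV windows may be under-seeded"
        )

    rng = np.random.default_rng(seed)
    n_struct = max(int(round(density * nx * h_s)), 1)
    n_flow = max(int(round(density * nx * (ny - h_s))), 1)
    pos_s = np.column_stack([rng.uniform(0, h_s, n_struct), rng.uniform(0, nx, n_struct)])
    pos_f = np.column_stack(
        [rng.uniform(h_s, ny, n_flow), rng.uniform(0, nx, n_flow)]
    )

    def to_px(v):
        return np.asarray(v, dtype=float) / 60.0 * dt / px_size  # px/frame

    d_struct = to_px(drift)  # (vx, vy)
    d_flow = to_px(np.asarray(flow) + np.asarray(drift))
    amp = 2.0 * np.pi * max(psf_sigma, 0.5) ** 2  # unit peak after blur

    frames = np.empty((n_frames, ny, nx), dtype=float)
    for f in range(n_frames):
        img = np.zeros((ny, nx))
        _splat(img, pos_s, 1.0)
        _splat(img, pos_f, 1.0)
        if psf_sigma > 0:
            # periodic blur to match the periodic particle wrap
            img = gaussian_filter(img, psf_sigma, mode="wrap") * amp
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        frames[f] = img
        # advance: (y += vy, x += vx), wrapping within each band
        pos_s[:, 0] = (pos_s[:, 0] + d_struct[1]) % h_s
        pos_s[:, 1] = (pos_s[:, 1] + d_struct[0]) % nx
        pos_f[:, 0] = h_s + (pos_f[:, 0] - h_s + d_flow[1]) % (ny - h_s)
        pos_f[:, 1] = (pos_f[:, 1] + d_flow[0]) % nx

    # the mask handed to drift estimation keeps clear of the band boundary,
    # where the PSF smears flowing content into the structure band
    # (the periodic blur also wraps the flow band's far edge into row 0)
    guard = int(np.ceil(4 * psf_sigma)) + 2
    structure_mask = np.zeros((ny, nx), dtype=bool)
    lo, hi = guard, max(h_s - guard, guard + 4)
    structure_mask[lo:hi, :] = True
    margin = 16
    roi = (slice(h_s + margin, ny - margin), slice(margin, nx - margin))

    seq = FrameSequence(frames=frames, dt=dt, px_size=px_size, roi=roi,
                        structure_mask=structure_mask)
    truth = GroundTruth(
        kind="speckle_movie",
        params=dict(
            nx=nx, ny=ny, n_frames=n_frames, dt=dt, density=density,
            flow=list(flow), drift=list(drift), px_size=px_size,
            psf_sigma=psf_sigma, noise_sd=noise_sd,
            flow_px_per_frame=list(d_flow), drift_px_per_frame=list(d_struct),
            structure_rows=h_s,
        ),
        seed=seed,
        warnings=warnings_list,
    )
    return seq, truth
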