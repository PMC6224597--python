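"""Synthetic FRAP traces: the inverse of the analysis pipeline.

The generator produces the three ROI series (bleached, reference,
background) that the double-normalization step consumes.  A shared
multiplicative acquisition-bleaching factor ``exp(-acq_decay * t)`` is
applied to both the bleached and the reference signal above background —
exactly the perturbation double normalization is designed to cancel — so
that after normalization and full-scale calibration the noiseless curve is
identically ``P (1 - exp(-k t))`` with t measured from the bleach frame.
"""

from __future__ import annotations

import numpy as np

from ..exceptions import ParameterError
from ..frap import FrapRecord
from .base import GroundTruth


def gen_frap_series(
    P: float = 0.795,
    k: float = 0.018733,
    bleach_depth: float = 0.8,
    acq_decay: float = 0.0,
    background: float = 0.1,
    noise_sd: float = 0.0,
    n_pre: int = 5,
    n_post: int = 17,
    dt: float = 30.0,
    seed: int | None = None,
    f0: float = 1.0,
    r0: float = 1.0,
):
    """Generate one synthetic FRAP record.

    Parameters
    ----------
    P, k : mobile fraction and recovery rate (1/s) of the true recovery
        ``P (1 - exp(-k t))``.
    bleach_depth : fractional drop of the bleached-ROI signal at the bleach
        frame (1 = bleached to background).
    acq_decay : acquisition photobleaching rate (1/s) shared by the bleached
        and reference ROI.
    n_pre, n_post : number of pre-bleach frames and of frames from the bleach
        frame onward (the bleach frame counts as the first post frame).
    f0, r0 : pre-bleach signal amplitudes above background.

    Returns
    -------
    (FrapRecord, GroundTruth)
    """
    if not 0.0 <= P <= 1.0:
        raise ParameterError("mobile fraction P must lie in [0, 1]")
    if k <= 0 or dt <= 0:
        raise ParameterError("k and dt must be positive")
    if not 0.0 < bleach_depth <= 1.0:
        raise ParameterError("bleach_depth must lie in (0, 1]")
    if n_pre < 3:
        raise ParameterError("need at least 3 pre-bleach frames")

    n = n_pre + n_post
    t = np.arange(n) * dt
    g = np.exp(-acq_decay * t)

    # fractional bleached-ROI signal: 1 pre-bleach, recovery after the bleach
    u = np.ones(n)
    t_since = t[n_pre:] - t[n_pre]
    u[n_pre:] = (1.0 - bleach_depth) + bleach_depth * P * (1.0 - np.exp(-k * t_since))

    i_frap = background + f0 * g * u
    i_ref = background + r0 * g
    i_back = np.full(n, background)

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        i_frap = i_frap + rng.normal(0.0, noise_sd, n)
        i_ref = i_ref + rng.normal(0.0, noise_sd, n)
        i_back = i_back + rng.normal(0.0, noise_sd, n)

    rec = FrapRecord(t=t, i_frap=i_frap, i_ref=i_ref, i_back=i_back, n_pre=n_pre)
    truth = GroundTruth(
        kind="frap_series",
        params=dict(
            P=P, k=k, t_half=float(np.log(2.0) / k), bleach_depth=bleach_depth,
            acq_decay=acq_decay, background=background, noise_sd=noise_sd,
            n_pre=n_pre, n_post=n_post, dt=dt, f0=f0, r0=r0,
        ),
        seed=seed,
    )
    return rec, truth
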