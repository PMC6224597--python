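"""Synthetic ablation displacement traces.

Pre-cut, the edge-to-edge distance drifts linearly; post-cut it relaxes as

    L(t) = L_inf - A1 exp(-(t - t_cut)/tau1) - A2 exp(-(t - t_cut)/tau2),

with amplitudes ``A1 = frac1 * v0 * tau1`` and ``A2 = (1-frac1) * v0 * tau2``,
so that the derivative at the cut equals ``v0`` exactly, ``frac1`` is the
fraction of the initial recoil velocity carried by the fast mode, the trace
is continuous at ``t_cut`` and the plateau sits at
``L(t_cut) + v0*(frac1*tau1 + (1-frac1)*tau2)``.
"""

from __future__ import annotations

import numpy as np

from ..ablation import DisplacementTrace
from ..exceptions import ParameterError
from .base import GroundTruth


def gen_recoil_trace(
    v0: float = 1.12,
    tau1: float = 1.0,
    tau2: float = 8.0,
    frac1: float = 0.7,
    pre_slope: float = 0.0,
    t_cut: float = 5.0,
    noise_sd: float = 0.0,
    dt: float = 0.25,
    duration: float = 60.0,
    seed: int | None = None,
    l0: float = 10.0,
    condition: str = "",
):
    """Generate one synthetic displacement trace around a laser cut.

    ``v0`` is the true initial recoil velocity (µm/s); ``tau1 <= tau2`` are
    the fast and slow relaxation times (s).
    """
    if tau1 <= 0 or tau2 <= 0:
        raise ParameterError("relaxation times must be positive")
    if tau1 > tau2:
        raise ParameterError("tau1 must not exceed tau2")
    if v0 < 0:
        raise ParameterError("v0 must be non-negative")
    if not 0.0 <= frac1 <= 1.0:
        raise ParameterError("frac1 must lie in [0, 1]")
    if not 0.0 < t_cut < duration:
        raise ParameterError("t_cut must lie inside (0, duration)")
    if dt <= 0:
        raise ParameterError("dt must be positive")

    t = np.arange(0.0, duration + 0.5 * dt, dt)
    l_cut = l0 + pre_slope * t_cut
    a1 = frac1 * v0 * tau1
    a2 = (1.0 - frac1) * v0 * tau2
    linf = l_cut + a1 + a2
    L = np.where(
        t <= t_cut,
        l0 + pre_slope * t,
        linf - a1 * np.exp(-(t - t_cut) / tau1) - a2 * np.exp(-(t - t_cut) / tau2),
    )
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        L = L + rng.normal(0.0, noise_sd, t.size)
    trace = DisplacementTrace(t=t, L=L, t_cut=t_cut, condition=condition)
    truth = GroundTruth(
        kind="recoil_trace",
        params=dict(v0=v0, tau1=tau1, tau2=tau2, frac1=frac1, A1=a1, A2=a2,
                    Linf=linf, pre_slope=pre_slope, t_cut=t_cut,
                    noise_sd=noise_sd, dt=dt, duration=duration, l0=l0,
                    total_rise=a1 + a2),
        seed=seed,
    )
    return trace, truth
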