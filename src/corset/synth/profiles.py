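"""Jointly Gaussian intensity-profile pairs with a set population correlation."""

from __future__ import annotations

import numpy as np

from ..exceptions import ParameterError
from .base import GroundTruth


def gen_correlated_profiles(
    rho: float = 0.59,
    n: int = 10_000,
    seed: int | None = None,
    mean: float = 100.0,
    sd: float = 10.0,
):
    """Two intensity profiles with population Pearson correlation ``rho``.

    Built from independent standard normals z1, z2 as
    ``x2 = rho*z1 + sqrt(1-rho²)*z2`` and affinely shifted to positive
    intensities (``mean`` ± a few ``sd``).  For ``rho = ±1`` the profiles are
    exact affine images of each other, so the sample Pearson is ±1 exactly.
    """
    if not -1.0 <= rho <= 1.0:
        raise ParameterError("rho must lie in [-1, 1]")
    if n < 10:
        raise ParameterError("need at least 10 samples")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    x1 = mean + sd * z1
    x2 = mean + sd * (rho * z1 + np.sqrt(max(1.0 - rho**2, 0.0)) * z2)
    truth = GroundTruth(
        kind="correlated_profiles",
        params=dict(rho=rho, n=n, mean=mean, sd=sd),
        seed=seed,
    )
    return x1, x2, truth
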