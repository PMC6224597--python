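"""FRAP recovery analysis: double normalization, full-scale calibration and
single-exponential fitting.

The bleached-ROI intensity is first corrected for background and acquisition
photobleaching with the double-normalization formula

    I_norm(t) = I_ref_pre / (I_ref(t) - I_back(t))
                * (I_frap(t) - I_back(t)) / I_frap_pre,

where the ``_pre`` quantities are pre-bleach averages of the
background-subtracted signals.  Full-scale calibration then maps the bleach
frame to 0 and the pre-bleach level to 1,

    I_norm_sc(t) = (I_norm(t) - I_norm(t_bleach)) / (I_norm_pre - I_norm(t_bleach)),

and the rescaled post-bleach curve is fitted with

    I(t) = P * (1 - exp(-k t)),

with mobile fraction ``P``, rate constant ``k`` (1/s), half-life
``t_half = ln 2 / k`` and immobile fraction ``1 - P``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import DataError, FitError

__all__ = [
    "FrapRecord",
    "FrapFit",
    "normalize_frap",
    "fit_recovery",
    "FrapRecoveryModel",
]


@dataclass
class FrapRecord:
    """Raw ROI-averaged intensity traces of one FRAP experiment.

    ``n_pre`` frames precede the bleach; frame index ``n_pre`` is the bleach
    frame (first frame acquired after photobleaching).
    """

    t: np.ndarray  # s
    i_frap: np.ndarray  # bleached-ROI mean intensity
    i_ref: np.ndarray  # reference-ROI mean intensity
    i_back: np.ndarray  # background-ROI mean intensity
    n_pre: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.i_frap = np.asarray(self.i_frap, dtype=float)
        self.i_ref = np.asarray(self.i_ref, dtype=float)
        self.i_back = np.asarray(self.i_back, dtype=float)
        n = self.t.size
        if not (self.i_frap.size == self.i_ref.size == self.i_back.size == n):
            raise DataError("all FRAP series must have the same length")
        if not 0 < self.n_pre < n:
            raise DataError("n_pre must leave at least one post-bleach frame")

    @property
    def t_bleach(self) -> float:
        """Time of the bleach frame (first post-bleach acquisition)."""
        return float(self.t[self.n_pre])

    @classmethod
    def from_csv(cls, path, n_pre: int) -> "FrapRecord":
        df = pd.read_csv(path)
        return cls(
            t=df["t"].to_numpy(),
            i_frap=df["I_frap"].to_numpy(),
            i_ref=df["I_ref"].to_numpy(),
            i_back=df["I_back"].to_numpy(),
            n_pre=n_pre,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"t": self.t, "I_frap": self.i_frap, "I_ref": self.i_ref, "I_back": self.i_back}
        ).to_csv(path, index=False)


@dataclass
class FrapFit:
    """Fitted single-exponential recovery parameters."""

    P: float  # mobile fraction
    k: float  # rate constant, 1/s
    t_half: float  # s, = ln 2 / k (derived, not refit)
    immobile: float  # = 1 - P
    rms: float  # residual RMS of the fit
    t_post: np.ndarray = field(repr=False)
    curve: np.ndarray = field(repr=False)  # fitted values at t_post
    flags: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "FRAP single-exponential recovery fit",
            f"  mobile fraction P     {self.P:10.4f}",
            f"  rate constant k       {self.k:10.5f} 1/s",
            f"  half-life t_1/2       {self.t_half:10.2f} s",
            f"  immobile fraction     {self.immobile:10.4f}",
            f"  residual RMS          {self.rms:10.5f}",
        ]
        if self.flags:
            lines.append("  flags: " + ", ".join(self.flags))
        return "\n".join(lines)


def normalize_frap(rec: FrapRecord):
    """Double-normalize and full-scale-rescale a FRAP record.

    Returns ``(i_norm, i_norm_sc)``; ``i_norm_sc`` is 0 at the bleach frame
    and 1 at the pre-bleach mean.
    """
    ref_bs = rec.i_ref - rec.i_back
    bad = np.nonzero(ref_bs <= 0)[0]
    if bad.size:
        raise DataError(
            f"reference minus background is non-positive at frame {bad[0]}"
        )
    pre = slice(0, rec.n_pre)
    i_ref_pre = float(np.mean(ref_bs[pre]))
    i_frap_pre = float(np.mean((rec.i_frap - rec.i_back)[pre]))
    if i_frap_pre <= 0:
        raise DataError("pre-bleach bleached-ROI signal is non-positive")

    i_norm = (i_ref_pre / ref_bs) * ((rec.i_frap - rec.i_back) / i_frap_pre)

    i_norm_pre = float(np.mean(i_norm[pre]))
    i_norm_bleach = float(i_norm[rec.n_pre])
    depth = i_norm_pre - i_norm_bleach
    if depth <= 1e-6 * max(abs(i_norm_pre), 1.0):
        raise DataError("no bleach detected: bleach-frame level equals pre-bleach level")
    i_norm_sc = (i_norm - i_norm_bleach) / depth
    return i_norm, i_norm_sc


def _recovery(t, P, k):
    return P * (1.0 - np.exp(-k * t))


def fit_recovery(t_post: np.ndarray, i_norm_sc: np.ndarray) -> FrapFit:
    """Fit ``P (1 - exp(-k t))`` to the post-bleach rescaled curve.

    ``t_post`` is measured from the bleach frame, so the first fitted sample
    sits at ``t = dt``.  Unweighted least squares; ``P`` is bounded by 1.2 so
    noisy full recoveries are not clipped (fits above 1 are flagged).
    """
    t_post = np.asarray(t_post, dtype=float)
    y = np.asarray(i_norm_sc, dtype=float)
    if t_post.size < 5:
        raise DataError("need at least 5 post-bleach frames to fit")
    n_tail = max(1, t_post.size // 4)
    p0 = float(np.mean(y[-n_tail:]))
    if p0 <= 0.02:
        raise FitError("no recovery detected: post-bleach curve has no plateau")
    # time at which the curve first reaches half its plateau -> k initializer
    above = np.nonzero(y >= 0.5 * p0)[0]
    t_half0 = t_post[above[0]] if above.size else t_post[-1]
    k0 = np.log(2.0) / max(t_half0, t_post[0])
    try:
        popt, _ = curve_fit(
            _recovery,
            t_post,
            y,
            p0=[min(p0, 1.2), k0],
            bounds=([1e-9, 1e-9], [1.2, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy non-convergence
        raise FitError(f"recovery fit did not converge: {exc}") from exc
    P, k = float(popt[0]), float(popt[1])
    curve = _recovery(t_post, P, k)
    rms = float(np.sqrt(np.mean((y - curve) ** 2)))
    flags = ["mobile fraction > 1"] if P > 1.0 else []
    return FrapFit(
        P=P,
        k=k,
        t_half=float(np.log(2.0) / k),
        immobile=1.0 - P,
        rms=rms,
        t_post=t_post,
        curve=curve,
        flags=flags,
    )


class FrapRecoveryModel:
    """Single-exponential FRAP recovery model bound to one record.

    Examples
    --------
    >>> fit = FrapRecoveryModel(record).fit()
    >>> print(fit.summary())
    """

    def __init__(self, record: FrapRecord):
        self.record = record
        self.i_norm, self.i_norm_sc = normalize_frap(record)

    def fit(self) -> FrapFit:
        rec = self.record
        post = slice(rec.n_pre + 1, None)
        t_post = rec.t[post] - rec.t_bleach
        return fit_recovery(t_post, self.i_norm_sc[post])
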