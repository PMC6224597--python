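"""Laser-ablation response analysis.

Three measurements quantify the mechanical response of the actomyosin corset
to a laser cut:

* **Recoil fitting** — the distance between two membrane edges is fitted with
  a linear model before the cut and a (single or double) exponential
  relaxation after it.  The effective cut time ``t0`` is the intersection of
  the two fitted curves, and the initial recoil velocity is the analytic
  derivative of the exponential model at ``t0`` — a proxy for the tension the
  structure was under before the cut.
* **Total displacement** — opening of the cut after a fixed horizon
  (50 s by default) relative to the pre-cut distance.
* **Bridge circularity tracking** — rachis-bridge openings are segmented by
  Niblack local thresholding, tracked across frames by maximum pixel overlap
  and scored by circularity ``4π·area/perimeter²``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_fill_holes, binary_opening, gaussian_filter
from scipy.optimize import brentq, curve_fit
from skimage.filters import threshold_niblack
from skimage.measure import find_contours, label as sk_label, regionprops

from .exceptions import DataError, FitError

__all__ = [
    "DisplacementTrace",
    "RecoilFit",
    "RecoilModel",
    "fit_recoil",
    "total_displacement",
    "segment_bridges",
    "track_circularity",
    "mask_circularity",
]


@dataclass
class DisplacementTrace:
    """Edge-to-edge distance time series around an ablation."""

    t: np.ndarray  # s
    L: np.ndarray  # µm
    t_cut: float  # nominal ablation time, s
    condition: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise DataError("time must be strictly increasing")
        if not self.t[0] < self.t_cut < self.t[-1]:
            raise DataError("t_cut must fall inside the trace")
        if np.count_nonzero(self.t <= self.t_cut) < 5:
            raise DataError("need at least 5 pre-cut samples")

    @classmethod
    def from_csv(cls, path, t_cut: float, condition: str = "") -> "DisplacementTrace":
        df = pd.read_csv(path)
        return cls(t=df["t"].to_numpy(), L=df["L"].to_numpy(), t_cut=t_cut,
                   condition=condition)

    def to_csv(self, path) -> None:
        pd.DataFrame({"t": self.t, "L": self.L}).to_csv(path, index=False)


@dataclass
class RecoilFit:
    """Fitted pre/post models and derived recoil quantities."""

    intercept: float
    slope: float
    model: str  # "single" | "double"
    params: dict  # Linf, A1, tau1 [, A2, tau2]; anchored at t_cut
    t_anchor: float
    t0: float  # effective cut time, s
    v_recoil: float  # µm/s, derivative of the post model at t0
    selection: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def post_value(self, t):
        return _exp_model(np.asarray(t, dtype=float), self.t_anchor, self.params)

    def post_velocity(self, t):
        return _exp_velocity(np.asarray(t, dtype=float), self.t_anchor, self.params)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Laser-ablation recoil fit",
            f"  pre-cut linear        L = {self.intercept:.4f} + {self.slope:.5f} t",
            f"  post-cut model        {self.model} exponential",
            f"    plateau L_inf       {p['Linf']:10.4f} µm",
            f"    A1, tau1            {p['A1']:10.4f} µm, {p['tau1']:.3f} s",
        ]
        if self.model == "double":
            lines.append(f"    A2, tau2            {p['A2']:10.4f} µm, {p['tau2']:.3f} s")
        lines += [
            f"  effective cut time t0 {self.t0:10.3f} s",
            f"  initial recoil v      {self.v_recoil:10.4f} µm/s",
        ]
        if self.flags:
            lines.append("  flags: " + ", ".join(self.flags))
        return "\n".join(lines)


def _exp_model(t, ta, p):
    y = p["Linf"] - p["A1"] * np.exp(-(t - ta) / p["tau1"])
    if "A2" in p:
        y = y - p["A2"] * np.exp(-(t - ta) / p["tau2"])
    return y


def _exp_velocity(t, ta, p):
    v = p["A1"] / p["tau1"] * np.exp(-(t - ta) / p["tau1"])
    if "A2" in p:
        v = v + p["A2"] / p["tau2"] * np.exp(-(t - ta) / p["tau2"])
    return v


def _peel_init(t, y, ta):
    """Exponential-peeling initializer for the double model.

    Fits the slow mode on the tail of log(L_inf - L), subtracts it, and fits
    the fast mode on the early residual.
    """
    linf0 = float(y[-1]) + max(float(y[-1] - y[-2]), 0.0)
    r = np.clip(linf0 - y, 1e-9, None)
    n = t.size
    tail = slice(max(n // 3, 2), None)
    s2, i2 = np.polyfit(t[tail] - ta, np.log(r[tail]), 1)
    tau2 = -1.0 / s2 if s2 < 0 else (t[-1] - t[0])
    a2 = float(np.exp(i2))
    fast = np.clip(r - a2 * np.exp(-(t - ta) / tau2), 1e-9, None)
    head = slice(0, max(n // 4, 3))
    s1, i1 = np.polyfit(t[head] - ta, np.log(fast[head]), 1)
    tau1 = -1.0 / s1 if s1 < 0 else tau2 / 5.0
    a1 = float(np.exp(i1))
    return linf0, a1, tau1, a2, tau2


def _fit_post(t, y, ta, double: bool):
    """Least-squares exponential fit anchored at ta; returns (params, rel_se)."""
    linf0 = float(y[-1])
    a0 = max(linf0 - float(y[0]), 1e-6)
    span = max(t[-1] - t[0], 1.0)
    if double:
        fun = lambda t, linf, a1, tau1, a2, tau2: (
            linf - a1 * np.exp(-(t - ta) / tau1) - a2 * np.exp(-(t - ta) / tau2)
        )
        try:
            l0, a1_0, tau1_0, a2_0, tau2_0 = _peel_init(t, y, ta)
        except Exception:
            l0, a1_0, tau1_0, a2_0, tau2_0 = (
                linf0, 0.5 * a0, min(1.0, span / 10), 0.5 * a0, span / 3)
        clip = lambda v, lo, hi: float(min(max(v, lo), hi))
        p0 = [l0, clip(a1_0, 1e-6, 10 * abs(a0) + 1), clip(tau1_0, 2e-3, 9 * span),
              clip(a2_0, 1e-6, 10 * abs(a0) + 1), clip(tau2_0, 2e-3, 9 * span)]
        lb = [-np.inf, 0.0, 1e-3, 0.0, 1e-3]
        ub = [np.inf, np.inf, 10 * span, np.inf, 10 * span]
    else:
        fun = lambda t, linf, a1, tau1: linf - a1 * np.exp(-(t - ta) / tau1)
        p0 = [linf0, a0, span / 5]
        lb = [-np.inf, 0.0, 1e-3]
        ub = [np.inf, np.inf, 10 * span]
    popt, pcov = curve_fit(fun, t, y, p0=p0, bounds=(lb, ub), maxfev=20000)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
        rel_se = np.abs(se / np.where(popt == 0, np.nan, popt))
    if double:
        linf, a1, tau1, a2, tau2 = popt
        if tau1 > tau2:  # order the modes fast-first
            a1, a2, tau1, tau2 = a2, a1, tau2, tau1
        params = dict(Linf=float(linf), A1=float(a1), tau1=float(tau1),
                      A2=float(a2), tau2=float(tau2))
    else:
        params = dict(Linf=float(popt[0]), A1=float(popt[1]), tau1=float(popt[2]))
    return params, rel_se


def fit_recoil(trace: DisplacementTrace, model: str = "auto") -> RecoilFit:
    """Fit the pre-cut linear / post-cut exponential recoil model.

    ``model`` is ``"single"``, ``"double"`` or ``"auto"``.  A weak recoil
    gives the double model too much freedom and it can grossly overestimate
    the velocity at the cut; the automatic rule therefore rejects the double
    model in favour of the single one when its velocity at the cut exceeds
    1.5x the largest finite-difference velocity over the first 3 s post-cut,
    or when any of its parameters has a relative standard error above 1.
    """
    if model not in ("single", "double", "auto"):
        raise ValueError("model must be 'single', 'double' or 'auto'")
    pre = trace.t <= trace.t_cut
    post = ~pre
    if np.count_nonzero(post) < 10:
        raise DataError("need at least 10 post-cut samples")
    tp, yp = trace.t[pre], trace.L[pre]
    slope, intercept = np.polyfit(tp, yp, 1)
    ta = trace.t_cut
    t_post, y_post = trace.t[post], trace.L[post]

    flags: list = []
    selection: dict = {}

    def _one(double):
        try:
            return _fit_post(t_post, y_post, ta, double)
        except RuntimeError as exc:
            raise FitError(f"post-cut fit did not converge: {exc}") from exc

    if model == "single":
        params, _ = _one(False)
        chosen = "single"
    elif model == "double":
        params, _ = _one(True)
        chosen = "double"
    else:
        params_d, rel_se_d = _one(True)
        v_d = float(_exp_velocity(ta, ta, params_d))
        early = t_post <= t_post[0] + 3.0
        te, ye = t_post[early], y_post[early]
        if te.size >= 2:
            v_fd_max = float(np.max(np.abs(np.diff(ye) / np.diff(te))))
        else:
            v_fd_max = np.inf
        bad_se = bool(np.any(~np.isfinite(rel_se_d)) or np.any(rel_se_d > 1.0))
        overestimates = v_d > 1.5 * v_fd_max
        selection = dict(v_double=v_d, v_fd_max=v_fd_max,
                         overestimates=overestimates, uncertain=bad_se)
        if overestimates or bad_se:
            params, _ = _one(False)
            chosen = "single"
        else:
            params, chosen = params_d, "double"

    # effective cut time: intersection of the linear and exponential curves
    def gap(t):
        return (intercept + slope * t) - _exp_model(t, ta, params)

    a = float(tp[-1])
    b = float(t_post[0])
    ga, gb = gap(a), gap(b)
    tol = 1e-9 * max(1.0, float(np.abs(trace.L).max()))
    t0 = None
    if abs(ga) < tol:
        t0 = a
    elif abs(gb) < tol:
        t0 = b
    elif ga * gb < 0:
        t0 = float(brentq(gap, a, b))
    else:
        # noise can push the crossing slightly before the last pre-cut
        # sample; widen the bracket backward by one frame gap before giving up
        a2 = a - (b - a)
        if gap(a2) * gb < 0:
            t0 = float(brentq(gap, a2, b))
            flags.append("intersection before last pre-cut sample")
    if t0 is None:
        t0 = 0.5 * (a + b)
        flags.append("no intersection")

    v_recoil = float(_exp_velocity(t0, ta, params))
    return RecoilFit(
        intercept=float(intercept), slope=float(slope), model=chosen,
        params=params, t_anchor=ta, t0=t0, v_recoil=v_recoil,
        selection=selection, flags=flags,
    )


class RecoilModel:
    """Model-object interface around :func:`fit_recoil`."""

    def __init__(self, trace: DisplacementTrace, model: str = "auto"):
        self.trace = trace
        self.model = model

    def fit(self) -> RecoilFit:
        return fit_recoil(self.trace, model=self.model)


def total_displacement(trace: DisplacementTrace, horizon: float = 50.0) -> float:
    """Opening ``L(t_cut + horizon) - mean pre-cut L`` in µm (sign preserved)."""
    t_end = trace.t_cut + horizon
    if trace.t[-1] < t_end:
        raise DataError(
            f"trace ends at {trace.t[-1]:.1f} s, before the requested "
            f"horizon t_cut + {horizon:.0f} s = {t_end:.1f} s"
        )
    l_end = float(np.interp(t_end, trace.t, trace.L))
    l_pre = float(np.mean(trace.L[trace.t <= trace.t_cut]))
    return l_end - l_pre


# ---------------------------------------------------------------------------
# bridge segmentation and circularity tracking
# ---------------------------------------------------------------------------


@dataclass
class SegmentationResult:
    labels: list  # per-frame integer label arrays
    n_empty: int
    warnings: list = field(default_factory=list)


def niblack_mask(image: np.ndarray, radius: int, k: float) -> np.ndarray:
    """Bright-pixel mask with threshold = local mean + k * local std."""
    window = 2 * int(radius) + 1
    # skimage's convention is mean - k*std, so the sign of k is flipped here
    thr = threshold_niblack(image.astype(float), window_size=window, k=-k)
    return image > thr


def segment_bridges(
    frames,
    niblack_radius: int = 35,
    niblack_k: float = 0.2,
    min_area: int = 50,
    opening: int = 0,
) -> SegmentationResult:
    """Label rachis-bridge openings (interiors of bright rings) per frame."""
    if niblack_radius < 3:
        raise ValueError("niblack_radius must be at least 3 px")
    labels = []
    n_empty = 0
    for img in frames:
        img = np.asarray(img, dtype=float)
        if np.ptp(img) == 0:
            labels.append(np.zeros(img.shape, dtype=int))
            n_empty += 1
            continue
        bright = niblack_mask(img, niblack_radius, niblack_k)
        interior = binary_fill_holes(bright) & ~bright
        if opening > 0:
            interior = binary_opening(interior, iterations=int(opening))
        lab = sk_label(interior)
        if min_area > 0:
            counts = np.bincount(lab.ravel())
            small = np.nonzero(counts < min_area)[0]
            lab[np.isin(lab, small)] = 0
            lab = sk_label(lab > 0)
        labels.append(lab)
        if lab.max() == 0:
            n_empty += 1
    msgs = []
    if n_empty > len(labels) / 2:
        msgs.append(f"empty segmentation on {n_empty}/{len(labels)} frames")
        warnings.warn(msgs[-1])
    return SegmentationResult(labels=labels, n_empty=n_empty, warnings=msgs)


def _contour_perimeter(mask: np.ndarray) -> float:
    """Perimeter of the largest marching-squares contour of a binary mask.

    The mask is lightly smoothed before contouring (smooth-contour
    convention): the raw binary iso-contour is a staircase that overestimates
    the length of a smooth boundary by several percent.
    """
    padded = np.pad(mask.astype(float), 3)
    padded = gaussian_filter(padded, 1.0)
    contours = find_contours(padded, 0.5)
    if not contours:
        return 0.0
    lengths = [np.sum(np.hypot(*np.diff(c, axis=0).T)) for c in contours]
    return float(max(lengths))


def mask_circularity(mask: np.ndarray) -> float:
    """Circularity 4π·area/perimeter² of a binary mask, clipped to 1."""
    area = float(np.count_nonzero(mask))
    per = _contour_perimeter(mask)
    if per == 0:
        return 0.0
    return float(min(4.0 * np.pi * area / per**2, 1.0))


@dataclass
class BridgeTrack:
    """Per-bridge identities and circularity series across frames."""

    table: pd.DataFrame  # columns: track, frame, label, area, perimeter, circularity, y, x
    terminated: list = field(default_factory=list)

    def circularity_series(self, track: int) -> pd.DataFrame:
        return self.table[self.table["track"] == track][["frame", "circularity"]]

    @property
    def n_tracks(self) -> int:
        return int(self.table["track"].nunique())


def track_circularity(labels) -> BridgeTrack:
    """Track labeled bridge openings by maximum pixel overlap.

    Ties are broken by intersection-over-union, then by centroid distance.
    A track terminates when no current object overlaps it.
    """
    if len(labels) < 2:
        raise DataError("need at least 2 frames to track")
    rows = []
    terminated = []
    next_track = 0
    prev_lab = None
    prev_tracks: dict = {}  # previous-frame label -> track id
    for f, lab in enumerate(labels):
        props = {p.label: p for p in regionprops(lab)}
        assign: dict = {}
        if prev_lab is not None and not props:
            terminated.extend((tr, f) for tr in prev_tracks.values())
        if prev_lab is not None and props:
            # joint histogram of previous vs current labels
            both = (prev_lab > 0) & (lab > 0)
            cand = []  # (overlap, iou, -dist, prev_label, cur_label)
            if np.any(both):
                pairs, counts = np.unique(
                    np.stack([prev_lab[both], lab[both]]), axis=1, return_counts=True
                ), None
                pl, cl = pairs[0]
                counts = np.unique(
                    np.stack([prev_lab[both], lab[both]]), axis=1, return_counts=True
                )[1]
                prev_areas = np.bincount(prev_lab.ravel())
                cur_areas = np.bincount(lab.ravel())
                prev_props = {p.label: p for p in regionprops(prev_lab)}
                for pv, cv, ov in zip(pl, cl, counts):
                    union = prev_areas[pv] + cur_areas[cv] - ov
                    d = np.hypot(
                        *(np.asarray(prev_props[pv].centroid) - np.asarray(props[cv].centroid))
                    )
                    cand.append((int(ov), ov / union, -float(d), int(pv), int(cv)))
                cand.sort(reverse=True)
                used_prev, used_cur = set(), set()
                for ov, iou, negd, pv, cv in cand:
                    if pv in used_prev or cv in used_cur or pv not in prev_tracks:
                        continue
                    assign[cv] = prev_tracks[pv]
                    used_prev.add(pv)
                    used_cur.add(cv)
            for pv, tr in prev_tracks.items():
                if tr not in assign.values():
                    terminated.append((tr, f))
        cur_tracks = {}
        for lbl, p in props.items():
            if lbl in assign:
                tr = assign[lbl]
            else:
                tr = next_track
                next_track += 1
            cur_tracks[lbl] = tr
            mask = lab == lbl
            per = _contour_perimeter(mask)
            circ = min(4.0 * np.pi * p.area / per**2, 1.0) if per > 0 else 0.0
            rows.append(
                dict(track=tr, frame=f, label=lbl, area=float(p.area),
                     perimeter=per, circularity=circ,
                     y=float(p.centroid[0]), x=float(p.centroid[1]))
            )
        prev_lab = lab
        prev_tracks = cur_tracks
    return BridgeTrack(table=pd.DataFrame(rows), terminated=terminated)
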