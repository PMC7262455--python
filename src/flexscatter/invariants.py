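"""Model-free SAXS invariants: Guinier analysis, dimensionless Kratky
transformation and per-frame Rg evolution across a SEC-SAXS elution.

The Guinier approximation ln I(q) = ln I(0) - (q Rg)^2 / 3 holds at low
q Rg; fitting ln I against q^2 over a window with upper q Rg <= 1.3 gives
the gradient m from which Rg = sqrt(-3 m).  For globular particles the
dimensionless Kratky curve (q Rg)^2 I(q)/I(0) peaks at (sqrt(3), 3/e);
flexible chains plateau or rise instead, which is the diagnostic used to
classify partially disordered proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    ArgumentError,
    InsufficientDataError,
    NoGuinierRegionError,
)
from .saxs_io import FrameSeries, ScatteringCurve

__all__ = [
    "GuinierFit",
    "KratkyCurve",
    "RgTrace",
    "KRATKY_GLOBULAR_POINT",
    "guinier_fit",
    "auto_guinier_range",
    "auto_guinier",
    "dimensionless_kratky",
    "rg_evolution",
]

#: Peak position of the dimensionless Kratky curve for an ideal globular
#: (Guinier) scatterer: x = sqrt(3), y = 3/e ~ 1.10.
KRATKY_GLOBULAR_POINT = (math.sqrt(3.0), 3.0 / math.e)


@dataclass(frozen=True)
class GuinierFit:
    """Result of a Guinier fit of ln I versus q^2.

    ``slope_m`` is the fitted gradient (A^2, negative); ``Rg = sqrt(-3 m)``
    holds exactly.  ``Rg_err`` is the SEM of the slope propagated through
    that identity.  ``window`` is the achieved (q Rg) range of the fitted
    points; ``residuals`` are standardized fit residuals in ln I space.
    """

    Rg: float
    Rg_err: float
    I0: float
    slope_m: float
    intercept: float
    window: tuple
    q_window: tuple
    n_points: int
    r_squared: float
    residuals: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class KratkyCurve:
    """Dimensionless Kratky curve: x = q Rg, y = (q Rg)^2 I(q) / I(0)."""

    x: np.ndarray
    y: np.ndarray
    reference: tuple = KRATKY_GLOBULAR_POINT

    @property
    def peak(self) -> tuple:
        i = int(np.argmax(self.y))
        return float(self.x[i]), float(self.y[i])


def _wls_line(x, y, w):
    """Weighted least squares y = a + b x; returns a, b, SE_b, R^2, resid."""
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    sxy = np.sum(w * (x - xm) * (y - ym))
    b = sxy / sxx
    a = ym - b * xm
    resid = y - (a + b * x)
    n = len(x)
    s2 = np.sum(w * resid**2) / max(n - 2, 1)
    se_b = math.sqrt(s2 / sxx)
    sst = np.sum(w * (y - ym) ** 2)
    r2 = 1.0 - np.sum(w * resid**2) / sst if sst > 0 else 1.0
    return a, b, se_b, r2, resid


def _fit_indices(curve, idx):
    """Guinier WLS on the given point indices; raises on bad slope/count."""
    q, I = curve.q[idx], curve.I[idx]
    if len(q) < 5:
        raise InsufficientDataError(
            f"Guinier window has {len(q)} points; >= 5 required")
    if np.any(I <= 0):
        raise NoGuinierRegionError("non-positive intensity in Guinier window")
    x = q**2
    y = np.log(I)
    if curve.has_sigma:
        s_ln = curve.sigma[idx] / I
        w = 1.0 / s_ln**2
    else:
        s_ln = None
        w = np.ones_like(x)
    a, m, se_m, r2, resid = _wls_line(x, y, w)
    if m >= 0:
        raise NoGuinierRegionError(
            "non-negative Guinier slope: no decaying low-q region")
    rg = math.sqrt(-3.0 * m)
    rg_err = 3.0 * se_m / (2.0 * rg)
    if s_ln is not None:
        std_resid = resid / s_ln
    else:
        rms = np.sqrt(np.mean(resid**2)) or 1.0
        std_resid = resid / rms
    return GuinierFit(
        Rg=rg, Rg_err=rg_err, I0=math.exp(a), slope_m=m, intercept=a,
        window=(float(q[0] * rg), float(q[-1] * rg)),
        q_window=(float(q[0]), float(q[-1])),
        n_points=len(q), r_squared=float(r2), residuals=std_resid,
    )


def _initial_indices(curve, start=0):
    """Robust bootstrap point set: from ``start`` to the first crossing of
    half the starting intensity (noise-tolerant; >= 5 points)."""
    n = len(curve)
    I = curve.I
    ref = float(np.median(I[start:min(start + 5, n)]))
    below = np.nonzero(I[start:] < 0.5 * ref)[0]
    end = start + (int(below[0]) if len(below) else n - start)
    return np.arange(start, min(max(end, start + 5), n))


def guinier_fit(curve: ScatteringCurve,
                window: tuple = (0.0, 1.3),
                max_iter: int = 20) -> GuinierFit:
    """Guinier fit over a (q Rg) window, iterated to self-consistency.

    The window is expressed in the dimensionless variable q Rg, so point
    selection depends on the fitted Rg itself; the fit is repeated
    (<= ``max_iter`` times) until the selected point set stabilizes.
    Weights are 1/sigma_lnI^2 with sigma_lnI = sigma/I when uncertainties
    are present, unit weights otherwise.
    """
    lo, hi = window
    if lo >= hi or hi <= 0:
        raise ArgumentError(f"invalid qRg window {window}")
    idx = _initial_indices(curve)
    prev = None
    fit = None
    for _ in range(max_iter):
        fit = _fit_indices(curve, idx)
        qrg = curve.q * fit.Rg
        sel = np.nonzero((qrg >= lo) & (qrg <= hi))[0]
        if len(sel) < 5:
            raise InsufficientDataError(
                f"qRg window {window} selects {len(sel)} points (< 5)")
        if prev is not None and np.array_equal(sel, prev):
            break
        prev, idx = sel, sel
    return fit


def auto_guinier_range(curve: ScatteringCurve,
                       qrg_max: float = 1.3,
                       r2_min: float = 0.95,
                       stability: float = 0.05,
                       max_start: int | None = None) -> tuple:
    """Find the widest self-consistent Guinier window.

    Scans candidate starting points from the lowest q upward.  For each
    start the upper end is set self-consistently at q Rg <= ``qrg_max``
    (<= 20 fit/window iterations); a candidate is accepted if the fit has
    R^2 >= ``r2_min``, negative slope, and a stable Rg (relative change
    below ``stability`` when either endpoint is dropped).  Among accepted
    windows the one with the most points wins, ties going to the lower
    starting q.  This removes low-q aggregation upturns automatically.

    Returns the achieved (qRg_low, qRg_high) window.
    """
    return _auto_search(curve, qrg_max, r2_min, stability, max_start)[0]


def _auto_search(curve, qrg_max, r2_min, stability, max_start=None):
    n = len(curve)
    if max_start is None:
        max_start = max(n - 5, 1)
    best = None  # (key, window, fit)
    for start in range(max_start):
        try:
            fit = _auto_fit_from(curve, start, qrg_max)
        except (InsufficientDataError, NoGuinierRegionError):
            continue
        if fit.r_squared < r2_min:
            continue
        if not _endpoints_stable(curve, start, fit, qrg_max, stability):
            continue
        key = (fit.n_points, -start)
        if best is None or key > best[0]:
            best = (key, fit.window, fit)
    if best is None:
        raise NoGuinierRegionError(
            "no window satisfies the Guinier criteria "
            f"(R^2 >= {r2_min}, qRg <= {qrg_max}, stable Rg)")
    return best[1], best[2]


def _auto_fit_from(curve, start, qrg_max, max_iter=20):
    n = len(curve)
    idx = _initial_indices(curve, start)
    fit = None
    for _ in range(max_iter):
        fit = _fit_indices(curve, idx)
        qrg = curve.q * fit.Rg
        stop = int(np.searchsorted(qrg, qrg_max, side="right"))
        new = np.arange(start, max(stop, start + 5))
        new = new[new < n]
        if np.array_equal(new, idx):
            break
        idx = new
    return fit


def _endpoints_stable(curve, start, fit, qrg_max, stability):
    q0, q1 = fit.q_window
    idx = np.nonzero((curve.q >= q0) & (curve.q <= q1))[0]
    if len(idx) < 6:
        return False
    for sub in (idx[1:], idx[:-1]):
        try:
            alt = _fit_indices(curve, sub)
        except (InsufficientDataError, NoGuinierRegionError):
            return False
        if abs(alt.Rg - fit.Rg) / fit.Rg >= stability:
            return False
    return True


def auto_guinier(curve: ScatteringCurve, qrg_max: float = 1.3,
                 r2_min: float = 0.95, stability: float = 0.05) -> GuinierFit:
    """Automatic window search returning the accepted Guinier fit."""
    return _auto_search(curve, qrg_max, r2_min, stability)[1]


def dimensionless_kratky(curve: ScatteringCurve, fit: GuinierFit) -> KratkyCurve:
    """Transform a curve to dimensionless Kratky coordinates.

    x = q Rg and y = x^2 I(q) / I(0) using the Guinier-derived Rg and
    I(0); invariant under rescaling of the intensities.  The globular
    reference point (sqrt(3), 3/e) is attached for plotting.
    """
    if fit.Rg <= 0 or fit.I0 <= 0:
        raise ArgumentError("Guinier fit must have positive Rg and I0")
    x = curve.q * fit.Rg
    y = x**2 * curve.I / fit.I0
    return KratkyCurve(x=x, y=y)


@dataclass(frozen=True)
class RgTrace:
    """Per-frame Guinier Rg across a frame series, with group summaries.

    ``table`` has one row per frame (frame_index, Rg, Rg_err, ok, reason);
    frames failing the Guinier analysis are flagged, never dropped.
    ``groups`` maps a group name to (mean, sd, n) over its analyzable
    frames.
    """

    table: pd.DataFrame
    groups: dict


def _resolve_groups(groups, n):
    if groups is None:
        return {}
    if groups == "thirds":
        third = n // 3
        return {"first_third": list(range(third)),
                "last_third": list(range(n - third, n))}
    return {name: list(idx) for name, idx in groups.items()}


def rg_evolution(series: FrameSeries,
                 policy: str | tuple = "auto",
                 groups="thirds") -> RgTrace:
    """Guinier Rg for every frame of a SEC-SAXS series.

    policy
        ``"auto"`` runs the automatic window search per frame; a
        ``(qrg_lo, qrg_hi)`` tuple applies a fixed q Rg window refit per
        frame; ``"fixed"`` determines the window on the first analyzable
        frame and freezes its q range for all others.
    groups
        ``"thirds"`` (first/last third, as used to diagnose an Rg drift
        across an elution peak), or a mapping name -> frame indices.
    """
    if len(series) < 2:
        raise ArgumentError("rg_evolution needs >= 2 frames")
    frozen_window = None
    rows = []
    for k, frame in enumerate(series.frames):
        rg = rg_err = np.nan
        ok, reason = True, ""
        try:
            if policy == "auto":
                fit = auto_guinier(frame)
            elif policy == "fixed":
                if frozen_window is None:
                    fit = auto_guinier(frame)
                    frozen_window = fit.q_window
                else:
                    q0, q1 = frozen_window
                    idx = np.nonzero((frame.q >= q0) & (frame.q <= q1))[0]
                    fit = _fit_indices(frame, idx)
            else:
                fit = guinier_fit(frame, window=tuple(policy))
            rg, rg_err = fit.Rg, fit.Rg_err
        except (InsufficientDataError, NoGuinierRegionError) as exc:
            ok, reason = False, str(exc)
        rows.append({"frame_index": series.frame_index[k],
                     "Rg": rg, "Rg_err": rg_err, "ok": ok, "reason": reason})
    table = pd.DataFrame(rows)
    summaries = {}
    for name, idx in _resolve_groups(groups, len(series)).items():
        sub = table.iloc[idx]
        good = sub[sub.ok]
        summaries[name] = (float(good.Rg.mean()),
                           float(good.Rg.std(ddof=1)) if len(good) > 1 else 0.0,
                           int(len(good)))
    return RgTrace(table=table, groups=summaries)
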