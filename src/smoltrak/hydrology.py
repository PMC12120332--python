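"""Flow-duration curves and percentage-exceedance standardization.

A flow-duration curve (FDC) relates a river's discharge to the percentage
of days that discharge is exceeded (Q95 = flow exceeded 95% of days, Q50 =
median flow, ...).  Expressing an observed discharge as its exceedance
percentile makes discharge comparable across rivers of very different
size: the exceedance of a flow depends only on where it sits in that
river's own flow regime.

Empirical exceedance uses the Weibull plotting position i/(n+1) (standard
hydrological practice, and it keeps the endpoints off 0/100 so the curve
is invertible).  A shape-preserving monotone cubic (PCHIP) interpolant is
fitted through the (exceedance, flow) pairs, and observed discharges are
mapped back to exceedance by root finding on that curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq


class DegenerateCurveError(ValueError):
    """Raised when a discharge series cannot support an FDC (constant flow)."""


@dataclass
class FlowDurationCurve:
    """Monotone flow <-> exceedance relationship for one river."""

    support: np.ndarray       # sorted unique daily mean discharges, ascending
    exceedance: np.ndarray    # percent of days each discharge is exceeded
    _flow_of_exc: PchipInterpolator  # exceedance (%) -> flow

    @property
    def flow_range(self):
        return float(self.support[0]), float(self.support[-1])

    def flow_at_exceedance(self, p):
        """Discharge exceeded ``p`` percent of the time (the Qp value)."""
        lo, hi = float(self.exceedance[-1]), float(self.exceedance[0])
        return float(self._flow_of_exc(np.clip(p, lo, hi)))


def build_fdc(daily_discharge) -> FlowDurationCurve:
    """Build the empirical flow-duration curve from >= 30 daily mean flows.

    Tied flows are collapsed to their mean plotting position so the curve
    stays strictly monotone; a constant series has no defined exceedance
    away from its single value and raises :class:`DegenerateCurveError`.
    """
    q = np.asarray(pd.Series(daily_discharge).dropna(), dtype=float)
    if len(q) < 30:
        raise ValueError(f"need >= 30 daily values to build an FDC, got {len(q)}")
    if (q < 0).any():
        raise ValueError("discharges must be non-negative")
    if np.ptp(q) < 1e-12:
        raise DegenerateCurveError("constant discharge series: exceedance undefined off the single value")

    n = len(q)
    order = np.argsort(q)[::-1]          # descending: rank 1 = largest flow
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    exc = 100.0 * ranks / (n + 1.0)      # Weibull plotting position

    df = pd.DataFrame({"flow": q, "exc": exc}).groupby("flow", as_index=False)["exc"].mean()
    flows = df["flow"].to_numpy()
    excs = df["exc"].to_numpy()          # strictly decreasing in flow
    interp = PchipInterpolator(excs[::-1], flows[::-1], extrapolate=False)
    return FlowDurationCurve(support=flows, exceedance=excs, _flow_of_exc=interp)


def exceedance_for_discharge(fdc: FlowDurationCurve, q_obs: float) -> float:
    """Percentage exceedance of an observed discharge.

    Solves flow(p) = q_obs on the monotone FDC.  Discharges outside the
    observed support are clamped to it with a warning rather than
    extrapolated.
    """
    lo, hi = fdc.flow_range
    q = float(q_obs)
    if q < lo or q > hi:
        warnings.warn(f"observed discharge {q} outside FDC support [{lo}, {hi}]; clamped")
        q = min(max(q, lo), hi)
    p_lo, p_hi = float(fdc.exceedance[-1]), float(fdc.exceedance[0])
    f = lambda p: float(fdc._flow_of_exc(p)) - q
    f_lo, f_hi = f(p_lo), f(p_hi)
    if f_lo <= 0:           # q at/above the largest support flow
        return p_lo
    if f_hi >= 0:           # q at/below the smallest support flow
        return p_hi
    return float(brentq(f, p_lo, p_hi, xtol=1e-10))


def migration_window_mean_discharge(daily_discharge: pd.DataFrame, window) -> float:
    """Mean of daily mean discharge inside the closed migration window
    (first tagging day through last downstream detection day).

    ``daily_discharge`` needs ``date`` and ``discharge_m3s`` columns.
    """
    start, end = (pd.Timestamp(w) for w in window)
    dates = pd.to_datetime(daily_discharge["date"], utc=True)
    if start.tz is None:
        start = start.tz_localize("UTC")
    if end.tz is None:
        end = end.tz_localize("UTC")
    sel = daily_discharge.loc[(dates >= start) & (dates <= end), "discharge_m3s"]
    if len(sel) == 0:
        name = ""
        if "river" in daily_discharge.columns and len(daily_discharge):
            name = f" for {daily_discharge['river'].iloc[0]}"
        raise ValueError(f"migration window [{start}, {end}] does not overlap the discharge series{name}")
    return float(sel.mean())
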