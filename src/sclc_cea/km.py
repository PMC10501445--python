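"""Pseudo-IPD reconstruction from digitized Kaplan-Meier curves.

Published survival figures provide only curve coordinates and a
numbers-at-risk table.  This module rebuilds per-subject (time, event)
records whose Kaplan-Meier estimate reproduces the digitized curve, in the
interval-constrained style used for survival extrapolation in health
technology assessment: within each at-risk interval the event and censoring
counts are chosen so the reconstructed product-limit value at the interval
end tracks the digitized survival, events sit at the digitized drop times,
and censorings are spread uniformly through the interval.

Conventions
-----------
The at-risk count ``n_i`` reported at time ``T_i`` counts subjects still at
risk *entering* the interval ``(T_i, T_{i+1}]``; events and censorings with
times in that half-open interval account for the decrement to ``n_{i+1}``.
Subjects still at risk after the last tabulated time are censored at the
last digitized time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "DigitizedCurve",
    "RiskTable",
    "InfeasibleRiskTableError",
    "preprocess_curve",
    "reconstruct_ipd",
    "km_estimate",
]

IPD_COLUMNS = ("time_months", "event", "arm", "endpoint")


class InfeasibleRiskTableError(ValueError):
    """The at-risk table cannot be realised by any event/censor allocation."""


@dataclass(frozen=True)
class DigitizedCurve:
    """Ordered (time, survival) coordinates read off a published KM plot."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        if len(t) != len(s):
            raise ValueError("times and survival must have equal length")
        if len(t) and (t[0] != 0.0 or s[0] != 1.0):
            raise ValueError("curve must start at (0, 1.0); run preprocess_curve first")
        if np.any(np.diff(t) < 0):
            raise ValueError("curve times must be non-decreasing")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing; run preprocess_curve first")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("survival values must lie in [0, 1]")

    def at(self, t: float) -> float:
        """Step-function survival: value at the last coordinate <= t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        idx = max(int(idx), 0)
        return float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "survival": self.survival})


@dataclass(frozen=True)
class RiskTable:
    """Numbers at risk printed beneath a published KM plot."""

    times: np.ndarray
    n_risk: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.n_risk, dtype=int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_risk", n)
        if len(t) != len(n):
            raise ValueError("times and n_risk must have equal length")
        if len(t) < 1:
            raise ValueError("risk table needs at least one entry")
        if np.any(np.diff(t) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        bad = np.nonzero(np.diff(n) > 0)[0]
        if len(bad):
            i = int(bad[0])
            raise InfeasibleRiskTableError(
                f"at-risk count increases between t={t[i]} and t={t[i + 1]} "
                f"({n[i]} -> {n[i + 1]})"
            )
        if np.any(n < 0):
            raise ValueError("at-risk counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "n_risk": self.n_risk})


def preprocess_curve(raw_points) -> DigitizedCurve:
    """Clean plot-read coordinates into a valid survival step function.

    Clamps survival into [0, 1], deduplicates repeated times (keeping the
    last reading), prepends (0, 1.0) when absent, and enforces monotone
    non-increase by a running minimum.
    """
    pts = np.asarray(raw_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("raw_points must be an iterable of (time, survival) pairs")
    pts = pts[np.isfinite(pts).all(axis=1)]
    if len(pts) == 0:
        raise ValueError("need at least 2 valid points")
    order = np.argsort(pts[:, 0], kind="stable")
    pts = pts[order]
    # deduplicate times, keep last reading
    _, last_idx = np.unique(pts[::-1, 0], return_index=True)
    keep = len(pts) - 1 - last_idx
    pts = pts[np.sort(keep)]
    t = pts[:, 0]
    s = np.clip(pts[:, 1], 0.0, 1.0)
    if t[0] != 0.0:
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])
    else:
        s[0] = 1.0
    s = np.minimum.accumulate(s)
    if len(t) < 2:
        raise ValueError("need at least 2 valid points")
    return DigitizedCurve(t, s)


def _km_after(segment: list[tuple[float, int]], at_risk: int, km: float) -> float:
    """Product-limit value after processing (time, is_event) records.

    Ties at equal times process events before censorings, matching the
    standard KM convention.
    """
    segment = sorted(segment, key=lambda r: (r[0], -r[1]))
    i = 0
    while i < len(segment):
        t0 = segment[i][0]
        d = c = 0
        while i < len(segment) and segment[i][0] == t0:
            if segment[i][1]:
                d += 1
            else:
                c += 1
            i += 1
        if d:
            if at_risk <= 0:
                return km
            km *= max(1.0 - d / at_risk, 0.0)
        at_risk -= d + c
    return km


def _allocate_events(d: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of d events over drop weights (ties to
    the earlier drop)."""
    if d == 0 or len(weights) == 0:
        return np.zeros(len(weights), dtype=int)
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    frac = d * w / w.sum()
    base = np.floor(frac).astype(int)
    rem = frac - base
    short = d - base.sum()
    # stable argsort on -remainder keeps earlier drops first on ties
    order = np.argsort(-rem, kind="stable")
    for j in order[:short]:
        base[j] += 1
    return base


def _interval_records(d: int, c: int, lo: float, hi: float,
                      drop_times: np.ndarray, drop_weights: np.ndarray
                      ) -> list[tuple[float, int]]:
    recs: list[tuple[float, int]] = []
    if len(drop_times):
        counts = _allocate_events(d, drop_weights)
        for t0, k in zip(drop_times, counts):
            recs.extend([(float(t0), 1)] * int(k))
    elif d:
        recs.extend([(0.5 * (lo + hi), 1)] * d)
    if c:
        cts = lo + (np.arange(1, c + 1) / (c + 1)) * (hi - lo)
        recs.extend((float(t0), 0) for t0 in cts)
    return recs


def reconstruct_ipd(curve: DigitizedCurve, risk: RiskTable, *,
                    arm: str = "active", endpoint: str = "OS") -> pd.DataFrame:
    """Rebuild pseudo individual patient data from a curve and risk table.

    Within each at-risk interval the split of the known total decrement into
    events and censorings is chosen (by exhaustive search over the interval's
    decrement) to minimise the gap between the reconstructed KM value and the
    digitized survival at the interval end; this cumulative targeting stops
    rounding errors from accumulating across intervals.
    """
    T = risk.times
    N = risk.n_risk
    if T[0] < curve.times[0] - 1e-9 or T[-1] > curve.times[-1] + 1e-9:
        raise ValueError(
            "risk-table times must lie within the digitized curve's time range"
        )
    records: list[tuple[float, int]] = []
    km_cur = curve.at(T[0])
    for i in range(len(T) - 1):
        lo, hi = float(T[i]), float(T[i + 1])
        n_i, n_next = int(N[i]), int(N[i + 1])
        delta = n_i - n_next
        target = curve.at(hi)
        in_iv = (curve.times > lo + 1e-12) & (curve.times <= hi + 1e-12)
        drops = -np.diff(curve.survival)
        drop_mask = in_iv[1:] & (drops > 1e-12)
        drop_times = curve.times[1:][drop_mask]
        drop_weights = drops[drop_mask]

        best_d, best_gap, best_recs = 0, np.inf, []
        for d in range(delta + 1):
            recs = _interval_records(d, delta - d, lo, hi, drop_times, drop_weights)
            km_new = _km_after(recs, n_i, km_cur)
            gap = abs(km_new - target)
            if gap < best_gap - 1e-15:
                best_d, best_gap, best_recs = d, gap, recs
        records.extend(best_recs)
        km_cur = _km_after(best_recs, n_i, km_cur)

    # residual subjects: censored at the last digitized time
    records.extend([(float(curve.times[-1]), 0)] * int(N[-1]))

    df = pd.DataFrame(records, columns=["time_months", "event"])
    df["arm"] = arm
    df["endpoint"] = endpoint
    return df.sort_values(["time_months", "event"], ascending=[True, False],
                          kind="stable", ignore_index=True)


def km_estimate(ipd: pd.DataFrame) -> DigitizedCurve:
    """Product-limit estimate of reconstructed/simulated records."""
    if len(ipd) == 0:
        raise ValueError("empty IPD")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd["time_months"], event_observed=ipd["event"])
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    if len(t) == 0 or t[0] != 0.0:
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])
    return DigitizedCurve(t, np.clip(s, 0.0, 1.0))
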