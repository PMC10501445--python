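"""Comparative economics: ICER/NMB, tornado, PSA, CEAC and price scenarios.

All analyses operate on :class:`CEResult` pairs (active vs control).  The
heavier ones take an *evaluator* — a callable mapping a
:class:`~sclc_cea.params.ModelParams` to a ``(active, control)`` result pair
— or a *price bundle* exposing ``evaluate(price_factor)``, so they run
identically on the full Markov model and on simple affine surrogates built
from published per-arm totals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from .params import AE_NAMES, ModelParams

logger = logging.getLogger(__name__)

__all__ = [
    "CEResult",
    "ICERReport",
    "icer",
    "nmb",
    "AffineBundle",
    "price_scenario",
    "threshold_price",
    "ThresholdResult",
    "draw_psa_params",
    "run_psa",
    "PSAResults",
    "ceac",
    "tornado",
    "COST_PARAMETERS",
    "PROBABILITY_PARAMETERS",
]

Evaluator = Callable[[ModelParams], tuple["CEResult", "CEResult"]]


@dataclass(frozen=True)
class CEResult:
    """Per-arm discounted totals (undiscounted companions optional)."""

    arm: str
    cost: float
    ly: float
    qaly: float
    cost_undiscounted: float | None = None
    ly_undiscounted: float | None = None
    qaly_undiscounted: float | None = None

    def __post_init__(self):
        if min(self.cost, self.ly, self.qaly) < 0:
            raise ValueError("totals must be non-negative")
        if self.qaly > self.ly + 1e-9:
            raise ValueError("QALYs cannot exceed life-years (utilities <= 1)")

    def to_dict(self) -> dict:
        return {
            "arm": self.arm,
            "cost": self.cost,
            "ly": self.ly,
            "qaly": self.qaly,
        }


@dataclass(frozen=True)
class ICERReport:
    """Incremental comparison of the active arm against the control arm."""

    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_qaly: float | None
    icer_per_ly: float | None
    status: str  # "ok" | "dominant" | "dominated" | "undefined"

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_ly": self.delta_ly,
            "delta_qaly": self.delta_qaly,
            "icer_per_qaly": self.icer_per_qaly,
            "icer_per_ly": self.icer_per_ly,
            "status": self.status,
        }


def icer(active: CEResult, control: CEResult) -> ICERReport:
    """Incremental cost-effectiveness ratios with dominance flags.

    The active arm *dominates* when it is cheaper and more effective
    (no ratio is reported), and is *dominated* in the mirror case.
    A ratio is undefined when the QALY difference is numerically zero.
    """
    dc = active.cost - control.cost
    dq = active.qaly - control.qaly
    dl = active.ly - control.ly
    if not all(map(math.isfinite, (dc, dq, dl))):
        raise ValueError("totals must be finite")
    if dc < 0 and dq > 0:
        status, per_q = "dominant", None
    elif dc > 0 and dq < 0:
        status, per_q = "dominated", None
    elif abs(dq) < 1e-12:
        status, per_q = "undefined", None
    else:
        status, per_q = "ok", dc / dq
    per_l = dc / dl if abs(dl) >= 1e-12 and status == "ok" else None
    return ICERReport(dc, dl, dq, per_q, per_l, status)


def nmb(result: CEResult, wtp: float) -> float:
    """Net monetary benefit ``wtp * QALY - cost``."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * result.qaly - result.cost


# ---------------------------------------------------------------------------
# price bundles
# ---------------------------------------------------------------------------

class PriceBundle(Protocol):
    def evaluate(self, price_factor: float) -> tuple[CEResult, CEResult]:
        """Results with the drug's price scaled by ``price_factor``."""


@dataclass(frozen=True)
class AffineBundle:
    """Price bundle over fixed per-arm totals with a known drug-attributable
    per-patient cost in the active arm.

    With ``price_factor`` f the active-arm cost becomes
    ``cost - (1 - f) * drug_cost_active``; effects are unchanged.  Useful for
    scenario arithmetic on published totals.
    """

    active: CEResult
    control: CEResult
    drug_cost_active: float

    def evaluate(self, price_factor: float) -> tuple[CEResult, CEResult]:
        a = self.active
        new_cost = a.cost - (1.0 - price_factor) * self.drug_cost_active
        return (
            CEResult(arm=a.arm, cost=new_cost, ly=a.ly, qaly=a.qaly),
            self.control,
        )


@dataclass(frozen=True)
class PriceScenarioResult:
    discount: float
    active: CEResult
    control: CEResult
    report: ICERReport


def price_scenario(bundle: PriceBundle, discount: float) -> PriceScenarioResult:
    """Re-evaluate both arms with the drug price reduced by ``discount``."""
    if not 0.0 <= discount <= 1.0:
        raise ValueError(f"price discount must lie in [0, 1], got {discount!r}")
    active, control = bundle.evaluate(1.0 - discount)
    return PriceScenarioResult(discount, active, control, icer(active, control))


@dataclass(frozen=True)
class ThresholdResult:
    status: str  # "ok" | "no_discount_needed" | "unreachable"
    discount: float | None
    discount_closed_form: float | None
    icer_at_discount: float | None


def _icer_at(bundle: PriceBundle, d: float) -> ICERReport:
    a, c = bundle.evaluate(1.0 - d)
    return icer(a, c)


def threshold_price(bundle: PriceBundle, wtp: float, *, rel_tol: float = 1e-6
                    ) -> ThresholdResult:
    """Price discount d* at which the ICER equals the WTP threshold.

    Solved by bisection on d in [0, 1]; because the ICER is affine in the
    discount (the drug price enters costs linearly and leaves effects
    untouched), the closed-form affine solution is computed as a
    cross-check and reported alongside.
    """
    r0 = _icer_at(bundle, 0.0)
    r1 = _icer_at(bundle, 1.0)
    if r0.delta_qaly <= 0:
        raise ValueError("threshold price requires a positive QALY gain")
    icer0 = r0.icer_per_qaly if r0.status == "ok" else -math.inf
    icer1 = r1.icer_per_qaly if r1.status == "ok" else -math.inf
    if icer0 <= wtp:
        return ThresholdResult("no_discount_needed", 0.0, 0.0, icer0)
    if icer1 >= wtp:
        return ThresholdResult("unreachable", None, None, None)

    # closed form of the affine relation ICER(d) = (dC0 - d*(dC0-dC1)) / dQ
    d_closed = (r0.delta_cost - wtp * r0.delta_qaly) / (r0.delta_cost - r1.delta_cost)

    lo, hi = 0.0, 1.0
    while hi - lo > 1e-13:
        d_mid = 0.5 * (lo + hi)
        rep = _icer_at(bundle, d_mid)
        val = rep.icer_per_qaly if rep.status == "ok" else -math.inf
        if val > wtp:
            lo = d_mid
        else:
            hi = d_mid
    d_mid = 0.5 * (lo + hi)
    rep = _icer_at(bundle, d_mid)
    if rep.status == "ok" and abs(rep.icer_per_qaly - wtp) / wtp > rel_tol:
        logger.warning("threshold_price: bisection residual exceeds tolerance")
    return ThresholdResult("ok", d_mid, float(d_closed), rep.icer_per_qaly)


# ---------------------------------------------------------------------------
# parameter registry for sensitivity analyses
# ---------------------------------------------------------------------------

COST_PARAMETERS: tuple[str, ...] = (
    "cost_serplulimab_cycle",
    "cost_etoposide_cycle",
    "cost_irinotecan_cycle",
    "cost_carboplatin_cycle",
    "cost_bsc_cycle",
    "cost_followup_cycle",
    *(f"adverse_events.{ae}.cost" for ae in AE_NAMES),
)

PROBABILITY_PARAMETERS: tuple[str, ...] = (
    "utility_pfs",
    "utility_pd",
    *(f"adverse_events.{ae}.disutility" for ae in AE_NAMES),
    *(f"adverse_events.{ae}.risk_active" for ae in AE_NAMES),
    *(f"adverse_events.{ae}.risk_control" for ae in AE_NAMES),
    "subsequent_immuno_share_active",
    "subsequent_immuno_share_control",
)


def _get_param(params: ModelParams, name: str) -> float:
    if name.startswith("adverse_events."):
        _, ae, fieldname = name.split(".")
        return getattr(params.adverse_events[ae], fieldname)
    return getattr(params, name)


def _set_param(params: ModelParams, name: str, value: float) -> ModelParams:
    out = params.replace()
    if name.startswith("adverse_events."):
        _, ae, fieldname = name.split(".")
        setattr(out.adverse_events[ae], fieldname, value)
    else:
        setattr(out, name, value)
    return out


# ---------------------------------------------------------------------------
# one-way sensitivity analysis
# ---------------------------------------------------------------------------

def tornado(evaluator: Evaluator, base_params: ModelParams, *,
            rel_range: float = 0.2,
            discount_range: tuple[float, float] = (0.0, 0.08),
            horizon_range: tuple[float, float] | None = (2.0, None),
            extra_parameters: Sequence[str] = ()) -> pd.DataFrame:
    """One-way sensitivity analysis of the ICER.

    Every cost, utility, disutility, AE-risk and pathway-share parameter is
    varied to ``base*(1 +/- rel_range)`` with all others held at base; the
    discount rate and the time horizon use their dedicated ranges (horizon
    high defaults to the base horizon).  Rows are sorted by descending
    ICER spread.
    """
    entries = []
    varied = list(COST_PARAMETERS) + list(PROBABILITY_PARAMETERS) + list(extra_parameters)

    def _icer_of(p: ModelParams) -> float | None:
        a, c = evaluator(p)
        rep = icer(a, c)
        return rep.icer_per_qaly

    for name in varied:
        base = _get_param(base_params, name)
        lo_v, hi_v = base * (1.0 - rel_range), base * (1.0 + rel_range)
        entries.append((name, base, lo_v, hi_v))
    entries.append(
        ("discount_annual", base_params.discount_annual, *discount_range)
    )
    if horizon_range is not None:
        h_lo, h_hi = horizon_range
        h_hi = base_params.horizon_years if h_hi is None else h_hi
        entries.append(("horizon_years", base_params.horizon_years, h_lo, h_hi))

    rows = []
    for name, base, lo_v, hi_v in entries:
        icer_lo = _icer_of(_set_param(base_params, name, lo_v))
        icer_hi = _icer_of(_set_param(base_params, name, hi_v))
        spread = (
            abs(icer_hi - icer_lo)
            if icer_lo is not None and icer_hi is not None
            else math.nan
        )
        rows.append(
            {
                "parameter": name,
                "base": base,
                "low": lo_v,
                "high": hi_v,
                "icer_low": icer_lo,
                "icer_high": icer_hi,
                "spread": spread,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("spread", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def draw_psa_params(base: ModelParams, seed: int, index: int) -> ModelParams:
    """One PSA parameter draw, reproducible from ``(seed, index)``.

    Costs follow Gamma distributions and utilities/disutilities/
    probabilities follow Beta distributions, each with mean equal to the
    base-case value and SD equal to 20% of the mean (Gamma shape 25; Beta
    by method of moments).  Parameters that are degenerate (0 or 1) stay
    fixed, as do the discount rate, horizon and survival parameters.
    """
    rng = np.random.default_rng([int(seed), int(index)])
    out = base.replace()
    for name in COST_PARAMETERS:
        mean = _get_param(base, name)
        if mean <= 0:
            continue
        draw = rng.gamma(shape=25.0, scale=mean / 25.0)
        out = _set_param(out, name, float(draw))
    for name in PROBABILITY_PARAMETERS:
        mean = _get_param(base, name)
        if mean <= 0.0 or mean >= 1.0:
            continue
        var = (0.2 * mean) ** 2
        cap = mean * (1.0 - mean)
        if var >= cap:
            logger.warning(
                "draw_psa_params: SD for %s infeasible for a Beta; shrunk", name
            )
            var = 0.9 * cap
        nu = cap / var - 1.0
        a, b = mean * nu, (1.0 - mean) * nu
        out = _set_param(out, name, float(rng.beta(a, b)))
    return out


@dataclass
class PSAResults:
    """Draw-level PSA output plus summary statistics."""

    draws: pd.DataFrame
    wtp: float
    seed: int
    base_active: CEResult | None = None
    base_control: CEResult | None = None

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    def prob_cost_effective(self, wtp: float | None = None) -> float:
        """Fraction of draws in which the active arm has positive
        incremental net monetary benefit."""
        w = self.wtp if wtp is None else wtp
        inc_nmb = w * self.draws["delta_qaly"] - self.draws["delta_cost"]
        return float((inc_nmb > 0).mean())

    def ceac(self, wtp_grid: Sequence[float] | None = None) -> pd.DataFrame:
        return ceac(self.draws["delta_cost"], self.draws["delta_qaly"], wtp_grid)

    def summary(self) -> dict:
        d = self.draws
        mean_dc = float(d["delta_cost"].mean())
        mean_dq = float(d["delta_qaly"].mean())
        return {
            "n_draws": self.n_draws,
            "seed": self.seed,
            "wtp": self.wtp,
            "mean_delta_cost": mean_dc,
            "mean_delta_qaly": mean_dq,
            "mean_delta_ly": float(d["delta_ly"].mean()),
            "icer_of_means": mean_dc / mean_dq if abs(mean_dq) > 1e-12 else None,
            "prob_cost_effective": self.prob_cost_effective(),
        }

    def plot_ceac(self, ax=None):
        """Cost-effectiveness acceptability curve (probability vs WTP)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.ceac()
        ax.plot(curve["wtp"], curve["prob_cost_effective"], drawstyle="steps-post")
        ax.axvline(self.wtp, color="grey", linestyle="--", linewidth=0.8)
        ax.set_xlabel("Willingness to pay ($/QALY)")
        ax.set_ylabel("Probability cost-effective (active arm)")
        ax.set_ylim(-0.02, 1.02)
        return ax


def run_psa(evaluator: Evaluator, base_params: ModelParams, *,
            n_draws: int = 1000, seed: int = 20230831,
            wtp: float | None = None) -> PSAResults:
    """Monte-Carlo PSA: evaluate both arms under ``n_draws`` parameter draws."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    w = base_params.wtp if wtp is None else wtp
    rows = []
    for i in range(n_draws):
        p = draw_psa_params(base_params, seed, i)
        active, control = evaluator(p)
        rows.append(
            {
                "draw": i,
                "cost_active": active.cost,
                "ly_active": active.ly,
                "qaly_active": active.qaly,
                "cost_control": control.cost,
                "ly_control": control.ly,
                "qaly_control": control.qaly,
                "delta_cost": active.cost - control.cost,
                "delta_ly": active.ly - control.ly,
                "delta_qaly": active.qaly - control.qaly,
            }
        )
    draws = pd.DataFrame(rows)
    draws["inc_nmb"] = w * draws["delta_qaly"] - draws["delta_cost"]
    return PSAResults(draws=draws, wtp=w, seed=seed)


def ceac(delta_cost, delta_qaly, wtp_grid: Sequence[float] | None = None
         ) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve of the active arm."""
    dc = np.asarray(delta_cost, dtype=float)
    dq = np.asarray(delta_qaly, dtype=float)
    if len(dc) == 0:
        raise ValueError("CEAC needs at least one PSA draw")
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 200_001.0, 2000.0)
    grid = np.asarray(wtp_grid, dtype=float)
    prob = [(w * dq - dc > 0).mean() for w in grid]
    return pd.DataFrame({"wtp": grid, "prob_cost_effective": prob})
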