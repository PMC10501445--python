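"""Model/Results front end of the cost-effectiveness analysis.

:class:`CostEffectivenessModel` bundles the per-arm fitted survival curves
with a :class:`~sclc_cea.params.ModelParams` input set; ``fit()`` runs the
cohort engine for both arms and returns :class:`CEResults` with the per-arm
totals, the incremental comparison and a text ``summary()``.  The
sensitivity analyses (tornado, PSA, CEAC), price scenarios and the
threshold-price solve hang off the model, reusing cohort traces whenever a
varied parameter cannot change the transition structure (prices, utilities,
AE inputs and pathway shares only enter the accrual step).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import econ
from .econ import CEResult, ICERReport, PSAResults, ThresholdResult, icer
from .markov import CohortTrace, accrue, build_trace
from .params import ARM_ACTIVE, ARM_CONTROL, ModelParams
from .survival import SurvivalFit, fit_all, select_model
from .synthetic import DEFAULT_MEDIANS, DEFAULT_SHAPES, calibrate_to_median

__all__ = ["CostEffectivenessModel", "CEResults"]

ENDPOINTS = ("PFS", "OS")

# parameters whose variation forces a rebuild of the cohort traces
_TRACE_FIELDS = (
    "horizon_years",
    "cycle_length_days",
    "background_mortality_annual",
    "secondline_duration",
)


def _weibull_fit_from_params(lambda_: float, gamma: float, *, endpoint: str,
                             arm: str) -> SurvivalFit:
    """Wrap externally calibrated Weibull parameters as a pseudo-fit.

    loglik/AIC/BIC are not meaningful for calibrated (not fitted)
    parameters and are set to NaN.
    """
    return SurvivalFit(
        family="weibull",
        params={"rate": float(lambda_), "shape": float(gamma)},
        loglik=float("nan"),
        n=1,
        n_events=1,
        endpoint=endpoint,
        arm=arm,
    )


class CostEffectivenessModel:
    """Markov cohort cost-effectiveness model of active vs control arm.

    Parameters
    ----------
    fits : nested mapping ``{arm: {endpoint: SurvivalFit}}`` with arms
        ``active``/``control`` and endpoints ``PFS``/``OS``.
    params : model inputs; defaults to the published base case.
    """

    def __init__(self, fits: dict[str, dict[str, SurvivalFit]],
                 params: ModelParams | None = None):
        for arm in (ARM_ACTIVE, ARM_CONTROL):
            for ep in ENDPOINTS:
                if ep not in fits.get(arm, {}):
                    raise ValueError(f"missing survival fit for {arm}/{ep}")
        self.fits = fits
        self.params = (params or ModelParams()).validate()
        self._trace_cache: dict[tuple, dict[str, CohortTrace]] = {}

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_medians(cls, params: ModelParams | None = None,
                     medians: dict | None = None,
                     shapes: dict | None = None) -> "CostEffectivenessModel":
        """Build from median survival times via Weibull calibration.

        Defaults are the trial's printed medians (PFS 5.7 vs 4.3 months,
        OS 15.4 vs 10.9 months) with the documented placeholder shapes.
        """
        medians = DEFAULT_MEDIANS if medians is None else medians
        shapes = DEFAULT_SHAPES if shapes is None else shapes
        fits: dict[str, dict[str, SurvivalFit]] = {}
        for ep, arm_medians in medians.items():
            for arm, m in arm_medians.items():
                wb = calibrate_to_median(m, shapes[ep])
                fits.setdefault(arm, {})[ep] = _weibull_fit_from_params(
                    wb.lambda_, wb.gamma, endpoint=ep, arm=arm
                )
        return cls(fits, params)

    @classmethod
    def from_ipd(cls, ipd: pd.DataFrame, params: ModelParams | None = None,
                 family: str = "auto") -> "CostEffectivenessModel":
        """Fit survival curves to pseudo-IPD and build the model.

        ``family="auto"`` fits all five candidate families per arm and
        endpoint and keeps the AIC/BIC winner; a family name forces that
        family everywhere.
        """
        from .survival import fit_distribution

        fits: dict[str, dict[str, SurvivalFit]] = {}
        for arm in (ARM_ACTIVE, ARM_CONTROL):
            for ep in ENDPOINTS:
                sub = ipd[(ipd["arm"] == arm) & (ipd["endpoint"] == ep)]
                if len(sub) == 0:
                    raise ValueError(f"no IPD records for {arm}/{ep}")
                if family == "auto":
                    fit = select_model(fit_all(sub, endpoint=ep, arm=arm))
                else:
                    fit = fit_distribution(sub, family, endpoint=ep, arm=arm)
                fits.setdefault(arm, {})[ep] = fit
        return cls(fits, params)

    # -- evaluation ---------------------------------------------------------
    def _traces_for(self, params: ModelParams) -> dict[str, CohortTrace]:
        key = tuple(getattr(params, f) for f in _TRACE_FIELDS)
        if key not in self._trace_cache:
            self._trace_cache[key] = {
                arm: build_trace(
                    self.fits[arm]["PFS"], self.fits[arm]["OS"], params, arm
                )
                for arm in (ARM_ACTIVE, ARM_CONTROL)
            }
        return self._trace_cache[key]

    def evaluate(self, params: ModelParams | None = None
                 ) -> tuple[CEResult, CEResult]:
        """(active, control) totals under the given (default: base) inputs.

        Horizons at or below the base horizon reuse the base traces by
        truncation; other trace-shaping changes trigger a rebuild.
        """
        p = self.params if params is None else params
        base = self.params
        truncatable = (
            p.horizon_years <= base.horizon_years
            and all(
                getattr(p, f) == getattr(base, f)
                for f in _TRACE_FIELDS
                if f != "horizon_years"
            )
        )
        if truncatable:
            traces = self._traces_for(base)
            n_cyc = p.n_cycles
            out = tuple(
                accrue(traces[arm], p, arm, n_cycles=n_cyc)
                for arm in (ARM_ACTIVE, ARM_CONTROL)
            )
        else:
            traces = self._traces_for(p)
            out = tuple(
                accrue(traces[arm], p, arm) for arm in (ARM_ACTIVE, ARM_CONTROL)
            )
        return out  # type: ignore[return-value]

    def fit(self) -> "CEResults":
        """Run both arms at the base-case inputs."""
        active, control = self.evaluate()
        traces = self._traces_for(self.params)
        return CEResults(self, active, control, icer(active, control), traces)

    # -- price bundle protocol ---------------------------------------------
    def evaluate_price(self, price_factor: float) -> tuple[CEResult, CEResult]:
        return self.evaluate(self.params.replace(serplulimab_price_factor=price_factor))

    # -- analyses -----------------------------------------------------------
    def tornado(self, **kw) -> pd.DataFrame:
        return econ.tornado(self.evaluate, self.params, **kw)

    def psa(self, n_draws: int = 1000, seed: int = 20230831,
            wtp: float | None = None) -> PSAResults:
        res = econ.run_psa(
            self.evaluate, self.params, n_draws=n_draws, seed=seed, wtp=wtp
        )
        res.base_active, res.base_control = self.evaluate()
        return res

    def price_scenario(self, discount: float) -> econ.PriceScenarioResult:
        return econ.price_scenario(_ModelBundle(self), discount)

    def threshold_price(self, wtp: float | None = None) -> ThresholdResult:
        w = self.params.wtp if wtp is None else wtp
        return econ.threshold_price(_ModelBundle(self), w)


@dataclass(frozen=True)
class _ModelBundle:
    """PriceBundle adapter over a full model."""

    model: CostEffectivenessModel

    def evaluate(self, price_factor: float) -> tuple[CEResult, CEResult]:
        return self.model.evaluate_price(price_factor)


class CEResults:
    """Base-case output: per-arm totals, incremental comparison, traces."""

    def __init__(self, model: CostEffectivenessModel, active: CEResult,
                 control: CEResult, report: ICERReport,
                 traces: dict[str, CohortTrace]):
        self.model = model
        self.active = active
        self.control = control
        self.report = report
        self.traces = traces

    def arm_results(self) -> dict[str, CEResult]:
        return {ARM_ACTIVE: self.active, ARM_CONTROL: self.control}

    def to_dict(self) -> dict:
        return {
            "arms": {a: r.to_dict() for a, r in self.arm_results().items()},
            "incremental": self.report.to_dict(),
            "wtp": self.model.params.wtp,
        }

    def summary(self) -> str:
        rep = self.report
        lines = [
            "Cost-effectiveness results (discounted)",
            "=" * 55,
            f"{'arm':<10}{'cost ($)':>14}{'LY':>10}{'QALY':>10}",
            "-" * 55,
        ]
        for arm, r in self.arm_results().items():
            lines.append(f"{arm:<10}{r.cost:>14,.2f}{r.ly:>10.4f}{r.qaly:>10.4f}")
        lines += [
            "-" * 55,
            f"incremental cost   : {rep.delta_cost:>12,.2f} $",
            f"incremental LY     : {rep.delta_ly:>12.4f}",
            f"incremental QALY   : {rep.delta_qaly:>12.4f}",
        ]
        if rep.status == "ok":
            lines.append(f"ICER               : {rep.icer_per_qaly:>12,.2f} $/QALY")
            if rep.icer_per_ly is not None:
                lines.append(f"                     {rep.icer_per_ly:>12,.2f} $/LY")
        else:
            lines.append(f"ICER status        : {rep.status}")
        wtp = self.model.params.wtp
        inc_nmb = wtp * rep.delta_qaly - rep.delta_cost
        lines.append(f"inc. NMB @ ${wtp:,.0f}/QALY: {inc_nmb:>12,.2f} $")
        return "\n".join(lines)

    def plot_trace(self, arm: str = ARM_ACTIVE, ax=None):
        """State occupancies over time for one arm."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tr = self.traces[arm].to_frame()
        for col, label in (
            ("occ_pfs", "PFS"),
            ("occ_pd1", "1st PD (2nd-line)"),
            ("occ_pd2", "2nd+ PD (BSC)"),
            ("occ_death", "death"),
        ):
            ax.plot(tr["t_years"], tr[col], label=label)
        ax.set_xlabel("years")
        ax.set_ylabel("state occupancy")
        ax.set_title(f"cohort trace ({arm})")
        ax.legend()
        return ax
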