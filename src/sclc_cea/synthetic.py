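"""Synthetic trial data emulating ASTRUM-005-like survival structure.

No individual patient data are publicly available for the underlying
phase-III trial, so every pipeline stage is exercised on simulated inputs
with the statistical structure the analysis assumes: two arms randomised
2:1 (585 patients total), Weibull event times calibrated to the printed
median PFS (5.7 vs 4.3 months) and OS (15.4 vs 10.9 months), and
administrative censoring at the end of follow-up.  The generator also emits
"digitized" curve coordinates and numbers-at-risk tables so the
reconstruction stage can be round-trip tested.

The fitted Weibull shapes of the original analysis are unpublished; the
default calibration shapes (1.2 for PFS, 1.0 for OS) are documented
placeholders, configurable everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .km import DigitizedCurve, RiskTable
from .params import ARM_ACTIVE, ARM_CONTROL, ModelParams

__all__ = [
    "TrialDesign",
    "WeibullArmParams",
    "DEFAULT_MEDIANS",
    "DEFAULT_SHAPES",
    "calibrate_to_median",
    "default_arm_params",
    "gen_weibull_ipd",
    "gen_digitized_fixture",
    "table1_fixture",
]

# printed trial medians (months) per endpoint and arm
DEFAULT_MEDIANS = {
    "PFS": {ARM_ACTIVE: 5.7, ARM_CONTROL: 4.3},
    "OS": {ARM_ACTIVE: 15.4, ARM_CONTROL: 10.9},
}
# calibration shapes (placeholders; the source analysis does not report them)
DEFAULT_SHAPES = {"PFS": 1.2, "OS": 1.0}


@dataclass(frozen=True)
class TrialDesign:
    """Randomised design: total size, allocation ratio and follow-up."""

    n_total: int = 585
    allocation_ratio: tuple[int, int] = (2, 1)  # active : control
    accrual_horizon_months: float = 30.0  # administrative censoring
    seed: int = 20230831

    def __post_init__(self):
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if min(self.allocation_ratio) <= 0:
            raise ValueError("allocation ratio components must be positive")

    def arm_sizes(self) -> dict[str, int]:
        a, c = self.allocation_ratio
        n_active = round(self.n_total * a / (a + c))
        return {ARM_ACTIVE: n_active, ARM_CONTROL: self.n_total - n_active}


@dataclass(frozen=True)
class WeibullArmParams:
    """Rate-form Weibull S(t) = exp(-lambda * t**gamma)."""

    lambda_: float
    gamma: float

    def __post_init__(self):
        if self.lambda_ <= 0 or self.gamma <= 0:
            raise ValueError("lambda and gamma must be positive")

    def survival(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.exp(-self.lambda_ * np.power(t, self.gamma))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        # inverse transform: t = (-log U / lambda)**(1/gamma)
        u = rng.uniform(size=n)
        return np.power(-np.log(u) / self.lambda_, 1.0 / self.gamma)


def calibrate_to_median(median: float, gamma: float) -> WeibullArmParams:
    """Weibull rate such that S(median) = 0.5 exactly: lambda = ln2/median**gamma."""
    if median <= 0 or gamma <= 0:
        raise ValueError("median and gamma must be positive")
    return WeibullArmParams(lambda_=math.log(2.0) / median**gamma, gamma=gamma)


def default_arm_params(medians: dict | None = None, shapes: dict | None = None
                       ) -> dict[str, dict[str, WeibullArmParams]]:
    """Per-endpoint, per-arm Weibull parameters calibrated to trial medians."""
    medians = DEFAULT_MEDIANS if medians is None else medians
    shapes = DEFAULT_SHAPES if shapes is None else shapes
    return {
        ep: {arm: calibrate_to_median(m, shapes[ep]) for arm, m in arms.items()}
        for ep, arms in medians.items()
    }


def gen_weibull_ipd(design: TrialDesign,
                    arm_params: dict[str, dict[str, WeibullArmParams]] | None = None,
                    censor_time: float | None = None) -> pd.DataFrame:
    """Simulate pseudo-IPD for every endpoint and arm.

    Event times are Weibull draws; times beyond ``censor_time`` (default:
    the design's accrual horizon) are recorded as censored there.  Output
    columns: ``time_months, event, arm, endpoint``.
    """
    if arm_params is None:
        arm_params = default_arm_params()
    ct = design.accrual_horizon_months if censor_time is None else float(censor_time)
    if ct < 0:
        raise ValueError("censor_time must be >= 0")
    rng = np.random.default_rng(design.seed)
    sizes = design.arm_sizes()
    frames = []
    for endpoint in sorted(arm_params):
        for arm in (ARM_ACTIVE, ARM_CONTROL):
            t = arm_params[endpoint][arm].sample(rng, sizes[arm])
            event = (t <= ct).astype(int)
            frames.append(
                pd.DataFrame(
                    {
                        "time_months": np.minimum(t, ct),
                        "event": event,
                        "arm": arm,
                        "endpoint": endpoint,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def gen_digitized_fixture(arm_params: WeibullArmParams, read_times,
                          design: TrialDesign, *, arm: str = ARM_ACTIVE,
                          risk_times=None, noise_sd: float = 0.0,
                          rng: np.random.Generator | None = None
                          ) -> tuple[DigitizedCurve, RiskTable]:
    """Emulate plot-digitizer output: curve coordinates plus a risk table.

    Curve points are the model survival S(t) at ``read_times`` (strictly
    increasing from 0), optionally perturbed by additive uniform digitization
    noise of half-width ``noise_sd`` and re-monotonized.  The risk table
    holds expected at-risk counts (arm size x S(t), before administrative
    censoring) at ``risk_times`` (default: every 6th read time).
    """
    rt = np.asarray(read_times, dtype=float)
    if len(rt) < 2 or rt[0] != 0.0 or np.any(np.diff(rt) <= 0):
        raise ValueError("read_times must be strictly increasing and start at 0")
    s = arm_params.survival(rt)
    if noise_sd > 0.0:
        if rng is None:
            rng = np.random.default_rng(design.seed)
        s = s + rng.uniform(-noise_sd, noise_sd, size=len(s))
        s[0] = 1.0
        s = np.minimum.accumulate(np.clip(s, 0.0, 1.0))
    curve = DigitizedCurve(rt, s)

    n_arm = design.arm_sizes()[arm]
    if risk_times is None:
        risk_times = rt[::6] if len(rt) > 6 else rt[[0, -1]]
    risk_times = np.asarray(risk_times, dtype=float)
    expected = np.round(n_arm * arm_params.survival(risk_times)).astype(int)
    expected = np.minimum.accumulate(expected)  # guard against rounding bumps
    return curve, RiskTable(risk_times, expected)


def table1_fixture() -> ModelParams:
    """Base-case model inputs (the published evaluation's input table)."""
    return ModelParams()
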