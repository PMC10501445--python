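"""Four-state Markov cohort engine for the ES-SCLC model.

States: progression-free survival (PFS), first progression on second-line
therapy (PD1, a tunnel of ``secondline_duration`` cycles), second and later
progression on best supportive care (PD2), and death.  The cohort enters
100% in PFS.  Per 21-day cycle at model time t:

* PFS -> PD1 with the time-varying progression probability
  ``Prob(FtP) = (P(t) - P(t+1)) / P(t)`` from the fitted PFS curve;
* PFS -> death with the age-independent background mortality probability
  per cycle (all-cause mortality, not disease-specific);
* PD1, PD2 -> death with ``Prob(PtD) = (O(t) - O(t+1)) / (O(t) - P(t))``
  from the fitted OS and PFS curves, clipped into [0, 1];
* PD1 residents advance to PD2 after the tunnel elapses; death is absorbing.

Accrual applies a half-cycle correction (average of adjacent-cycle
occupancies), discounts at the cycle-start time, and adds a one-off
adverse-event cost and QALY decrement at model entry (grade >=3 events
cluster in the induction phase).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .econ import CEResult
from .params import ARM_ACTIVE, DAYS_PER_YEAR, Demographics, ModelParams
from .survival import SurvivalFit, survival_at

logger = logging.getLogger(__name__)

__all__ = [
    "CohortTrace",
    "prob_progress",
    "prob_pd_death",
    "background_mortality_cycle",
    "compute_doses",
    "build_trace",
    "accrue",
]

_EPS = 1e-12


def prob_progress(p_t: float, p_next: float) -> float:
    """Per-cycle PFS->progression probability (P(t) - P(t+1)) / P(t)."""
    if p_t < 0 or p_t > 1 or p_next < 0:
        raise ValueError("survival probabilities must lie in [0, 1]")
    if p_next > p_t + 1e-9:
        raise ValueError(f"P(t+1)={p_next} exceeds P(t)={p_t}")
    if p_t <= _EPS:
        return 0.0  # empty state: no one left to progress
    return min(max((p_t - p_next) / p_t, 0.0), 1.0)


def prob_pd_death(p_t: float, o_t: float, o_next: float) -> float:
    """Per-cycle PD->death probability (O(t) - O(t+1)) / (O(t) - P(t)).

    Values outside [0, 1] (digitization noise can make the curves cross)
    are clipped with a logged warning.
    """
    denom = o_t - p_t
    if denom <= _EPS:
        logger.warning(
            "prob_pd_death: O(t) - P(t) = %.3e <= 0 (empty PD state); returning 0",
            denom,
        )
        return 0.0
    raw = (o_t - o_next) / denom
    if raw < 0.0 or raw > 1.0:
        logger.warning("prob_pd_death: raw value %.4f clipped into [0, 1]", raw)
    return min(max(raw, 0.0), 1.0)


def background_mortality_cycle(annual_prob: float, cycle_length_days: float = 21.0) -> float:
    """Convert an annual all-cause death probability to a per-cycle one."""
    if not 0.0 <= annual_prob < 1.0:
        raise ValueError(f"annual probability must lie in [0, 1), got {annual_prob!r}")
    return 1.0 - (1.0 - annual_prob) ** (cycle_length_days / DAYS_PER_YEAR)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def compute_doses(demo: Demographics, *, serplulimab_mg_per_kg: float = 4.5,
                  etoposide_mg_per_m2: float = 100.0,
                  carboplatin_auc: float = 5.0) -> dict[str, float]:
    """Per-administration doses (mg), rounded half-up to the nearest mg.

    Serplulimab is weight-based (4.5 mg/kg); etoposide is BSA-based
    (100 mg/m2 on days 1-3, so the per-cycle total is 3 daily doses);
    carboplatin follows the Calvert formula ``AUC x (CrCl + 25)`` with
    creatinine clearance from Cockcroft-Gault (male form, Scr in mg/dL).
    """
    if min(demo.weight_kg, demo.bsa_m2, demo.serum_creatinine_mg_dl) <= 0:
        raise ValueError("weight, BSA and serum creatinine must be positive")
    crcl = ((140.0 - demo.age_years) * demo.weight_kg) / (
        72.0 * demo.serum_creatinine_mg_dl
    )
    if demo.sex == "female":
        crcl *= 0.85
    etoposide_daily = _round_half_up(etoposide_mg_per_m2 * demo.bsa_m2)
    return {
        "serplulimab_mg": _round_half_up(serplulimab_mg_per_kg * demo.weight_kg),
        "etoposide_mg_per_day": etoposide_daily,
        "etoposide_mg_per_cycle": 3 * etoposide_daily,
        "carboplatin_mg": _round_half_up(carboplatin_auc * (crcl + 25.0)),
        "crcl_ml_min": crcl,
    }


@dataclass
class CohortTrace:
    """Per-cycle state occupancies (rows 0..n_cycles inclusive)."""

    occ_pfs: np.ndarray
    occ_pd1: np.ndarray
    occ_pd2: np.ndarray
    occ_death: np.ndarray
    cycle_length_days: float
    arm: str

    @property
    def n_cycles(self) -> int:
        return len(self.occ_pfs) - 1

    @property
    def t_years(self) -> np.ndarray:
        return np.arange(len(self.occ_pfs)) * self.cycle_length_days / DAYS_PER_YEAR

    def occupancy_matrix(self) -> np.ndarray:
        return np.column_stack([self.occ_pfs, self.occ_pd1, self.occ_pd2, self.occ_death])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self.occ_pfs)),
                "t_years": self.t_years,
                "occ_pfs": self.occ_pfs,
                "occ_pd1": self.occ_pd1,
                "occ_pd2": self.occ_pd2,
                "occ_death": self.occ_death,
            }
        )


def build_trace(pfs_fit: SurvivalFit, os_fit: SurvivalFit, params: ModelParams,
                arm: str = ARM_ACTIVE, *, n_cycles: int | None = None) -> CohortTrace:
    """Run the cohort through ``n_cycles`` (default: floor(horizon / cycle))."""
    params.validate()
    n_cyc = params.n_cycles if n_cycles is None else int(n_cycles)
    if n_cyc <= 0:
        raise ValueError("horizon must cover at least one cycle")
    cyc_m = params.cycle_months
    t_bound = np.arange(n_cyc + 1) * cyc_m  # months at cycle boundaries
    P = np.asarray(survival_at(pfs_fit, t_bound), dtype=float)
    O = np.asarray(survival_at(os_fit, t_bound), dtype=float)
    p_bg = background_mortality_cycle(
        params.background_mortality_annual, params.cycle_length_days
    )

    K = max(int(params.secondline_duration), 1)
    pd1 = np.zeros(K)  # tunnel compartments, pd1[j] = in 2nd-line for j cycles
    pfs, pd2, dead = 1.0, 0.0, 0.0

    occ = np.zeros((n_cyc + 1, 4))
    occ[0] = (pfs, 0.0, 0.0, 0.0)
    renormalised = False
    for k in range(n_cyc):
        p_prog = prob_progress(P[k], min(P[k + 1], P[k]))
        if p_prog + p_bg > 1.0:
            p_prog = 1.0 - p_bg  # mortality floor preserved
            renormalised = True
        if O[k] - P[k] <= _EPS:
            p_ptd = 0.0  # PD states empty (model entry): nothing to transition
        else:
            p_ptd = prob_pd_death(P[k], O[k], min(O[k + 1], O[k]))

        to_pd = pfs * p_prog
        pfs_death = pfs * p_bg
        pd_death = (pd1.sum() + pd2) * p_ptd

        pfs = pfs - to_pd - pfs_death
        surv_pd1 = pd1 * (1.0 - p_ptd)
        pd2 = pd2 * (1.0 - p_ptd) + surv_pd1[K - 1]
        pd1[1:] = surv_pd1[:-1]
        pd1[0] = to_pd
        dead += pfs_death + pd_death

        occ[k + 1] = (pfs, pd1.sum(), pd2, dead)

    if renormalised:
        logger.warning(
            "build_trace(%s): PFS exit probabilities exceeded 1 in some cycles; "
            "progression reduced to preserve the background-mortality floor",
            arm,
        )
    return CohortTrace(
        occ_pfs=occ[:, 0], occ_pd1=occ[:, 1], occ_pd2=occ[:, 2], occ_death=occ[:, 3],
        cycle_length_days=params.cycle_length_days, arm=arm,
    )


def _state_costs(params: ModelParams, arm: str, n_cyc: int) -> tuple[np.ndarray, float, float]:
    """Per-cycle unit costs for (PFS by cycle index, PD1, PD2)."""
    serp = params.cost_serplulimab_cycle * params.serplulimab_price_factor
    active = arm == ARM_ACTIVE
    chemo = params.cost_etoposide_cycle + params.cost_carboplatin_cycle
    induction = chemo + (serp if active else 0.0)
    maintenance = serp if active else 0.0
    pfs_cost = np.full(n_cyc, maintenance + params.cost_followup_cycle)
    pfs_cost[: params.induction_cycles] = induction + params.cost_followup_cycle

    mix = params.secondline_mix_irinotecan
    secondline_chemo = (
        mix * (params.cost_irinotecan_cycle + params.cost_carboplatin_cycle)
        + (1.0 - mix) * (params.cost_etoposide_cycle + params.cost_carboplatin_cycle)
    )
    pd1_cost = (
        secondline_chemo
        + params.immuno_share(arm) * (serp if active else 0.0)
        + params.cost_followup_cycle
    )
    pd2_cost = params.cost_bsc_cycle
    return pfs_cost, pd1_cost, pd2_cost


def accrue(trace: CohortTrace, params: ModelParams, arm: str | None = None,
           *, n_cycles: int | None = None) -> CEResult:
    """Accumulate discounted and undiscounted cost, LY and QALY totals.

    ``n_cycles`` may truncate the trace (shorter horizon on the same
    occupancy path), which the one-way sensitivity analysis exploits.
    """
    arm = trace.arm if arm is None else arm
    n_cyc = trace.n_cycles if n_cycles is None else min(int(n_cycles), trace.n_cycles)
    cyc_y = params.cycle_years

    occ = trace.occupancy_matrix()[: n_cyc + 1]
    mid = 0.5 * (occ[:-1] + occ[1:])  # half-cycle correction
    t_start = np.arange(n_cyc) * cyc_y
    disc = (1.0 + params.discount_annual) ** (-t_start)

    pfs_cost, pd1_cost, pd2_cost = _state_costs(params, arm, n_cyc)
    cost_cyc = mid[:, 0] * pfs_cost + mid[:, 1] * pd1_cost + mid[:, 2] * pd2_cost
    ly_cyc = (mid[:, 0] + mid[:, 1] + mid[:, 2]) * cyc_y
    qaly_cyc = (
        mid[:, 0] * params.utility_pfs + (mid[:, 1] + mid[:, 2]) * params.utility_pd
    ) * cyc_y

    ae_cost = sum(p.cost * p.risk(arm) for p in params.adverse_events.values())
    ae_qaly = sum(p.disutility * p.risk(arm) for p in params.adverse_events.values()) * cyc_y

    cost_undisc = float(cost_cyc.sum() + ae_cost)
    ly_undisc = float(ly_cyc.sum())
    qaly_undisc = float(qaly_cyc.sum() - ae_qaly)
    return CEResult(
        arm=arm,
        cost=float((cost_cyc * disc).sum() + ae_cost),  # AE burden at t=0, disc=1
        ly=float((ly_cyc * disc).sum()),
        qaly=float((qaly_cyc * disc).sum() - ae_qaly),
        cost_undiscounted=cost_undisc,
        ly_undiscounted=ly_undisc,
        qaly_undiscounted=qaly_undisc,
    )
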