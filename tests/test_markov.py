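"""Cohort engine: transitions, doses, traces and accrual."""

import math

import numpy as np
import pytest

from sclc_cea import (
    Demographics,
    ModelParams,
    accrue,
    background_mortality_cycle,
    build_trace,
    compute_doses,
    prob_pd_death,
    prob_progress,
    survival_at,
)
from sclc_cea.survival import SurvivalFit


def _wfit(rate, shape=1.0):
    return SurvivalFit("weibull", {"rate": rate, "shape": shape}, 0.0, 1, 1)


FLAT = _wfit(1e-12)  # survival ~ 1 over the whole horizon


class TestTransitionProbabilities:
    def test_prob_progress_boundaries(self):
        assert prob_progress(1.0, 1.0) == 0.0
        assert prob_progress(0.5, 0.0) == 1.0
        assert prob_progress(0.0, 0.0) == 0.0  # empty state

    def test_prob_progress_exponential_cycle(self):
        lam = math.log(2) / 5.7
        p_next = math.exp(-lam * 0.69)
        assert prob_progress(1.0, p_next) == pytest.approx(0.0805, abs=2e-4)

    def test_prob_progress_rejects_increasing_survival(self):
        with pytest.raises(ValueError):
            prob_progress(0.5, 0.6)

    def test_prob_pd_death_arithmetic(self):
        assert prob_pd_death(0.4, 0.8, 0.7) == pytest.approx(0.25)
        assert prob_pd_death(0.4, 0.8, 0.8) == 0.0

    def test_prob_pd_death_clips_and_handles_empty_state(self, caplog):
        assert prob_pd_death(0.75, 0.8, 0.7) == 1.0  # raw 2.0 -> clipped
        assert prob_pd_death(0.8, 0.8, 0.7) == 0.0  # O(t)=P(t): empty PD

    def test_background_mortality(self):
        assert background_mortality_cycle(0.0) == 0.0
        assert background_mortality_cycle(0.00718) == pytest.approx(4.14e-4, abs=1e-6)
        # inverse identity round-trips the annual probability
        q = 0.00718
        per_cycle = background_mortality_cycle(q)
        assert 1 - (1 - per_cycle) ** (365.25 / 21) == pytest.approx(q, rel=1e-10)
        with pytest.raises(ValueError):
            background_mortality_cycle(1.5)


class TestDoses:
    def test_published_demographics(self):
        doses = compute_doses(Demographics())
        assert doses["serplulimab_mg"] == 293  # round-half-up of 4.5*65=292.5
        assert doses["etoposide_mg_per_day"] == 172
        assert doses["etoposide_mg_per_cycle"] == 516
        assert doses["crcl_ml_min"] == pytest.approx(71.23, abs=0.01)
        assert doses["carboplatin_mg"] == 481  # Calvert: 5*(71.23+25)

    def test_invalid_demographics_rejected(self):
        with pytest.raises(ValueError):
            compute_doses(Demographics(weight_kg=0.0))


class TestTrace:
    def test_no_transitions_keeps_cohort_in_pfs(self):
        p = ModelParams(background_mortality_annual=0.0, discount_annual=0.0)
        tr = build_trace(FLAT, FLAT, p)
        assert tr.occ_pfs[-1] == pytest.approx(1.0)
        res = accrue(tr, p)
        assert res.ly_undiscounted == pytest.approx(tr.n_cycles * p.cycle_years)

    def test_occupancy_conservation_and_absorbing_death(self, base_model):
        p = base_model.params
        tr = build_trace(base_model.fits["active"]["PFS"], base_model.fits["active"]["OS"], p)
        rows = tr.occupancy_matrix()
        assert np.abs(rows.sum(axis=1) - 1.0).max() < 1e-9
        assert (np.diff(tr.occ_death) >= -1e-12).all()
        assert ((rows >= -1e-12) & (rows <= 1 + 1e-12)).all()

    def test_alive_fraction_tracks_os_after_burn_in(self):
        """With zero background mortality the model's survivors follow the OS
        curve; the first cycle's OS drop cannot be realised (the PD state is
        still empty), an offset that decays over subsequent cycles."""
        p = ModelParams(background_mortality_annual=0.0)
        pfs, osf = _wfit(math.log(2) / 2.0), _wfit(0.05)
        tr = build_trace(pfs, osf, p)
        t_b = np.arange(tr.n_cycles + 1) * p.cycle_months
        O = survival_at(osf, t_b)
        dev = np.abs((1 - tr.occ_death) - O)
        assert dev.max() <= (1 - O[1]) + 1e-9  # bounded by the cycle-0 gap
        assert dev[-1] < 5e-4  # and it decays

    def test_trace_ly_matches_exponential_closed_form(self):
        """Background-mortality-only cohort: undiscounted LY equals the
        truncated exponential integral (1 - e^(-lambda T)) / lambda."""
        q = 0.15
        p = ModelParams(background_mortality_annual=q, discount_annual=0.0)
        tr = build_trace(FLAT, FLAT, p)
        res = accrue(tr, p)
        lam = -math.log(1.0 - q)  # per year
        T = tr.n_cycles * p.cycle_years
        closed = (1.0 - math.exp(-lam * T)) / lam
        assert res.ly_undiscounted == pytest.approx(closed, rel=2e-3)


class TestAccrue:
    def test_qaly_equals_ly_with_unit_utilities_no_aes(self):
        p = ModelParams(utility_pfs=1.0, utility_pd=1.0)
        for prof in p.adverse_events.values():
            prof.risk_active = prof.risk_control = 0.0
        tr = build_trace(_wfit(0.1), _wfit(0.05), p)
        res = accrue(tr, p, "active")
        assert res.qaly == pytest.approx(res.ly, rel=1e-12)

    def test_discounting_strictly_reduces_totals(self, base_model):
        p0 = base_model.params.replace(discount_annual=0.0)
        p5 = base_model.params.replace(discount_annual=0.05)
        tr = build_trace(base_model.fits["active"]["PFS"], base_model.fits["active"]["OS"], p0)
        r0, r5 = accrue(tr, p0, "active"), accrue(tr, p5, "active")
        assert r5.cost < r0.cost and r5.qaly < r0.qaly and r5.ly < r0.ly

    def test_cost_linearity(self, base_model):
        """Doubling every unit cost doubles the total cost."""
        p = base_model.params
        doubled = p.replace(
            **{
                f: 2 * getattr(p, f)
                for f in (
                    "cost_serplulimab_cycle",
                    "cost_etoposide_cycle",
                    "cost_irinotecan_cycle",
                    "cost_carboplatin_cycle",
                    "cost_bsc_cycle",
                    "cost_followup_cycle",
                )
            }
        )
        for prof in doubled.adverse_events.values():
            prof.cost *= 2
        tr = build_trace(base_model.fits["active"]["PFS"], base_model.fits["active"]["OS"], p)
        assert accrue(tr, doubled, "active").cost == pytest.approx(
            2 * accrue(tr, p, "active").cost, rel=1e-12
        )

    def test_shorter_horizon_never_increases_totals(self, base_model):
        p = base_model.params
        tr = build_trace(base_model.fits["active"]["PFS"], base_model.fits["active"]["OS"], p)
        full = accrue(tr, p, "active")
        short = accrue(tr, p, "active", n_cycles=p.n_cycles // 3)
        assert short.cost <= full.cost
        assert short.ly <= full.ly and short.qaly <= full.qaly

    def test_bsc_only_control_costs_nothing_without_pd(self):
        p = ModelParams(
            background_mortality_annual=0.0,
            cost_etoposide_cycle=0.0,
            cost_carboplatin_cycle=0.0,
            cost_irinotecan_cycle=0.0,
            cost_followup_cycle=0.0,
        )
        for prof in p.adverse_events.values():
            prof.risk_control = 0.0
        tr = build_trace(FLAT, FLAT, p, "control")  # no progression ever
        # PD occupancy from the ~1e-12 rate leak is ~1e-10, so BSC accrues
        # essentially nothing
        assert accrue(tr, p, "control").cost == pytest.approx(0.0, abs=1e-5)

    def test_cycle_count(self):
        assert ModelParams().n_cycles == 129  # floor(7.44 * 365.25 / 21)
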