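"""ICER/NMB algebra, tornado, PSA draws, CEAC and price scenarios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sclc_cea import AffineBundle, CEResult, ceac, icer, nmb, price_scenario, threshold_price
from sclc_cea.econ import draw_psa_params, run_psa, tornado
from sclc_cea.params import ModelParams


def _res(arm, cost, qaly, ly=None):
    return CEResult(arm=arm, cost=cost, qaly=qaly, ly=qaly if ly is None else ly)


class TestICER:
    def test_simple_ratio(self):
        rep = icer(_res("active", 100.0, 1.0), _res("control", 0.0, 0.5))
        assert rep.icer_per_qaly == pytest.approx(200.0)
        assert rep.status == "ok"

    def test_dominant_no_ratio(self):
        rep = icer(_res("active", 50.0, 1.0), _res("control", 100.0, 0.5))
        assert rep.status == "dominant" and rep.icer_per_qaly is None

    def test_dominated(self):
        rep = icer(_res("active", 200.0, 0.4), _res("control", 100.0, 0.5))
        assert rep.status == "dominated" and rep.icer_per_qaly is None

    def test_zero_qaly_gain_undefined(self):
        rep = icer(_res("active", 200.0, 0.5), _res("control", 100.0, 0.5))
        assert rep.status == "undefined" and rep.icer_per_qaly is None

    @settings(deadline=None, derandomize=True)
    @given(
        ca=st.floats(0, 1e6), cc=st.floats(0, 1e6),
        qa=st.floats(0.01, 10), qc=st.floats(0.01, 10),
        wtp=st.floats(0, 5e5),
    )
    def test_nmb_sign_consistent_with_icer(self, ca, cc, qa, qc, wtp):
        """Positive incremental NMB <=> ICER < WTP whenever dQ > 0."""
        active, control = _res("active", ca, qa), _res("control", cc, qc)
        rep = icer(active, control)
        if rep.delta_qaly > 1e-9:
            inc_nmb = nmb(active, wtp) - nmb(control, wtp)
            icer_val = rep.icer_per_qaly if rep.status == "ok" else -np.inf
            assert (inc_nmb > 0) == (icer_val < wtp) or abs(inc_nmb) < 1e-6


class TestNMB:
    def test_zero_wtp(self):
        assert nmb(_res("a", 120.0, 1.0), 0.0) == -120.0

    def test_arithmetic(self):
        r = _res("a", 26402.0, 0.14736)
        assert nmb(r, 37423.0) - nmb(_res("c", 0.0, 0.0), 37423.0) == pytest.approx(
            37423 * 0.14736 - 26402, rel=1e-9
        )


class TestTornado:
    def test_degenerate_range_zero_spread(self, base_model):
        df = tornado(base_model.evaluate, base_model.params, rel_range=0.0,
                     discount_range=(0.05, 0.05), horizon_range=(7.44, 7.44))
        assert df["spread"].abs().max() == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_cost_endpoints_straddle_base(self, base_model):
        base_icer = base_model.fit().report.icer_per_qaly
        df = base_model.tornado()
        row = df[df.parameter == "cost_serplulimab_cycle"].iloc[0]
        assert row.icer_low < base_icer < row.icer_high

    def test_common_cost_with_equal_risks_cancels(self, base_model):
        """A cost entering both arms identically leaves the ICER unchanged."""
        p = base_model.params.replace()
        for prof in p.adverse_events.values():
            prof.risk_control = prof.risk_active  # equalise AE burden
        base = icer(*base_model.evaluate(p)).icer_per_qaly
        p2 = p.replace()
        p2.adverse_events["anemia"].cost *= 2
        assert icer(*base_model.evaluate(p2)).icer_per_qaly == pytest.approx(base, rel=1e-9)

    def test_serplulimab_cost_tops_fixed_range_parameters(self, base_model):
        df = base_model.tornado()
        pm = df[~df.parameter.isin(["horizon_years", "discount_annual"])]
        assert pm.iloc[0].parameter == "cost_serplulimab_cycle"

    def test_icer_varies_negatively_with_horizon(self, base_model):
        df = base_model.tornado()
        row = df[df.parameter == "horizon_years"].iloc[0]
        assert row.icer_low > row.icer_high  # shorter horizon -> higher ICER


class TestPSADraws:
    def test_deterministic_per_seed_index(self, base_params):
        a = draw_psa_params(base_params, seed=5, index=17)
        b = draw_psa_params(base_params, seed=5, index=17)
        assert a.to_dict() == b.to_dict()
        c = draw_psa_params(base_params, seed=5, index=18)
        assert c.cost_serplulimab_cycle != a.cost_serplulimab_cycle

    def test_gamma_mean_matches_base(self, base_params):
        draws = [
            draw_psa_params(base_params, seed=3, index=i).cost_serplulimab_cycle
            for i in range(4000)
        ]
        mean, sd = np.mean(draws), np.std(draws)
        se = sd / np.sqrt(len(draws))
        assert abs(mean - 2382.65) < 2 * se + 1e-9 or abs(mean - 2382.65) < 0.01 * 2382.65
        assert sd == pytest.approx(0.2 * 2382.65, rel=0.1)

    def test_beta_draws_stay_in_unit_interval(self, base_params):
        for i in range(200):
            d = draw_psa_params(base_params, seed=11, index=i)
            assert 0.0 < d.utility_pfs < 1.0
            assert 0.0 < d.adverse_events["anemia"].risk_active < 1.0

    def test_fixed_quantities_not_sampled(self, base_params):
        d = draw_psa_params(base_params, seed=1, index=0)
        assert d.discount_annual == base_params.discount_annual
        assert d.horizon_years == base_params.horizon_years
        assert d.background_mortality_annual == base_params.background_mortality_annual


class TestRunPSA:
    def test_seed_reproducibility(self, base_model):
        a = base_model.psa(n_draws=50, seed=99)
        b = base_model.psa(n_draws=50, seed=99)
        assert a.summary() == b.summary()
        assert a.draws.equals(b.draws)

    def test_icer_of_means_identity(self, base_model):
        s = base_model.psa(n_draws=50, seed=1).summary()
        assert s["icer_of_means"] == pytest.approx(
            s["mean_delta_cost"] / s["mean_delta_qaly"], rel=1e-12
        )

    def test_single_draw_close_to_base_case(self, base_model):
        """PSA means converge on the deterministic base case (unbiased draws)."""
        s = base_model.psa(n_draws=400, seed=2).summary()
        base = base_model.fit().report
        assert s["mean_delta_cost"] == pytest.approx(base.delta_cost, rel=0.05)
        assert s["mean_delta_qaly"] == pytest.approx(base.delta_qaly, rel=0.05)


class TestCEAC:
    def test_wtp_zero_counts_cheaper_draws(self):
        curve = ceac([10.0, -5.0, 3.0], [0.1, 0.1, 0.1], [0.0])
        assert curve.prob_cost_effective.iloc[0] == pytest.approx(1 / 3)

    def test_monotone_when_all_gains_positive(self, base_model):
        psa = base_model.psa(n_draws=100, seed=4)
        assert (psa.draws.delta_qaly > 0).all()
        curve = psa.ceac(np.arange(0, 300_001, 10_000))
        assert (np.diff(curve.prob_cost_effective) >= -1e-12).all()
        assert curve.prob_cost_effective.between(0, 1).all()

    def test_large_wtp_limit(self, base_model):
        psa = base_model.psa(n_draws=100, seed=4)
        frac_gain = (psa.draws.delta_qaly > 0).mean()
        curve = psa.ceac([1e12])
        assert curve.prob_cost_effective.iloc[0] == pytest.approx(frac_gain)


class TestPriceScenarios:
    def _bundle(self):
        active = _res("active", 33191.0, 0.7873647, ly=1.51)
        control = _res("control", 6789.0, 0.64, ly=1.25)
        return AffineBundle(active=active, control=control, drug_cost_active=25581.14)

    def test_zero_discount_unchanged(self, base_model):
        base = base_model.fit().report.icer_per_qaly
        assert base_model.price_scenario(0.0).report.icer_per_qaly == pytest.approx(
            base, rel=1e-12
        )

    def test_out_of_range_discount_rejected(self):
        with pytest.raises(ValueError):
            price_scenario(self._bundle(), 1.5)

    def test_icer_affine_in_discount(self, base_model):
        """Three-point collinearity of ICER(d) to 1e-9."""
        d = [0.0, 0.4, 0.8]
        v = [base_model.price_scenario(x).report.icer_per_qaly for x in d]
        interp = v[0] + (v[2] - v[0]) * (d[1] - d[0]) / (d[2] - d[0])
        assert v[1] == pytest.approx(interp, rel=1e-9)
        assert v[0] > v[1] > v[2]  # strictly decreasing while dQ > 0

    def test_threshold_bisection_vs_closed_form(self, base_model):
        res = base_model.threshold_price(37423.0)
        assert res.status == "ok"
        assert res.discount == pytest.approx(res.discount_closed_form, abs=1e-8)
        # defining property: plugging d* back reproduces the WTP
        rep = base_model.price_scenario(res.discount).report
        assert rep.icer_per_qaly == pytest.approx(37423.0, rel=1e-6)

    def test_threshold_status_no_discount_needed(self):
        b = self._bundle()
        assert threshold_price(b, 1e9).status == "no_discount_needed"

    def test_threshold_status_unreachable(self):
        active = _res("active", 1e6, 0.7, ly=1.5)
        b = AffineBundle(active=active, control=_res("control", 0.0, 0.6, ly=1.2),
                         drug_cost_active=10.0)  # price cut can't reach WTP
        assert threshold_price(b, 100.0).status == "unreachable"
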