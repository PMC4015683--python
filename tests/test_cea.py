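"""Net health benefit, paired PSA, acceptability curves and sweeps."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from dietmm.cea import age_targeting_sweep, ceac, nhb, run_psa
from dietmm.markov_engine import Scenario

pytestmark = pytest.mark.filterwarnings(
    "ignore:.*too few for stable.*:RuntimeWarning"
)


class TestNHB:
    def test_hand_arithmetic_low_cost(self):
        assert nhb(4.3, 16_939, 30_000) == pytest.approx(3.735366667, abs=1e-6)

    def test_zero_deltas(self):
        assert nhb(0.0, 0.0, 30_000) == 0.0

    def test_hand_arithmetic_high_cost(self):
        assert nhb(4.3, 293_276, 30_000) == pytest.approx(-5.475866667, abs=1e-6)

    def test_nonpositive_threshold(self):
        with pytest.raises(ValueError):
            nhb(1.0, 1.0, 0.0)

    def test_increasing_in_threshold_when_costly(self):
        values = [nhb(1.0, 10_000, lam) for lam in (10_000, 20_000, 40_000)]
        assert values[0] < values[1] < values[2]


class TestCEAC:
    @staticmethod
    def _frame(dq, dc):
        return pd.DataFrame({"d_qaly_3_5": dq, "d_cost_total": dc})

    def test_step_function(self):
        per_sim = self._frame([1.0] * 50, [15_000.0] * 50)
        curve = ceac(per_sim, [5_000, 10_000, 14_999, 15_001, 30_000])
        assert list(curve["probability"]) == [0.0, 0.0, 0.0, 1.0, 1.0]

    def test_dominant_intervention(self):
        per_sim = self._frame([0.5] * 20, [-100.0] * 20)
        curve = ceac(per_sim, [1_000, 30_000, 100_000])
        assert (curve["probability"] == 1.0).all()

    def test_symmetric_qalys_give_half(self):
        dq = np.concatenate([np.linspace(-1, -1e-6, 500), np.linspace(1e-6, 1, 500)])
        per_sim = self._frame(dq, np.zeros(1000))
        curve = ceac(per_sim, [10_000, 30_000])
        assert np.allclose(curve["probability"], 0.5)

    def test_monotone_when_all_qalys_positive(self):
        rng = np.random.default_rng(4)
        per_sim = self._frame(rng.uniform(0.1, 2, 200), rng.normal(5_000, 8_000, 200))
        curve = ceac(per_sim, np.arange(2_500, 100_001, 2_500))
        assert (np.diff(curve["probability"]) >= 0).all()

    def test_rejects_empty_and_bad_grid(self):
        with pytest.raises(ValueError):
            ceac(self._frame([], []))
        with pytest.raises(ValueError):
            ceac(self._frame([1.0], [1.0]), [-5.0, 10.0])


class TestRunPSA:
    def test_null_scenario_deltas_are_exactly_zero(self, small_arrays, effect):
        null = Scenario(name="null", rr_active=False, unit_cost=0.0)
        res = run_psa(small_arrays, null, effect, n_sims=20, seed=42)
        deltas = res.per_sim.drop(columns=[])
        assert (deltas.to_numpy() == 0.0).all()

    def test_cost_only_scenario_sign_logic(self, small_arrays, effect):
        costly = Scenario(name="cost_only", rr_active=False, unit_cost=35.0)
        res = run_psa(small_arrays, costly, effect, n_sims=20, seed=42)
        assert (res.per_sim["d_qaly_3_5"] == 0.0).all()
        assert (res.per_sim["d_cost_total"] > 0.0).all()
        assert (res.per_sim["nhb"] < 0.0).all()
        assert res.p_cost_effective == 0.0

    def test_fixed_seed_is_reproducible(self, small_arrays, effect):
        a = run_psa(small_arrays, Scenario(), effect, n_sims=15, seed=9)
        b = run_psa(small_arrays, Scenario(), effect, n_sims=15, seed=9)
        assert a.per_sim.equals(b.per_sim)
        assert a.ceac.equals(b.ceac)

    def test_accounting_identity_every_simulation(self, small_arrays, effect):
        res = run_psa(small_arrays, Scenario(), effect, n_sims=25, seed=1)
        np.testing.assert_array_equal(
            res.per_sim["d_cost_total"].to_numpy(),
            (res.per_sim["cost_intervention"] + res.per_sim["d_cost_other"]).to_numpy(),
        )

    def test_intervention_cost_scales_with_unit_cost(self, small_arrays, effect):
        base = Scenario(unit_cost=35.0)
        double = dataclasses.replace(base, unit_cost=70.0)
        a = run_psa(small_arrays, base, effect, n_sims=10, seed=3)
        b = run_psa(small_arrays, double, effect, n_sims=10, seed=3)
        ratio = (b.per_sim["cost_intervention"] / a.per_sim["cost_intervention"])
        np.testing.assert_allclose(ratio, 2.0, rtol=1e-12)
        # the RR pathway is untouched by the unit cost
        assert a.per_sim["d_qaly_3_5"].equals(b.per_sim["d_qaly_3_5"])

    def test_discount_ordering_per_simulation(self, small_arrays, effect):
        res = run_psa(small_arrays, Scenario(), effect, n_sims=10, seed=5)
        # 1.5%-discounted QALY gains exceed 3.5%-discounted gains here because
        # the intervention's benefits arrive late in life
        assert (res.per_sim["d_qaly_1_5"] >= res.per_sim["d_qaly_3_5"]).all()

    def test_summary_brackets_mean(self, small_arrays, effect):
        res = run_psa(small_arrays, Scenario(), effect, n_sims=40, seed=5)
        s = res.summary
        assert ((s["lo95"] <= s["mean"]) & (s["mean"] <= s["hi95"])).all()

    def test_unpaired_mode_runs(self, small_arrays, effect):
        res = run_psa(small_arrays, Scenario(), effect, n_sims=10, seed=2,
                      paired=False)
        # without common random numbers the null comparison is noisy
        assert res.per_sim["d_qaly_3_5"].std() > 0

    def test_rejects_zero_sims(self, small_arrays, effect):
        with pytest.raises(ValueError):
            run_psa(small_arrays, Scenario(), effect, n_sims=0, seed=1)


class TestAgeSweep:
    def test_six_band_table_shape(self, small_arrays, effect):
        bands = [(30, 100), (30, 74), (40, 100), (40, 74), (50, 100), (50, 74)]
        table, results = age_targeting_sweep(
            small_arrays, bands, effect, n_sims=5, seed=11
        )
        assert len(table) == 6
        assert set(results) == set(bands)
        assert {"ly_healthy", "d_qaly", "d_cost", "nhb", "p_cost_effective"} \
            <= set(table.columns)

    def test_full_band_reproduces_base_case(self, small_arrays, effect):
        table, results = age_targeting_sweep(
            small_arrays, [(30, 100)], effect, n_sims=8, seed=13
        )
        base = run_psa(small_arrays, Scenario(eligible_age=(30, 100)), effect,
                       n_sims=8, seed=13)
        assert results[(30, 100)].per_sim.equals(base.per_sim)

    def test_rejects_misordered_band(self, small_arrays, effect):
        with pytest.raises(ValueError):
            age_targeting_sweep(small_arrays, [(74, 50)], effect, n_sims=2, seed=1)

    def test_near_empty_band_has_near_zero_cost(self, small_arrays, effect):
        table, results = age_targeting_sweep(
            small_arrays, [(95, 100)], effect, n_sims=5, seed=3
        )
        base = run_psa(small_arrays, Scenario(), effect, n_sims=5, seed=3)
        assert (
            results[(95, 100)].per_sim["cost_intervention"].mean()
            < 0.02 * base.per_sim["cost_intervention"].mean()
        )
        assert abs(results[(95, 100)].nhb_mean) < abs(base.nhb_mean) + 0.5
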