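import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from swaysync.datatypes import SwayTrial
from swaysync.stats import (
    bonferroni_correct,
    lag_ttests,
    rm_anova_by_receiver,
    rm_anova_ncr,
    single_regression,
    sncr_long_table,
    variance_summary,
)


class TestBonferroni:
    def test_monotone_and_capped(self):
        assert bonferroni_correct(0.03, 2) == 0.06
        assert bonferroni_correct(0.7, 2) == 1.0
        assert bonferroni_correct(0.2, 1) == 0.2
        with pytest.raises(ValueError):
            bonferroni_correct(1.5, 2)


class TestSingleRegression:
    def test_exact_line(self):
        X = np.arange(10.0)
        reg = single_regression(X, 2 * X + 1)
        assert reg.B1 == pytest.approx(2.0)
        assert reg.B0 == pytest.approx(1.0)
        assert reg.p_B1 == pytest.approx(0.0)

    def test_agrees_with_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        X = rng.standard_normal(25)
        Y = 1.5 * X + rng.standard_normal(25)
        reg = single_regression(X, Y)
        ref = sm.OLS(Y, sm.add_constant(X)).fit()
        assert reg.B0 == pytest.approx(ref.params[0], abs=1e-10)
        assert reg.B1 == pytest.approx(ref.params[1], abs=1e-10)
        assert reg.t_B1 == pytest.approx(ref.tvalues[1], abs=1e-8)
        assert reg.p_B1 == pytest.approx(ref.pvalues[1], abs=1e-10)

    def test_bonferroni_applied_to_p_only(self, rng):
        X = rng.standard_normal(15)
        Y = rng.standard_normal(15)
        raw = single_regression(X, Y)
        corr = single_regression(X, Y, bonferroni=3)
        assert corr.p_B1 == min(1.0, 3 * raw.p_B1)
        assert corr.B1 == raw.B1

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            single_regression(np.ones(10), rng.standard_normal(10))
        with pytest.raises(ValueError):
            single_regression(np.arange(2.0), np.arange(2.0))


class TestLagTtests:
    def test_symmetric_lags_give_null_oo_test(self):
        table = lag_ttests({"OO": np.array([-3.0, -1.0, 1.0, 3.0])})
        row = table.iloc[0]
        assert row["t"] == pytest.approx(0.0)
        assert row["p_raw"] == pytest.approx(1.0)

    def test_paired_comparisons_match_scipy_with_correction(self, rng):
        oo = rng.normal(0, 50, 22)
        bo = oo + rng.normal(-150, 80, 22)
        ob = oo + rng.normal(200, 80, 22)
        table = lag_ttests({"OO": oo, "BO": bo, "OB": ob}).set_index(
            "condition"
        )
        t_ref, p_ref = sps.ttest_rel(bo, oo)
        assert table.loc["BO", "t"] == pytest.approx(t_ref)
        assert table.loc["BO", "p_corrected"] == pytest.approx(
            min(1.0, 2 * p_ref)
        )
        assert table.loc["BO", "p_corrected"] >= table.loc["BO", "p_raw"]

    def test_unpaired_data_rejected(self, rng):
        with pytest.raises(ValueError):
            lag_ttests({"OO": np.zeros(5), "BO": np.zeros(4)})
        with pytest.raises(ValueError):
            lag_ttests({"BO": np.zeros(5)})


def _long_table(cells: np.ndarray) -> pd.DataFrame:
    """Long-format ANOVA table from an (n_subjects, 8) cell array."""
    from swaysync.stats import _CELL_ORDER

    rows = []
    for pid, subject_cells in enumerate(cells):
        for (sender, receiver, distance), val in zip(
            _CELL_ORDER, subject_cells
        ):
            rows.append(
                {
                    "participant": pid,
                    "sender": sender,
                    "receiver": receiver,
                    "distance": distance,
                    "sncr": val,
                }
            )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_identical_cells_give_zero_f(self):
        res = rm_anova_ncr(_long_table(np.full((10, 8), 7.0)))
        for eff in res.effects:
            assert eff.F == 0.0 and eff.p == 1.0

    def test_injected_receiver_effect_dominates(self, rng):
        cells = rng.normal(10, 1, size=(44, 8))
        from swaysync.stats import _CELL_ORDER

        receiver_code = np.array(
            [+1 if r == "O" else -1 for (_, r, _) in _CELL_ORDER]
        )
        cells += 3.0 * receiver_code  # +3 for open receivers
        res = rm_anova_ncr(_long_table(cells))
        fs = {e.effect: e.F for e in res.effects}
        assert fs["RECEIVER"] == max(fs.values())
        assert res["RECEIVER"].p < 1e-6
        assert res["RECEIVER"].eta_p2 > 0.9
        assert res["RECEIVER"].df1 == 1 and res["RECEIVER"].df2 == 43

    def test_agrees_with_pingouin_on_two_factor_subdesign(self, rng):
        """Independent oracle for the follow-up SENDER x DISTANCE ANOVA."""
        pingouin = pytest.importorskip("pingouin")

        cells = rng.normal(10, 2, size=(20, 8))
        table = _long_table(cells)
        mine = rm_anova_by_receiver(table)["O"]
        sub = table[table["receiver"] == "O"]
        ref = pingouin.rm_anova(
            data=sub, dv="sncr", within=["sender", "distance"],
            subject="participant", detailed=True,
        ).set_index("Source")
        assert mine["SENDER"].F == pytest.approx(
            float(ref.loc["sender", "F"]), rel=1e-6
        )
        assert mine["DISTANCE"].F == pytest.approx(
            float(ref.loc["distance", "F"]), rel=1e-6
        )
        assert mine["SENDERxDISTANCE"].F == pytest.approx(
            float(ref.loc["sender * distance", "F"]), rel=1e-6
        )

    def test_incomplete_cells_rejected(self, rng):
        table = _long_table(rng.normal(10, 1, size=(6, 8)))
        broken = table[
            ~(
                (table["participant"] == 0)
                & (table["sender"] == "O")
                & (table["receiver"] == "O")
                & (table["distance"] == "Near")
            )
        ]
        with pytest.raises(ValueError):
            rm_anova_ncr(broken)


class TestVarianceSummary:
    def _trial(self, x, y, condition="OB", distance="Near"):
        return SwayTrial(
            x=x, y=y, fs=200.0, axis="AP", distance=distance,
            condition=condition, pair_id=0, trial_id=0,
        )

    def test_constant_and_unit_noise_variances(self, rng):
        n = 2000
        trial = self._trial(
            np.linspace(0, 5, n),  # pure trend: detrended variance 0
            rng.standard_normal(n),
        )
        table = variance_summary([trial]).set_index("state")
        assert table.loc["O (with partner: B)", "variance_mm2"] == (
            pytest.approx(0.0, abs=1e-12)
        )
        assert table.loc["B (with partner: O)", "variance_mm2"] == (
            pytest.approx(1.0, rel=0.15)
        )

    def test_stratifies_by_own_and_partner_state(self, rng):
        trials = [
            self._trial(rng.standard_normal(500), rng.standard_normal(500),
                        condition=c)
            for c in ("OO", "BO", "OB", "BB")
        ]
        table = variance_summary(trials)
        assert set(table["state"]) == {
            "O (with partner: O)", "O (with partner: B)",
            "B (with partner: O)", "B (with partner: B)",
        }


class TestSncrLongTable:
    def test_participant_and_role_assignment(self):
        records = [
            {
                "pair_id": 3, "condition": "BO", "distance": "Far",
                "sncr_y_to_x": 12.0, "sncr_x_to_y": 4.0,
            }
        ]
        table = sncr_long_table(records)
        # participant x (id 6) is blindfolded and receives from open y
        row_x = table[table["participant"] == 6].iloc[0]
        assert row_x["receiver"] == "B" and row_x["sender"] == "O"
        assert row_x["sncr"] == 12.0
        row_y = table[table["participant"] == 7].iloc[0]
        assert row_y["receiver"] == "O" and row_y["sender"] == "B"
        assert row_y["sncr"] == 4.0
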