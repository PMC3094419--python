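"""Supervised forward selection, pruning, per-IQR reporting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from airlur.lur import (
    LURModel,
    backward_prune,
    default_plan,
    forward_build,
    per_iqr_effects,
    predict,
    select_best_per_family,
    univariate_r2,
    GROUP_ORDER,
)


def make_table(n=60, seed=0, columns=None):
    """Independent random columns under recognisable predictor names."""
    rng = np.random.default_rng(seed)
    columns = columns or [
        "traf_buf_100",
        "traf_buf_250",
        "logdist_all",
        "flow_near_busy",
        "lu_residential_300",
        "lu_residential_1000",
        "pop_300",
        "lu_industry_300",
        "lu_water_300",
        "background_no2",
    ]
    data = {}
    for c in columns:
        if c == "background_no2":
            data[c] = rng.uniform(15, 25, n)
        elif c.startswith("lu_"):
            data[c] = rng.uniform(0, 1, n)
        elif c.startswith("logdist"):
            data[c] = rng.uniform(0, 7, n)
        else:
            data[c] = rng.uniform(0, 10000, n)
    return pd.DataFrame(data, index=[f"S{i:02d}" for i in range(n)])


class TestUnivariateR2:
    def test_self_correlation_is_one(self):
        y = np.arange(10.0)
        assert univariate_r2(y, y) == pytest.approx(1.0)

    def test_orthogonal_predictor_near_zero(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=5000)
        x = rng.normal(size=5000)
        assert univariate_r2(y, x) < 0.01

    def test_three_point_hand_value(self):
        # (1,2),(2,4),(3,5): r^2 = 81/84
        assert univariate_r2([2, 4, 5], [1, 2, 3]) == pytest.approx(81 / 84, abs=1e-4)

    def test_constant_predictor_is_zero(self):
        assert univariate_r2([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]) == 0.0


class TestBestPerFamily:
    def test_single_variant(self):
        table = make_table()
        y = table["traf_buf_100"]
        assert select_best_per_family(y, table, ["traf_buf_100"]) == "traf_buf_100"

    def test_argmax_wins(self):
        table = make_table()
        y = table["traf_buf_250"] + np.random.default_rng(1).normal(0, 1, len(table))
        got = select_best_per_family(y, table, ["traf_buf_100", "traf_buf_250"])
        assert got == "traf_buf_250"

    def test_driving_radius_beats_other_radii(self):
        table = make_table()
        rng = np.random.default_rng(2)
        y = 5.0 * table["lu_residential_300"] + rng.normal(0, 0.1, len(table))
        got = select_best_per_family(y, table, ["lu_residential_300", "lu_residential_1000"])
        assert got == "lu_residential_300"

    def test_tie_breaks_to_smaller_radius(self):
        table = make_table()
        table["lu_residential_1000"] = table["lu_residential_300"]  # exact tie
        y = table["lu_residential_300"]
        got = select_best_per_family(y, table, ["lu_residential_1000", "lu_residential_300"])
        assert got == "lu_residential_300"


class TestForwardBuild:
    def test_noise_free_recovery_selects_exactly_the_truth(self):
        table = make_table(seed=3)
        y = 4.0 + 1.0 * table["background_no2"] + 2e-3 * table["traf_buf_100"]
        model = forward_build(y.to_numpy(), table, a_priori=["background_no2"])
        assert model.variables == ["background_no2", "traf_buf_100"]
        assert model.r2 == pytest.approx(1.0)
        assert model.coefficients["traf_buf_100"] == pytest.approx(2e-3, rel=1e-6)

    def test_sign_violating_candidate_rejected(self):
        table = make_table(seed=4)
        y = -3e-3 * table["traf_buf_100"]  # strong but wrong-signed for its family
        model = forward_build(y.to_numpy(), table)
        assert "traf_buf_100" not in model.variables
        offers = [t for t in model.trace if t.get("candidate") == "traf_buf_100"]
        assert offers and not offers[0]["sign_ok"]

    def test_flipping_an_accepted_coefficient_blocks_entry(self):
        """A candidate whose entry turns the a-priori term negative is refused
        even though it raises the adjusted R-squared."""
        rng = np.random.default_rng(5)
        n = 80
        bg = rng.uniform(15, 25, n)
        confounder = 3.0 * bg + rng.normal(0, 0.5, n)
        table = pd.DataFrame({"background_no2": bg, "traf_buf_100": confounder})
        y = confounder - 2.0 * bg  # joint fit drives bg coefficient negative
        model = forward_build(y, table, a_priori=["background_no2"])
        assert "traf_buf_100" not in model.variables
        offer = [t for t in model.trace if t.get("candidate") == "traf_buf_100"][0]
        assert not offer["sign_ok"]

    def test_groups_processed_in_declared_order(self):
        table = make_table(seed=6)
        rng = np.random.default_rng(6)
        y = (
            2e-3 * table["traf_buf_100"]
            + 8.0 * table["lu_residential_300"]
            + 6.0 * table["lu_industry_300"]
            + rng.normal(0, 0.3, len(table))
        )
        model = forward_build(y.to_numpy(), table)
        picked_groups = []
        plan = default_plan(table.columns)
        for v in model.variables:
            fam = plan.family_of(v)
            for g, fams in plan.groups.items():
                if fam in fams:
                    picked_groups.append(GROUP_ORDER.index(g))
        assert picked_groups == sorted(picked_groups)

    def test_within_selected_set_is_oracle_reachable(self):
        """Exhaustive enumeration over all admissible offer orders."""
        for seed in range(8):
            table = make_table(n=50, seed=100 + seed)
            rng = np.random.default_rng(seed)
            coef = {
                "traf_buf_100": 2e-3 * rng.integers(0, 2),
                "lu_residential_300": 8.0 * rng.integers(0, 2),
                "lu_water_300": -4.0 * rng.integers(0, 2),
                "pop_300": 1e-3 * rng.integers(0, 2),
            }
            y = sum(c * table[k] for k, c in coef.items()) + rng.normal(0, 1.0, len(table))
            y = y.to_numpy()
            plan = default_plan(table.columns)
            model = forward_build(y, table, plan)
            reachable = enumerate_reachable_sets(y, table, plan)
            assert frozenset(model.variables) in reachable


def enumerate_reachable_sets(y, table, plan, delta=1.0):
    """All selections reachable under any within-group offer order.

    Independent re-statement of the acceptance rule: group order fixed,
    best-per-family candidates, accept iff the adjusted R-squared rises by
    delta points and all signs hold, rejected candidates never retried.
    """
    import statsmodels.api as sm

    def adj_r2(vars_):
        if not vars_:
            return 0.0
        X = sm.add_constant(table[list(vars_)].to_numpy(float))
        return float(sm.OLS(y, X).fit().rsquared_adj)

    def signs_ok(vars_):
        X = sm.add_constant(table[list(vars_)].to_numpy(float))
        params = sm.OLS(y, X).fit().params[1:]
        for coef, v in zip(params, vars_):
            if plan.sign_of(v) * coef < 0:
                return False
        return True

    def group_candidates(group, selected):
        out = []
        for fam in plan.groups.get(group, []):
            cols = [c for c in plan.families[fam] if c not in selected]
            if cols:
                out.append(select_best_per_family(y, table, cols))
        return out

    results = set()

    def run_group(gi, selected):
        if gi == len(GROUP_ORDER):
            results.add(frozenset(selected))
            return
        cands = group_candidates(GROUP_ORDER[gi], selected)
        for order in set(itertools.permutations(cands)):
            sel = list(selected)
            for c in order:
                trial = sel + [c]
                if adj_r2(trial) - adj_r2(sel) >= delta / 100.0 and signs_ok(trial):
                    sel = trial
            run_group(gi + 1, sel)

    run_group(0, [])
    return results


class TestBackwardPrune:
    def test_contributing_variables_survive(self):
        table = make_table(seed=7)
        rng = np.random.default_rng(7)
        y = 1.0 * table["background_no2"] + 2e-3 * table["traf_buf_100"] + rng.normal(0, 0.2, len(table))
        model = forward_build(y.to_numpy(), table, a_priori=["background_no2"])
        pruned = backward_prune(model, y.to_numpy(), table)
        assert pruned.variables == model.variables

    def test_pure_noise_variable_removed(self):
        table = make_table(n=200, seed=8)
        rng = np.random.default_rng(8)
        y = 2e-3 * table["traf_buf_100"] + rng.normal(0, 0.5, len(table))
        model = forward_build(y.to_numpy(), table)
        # inject an irrelevant variable as if selection had admitted it
        model.variables.append("lu_industry_300")
        pruned = backward_prune(model, y.to_numpy(), table)
        assert "lu_industry_300" not in pruned.variables
        assert "traf_buf_100" in pruned.variables

    def test_a_priori_variable_never_removed(self):
        table = make_table(seed=9)
        rng = np.random.default_rng(9)
        # background is pure noise for this response, yet protected
        y = 2e-3 * table["traf_buf_100"] + rng.normal(0, 0.5, len(table))
        model = forward_build(y.to_numpy(), table, a_priori=["background_no2"])
        pruned = backward_prune(model, y.to_numpy(), table)
        assert "background_no2" in pruned.variables


class TestReporting:
    def test_effect_is_coefficient_times_iqr(self):
        table = make_table(seed=10)
        y = 0.773 * table["background_no2"] + 5.0
        model = forward_build(y.to_numpy(), table, a_priori=["background_no2"])
        eff = per_iqr_effects(model, y.to_numpy(), table)
        row = eff[eff.variable == "background_no2"].iloc[0]
        iqr = np.subtract(*np.percentile(table["background_no2"], [75, 25]))
        assert row["effect_per_iqr"] == pytest.approx(0.773 * iqr, rel=1e-6)

    def test_zero_coefficient_gives_zero_effect(self):
        eff_scale = 0.773 * 4.4
        assert eff_scale == pytest.approx(3.40, abs=0.01)  # sanity of the arithmetic

    def test_constant_predictor_zero_iqr(self):
        table = make_table(seed=11)
        table["lu_water_300"] = 0.25
        y = 1.0 * table["background_no2"]
        model = LURModel(
            variables=["background_no2", "lu_water_300"],
            a_priori=["background_no2"],
            coefficients={"background_no2": 1.0, "lu_water_300": 0.0},
            intercept=0.0, r2=1.0, adj_r2=1.0, n=len(table),
        )
        eff = per_iqr_effects(model, y.to_numpy(), table)
        assert eff[eff.variable == "lu_water_300"]["effect_per_iqr"].iloc[0] == 0.0


class TestPredict:
    def test_mean_prediction_at_mean_inputs(self):
        table = make_table(seed=12)
        rng = np.random.default_rng(12)
        y = 1.0 * table["background_no2"] + rng.normal(0, 1, len(table))
        model = forward_build(y.to_numpy(), table, a_priori=["background_no2"])
        fitted = predict(model, table)
        assert fitted.mean() == pytest.approx(np.mean(y), rel=1e-9)
        assert np.sum(y - fitted) == pytest.approx(0.0, abs=1e-8)

    def test_missing_model_column_raises(self):
        table = make_table(seed=13)
        y = 1.0 * table["background_no2"]
        model = forward_build(y.to_numpy(), table, a_priori=["background_no2"])
        with pytest.raises(KeyError):
            predict(model, table.drop(columns=["background_no2"]))

    def test_json_round_trip(self):
        table = make_table(seed=14)
        y = 1.0 * table["background_no2"] + 2e-3 * table["traf_buf_100"]
        model = forward_build(y.to_numpy(), table, a_priori=["background_no2"])
        clone = LURModel.from_json(model.to_json())
        np.testing.assert_allclose(predict(clone, table), predict(model, table))


def test_final_model_never_worse_than_a_priori_only():
    for seed in range(5):
        table = make_table(seed=200 + seed)
        rng = np.random.default_rng(seed)
        y = rng.normal(20, 5, len(table))
        model = forward_build(y, table, a_priori=["background_no2"])
        base = forward_build(y, table.iloc[:, :0].assign(background_no2=table["background_no2"]),
                             a_priori=["background_no2"])
        assert model.adj_r2 >= base.adj_r2 - 1e-12
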