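import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from benthoval import skillstats as sk


def _vt(node, year, month, diffs, obs=10.0):
    """Minimal validation-table fragment with prescribed mod-obs differences."""
    diffs = np.asarray(diffs, dtype=float)
    obs = np.full(diffs.size, obs) if np.ndim(obs) == 0 else np.asarray(obs)
    return pd.DataFrame(
        {
            "node_id": node, "year": year, "month": month,
            "obs_temp": obs, "mod_temp": obs + diffs,
        }
    )


class TestSkillMetrics:
    def test_hand_computed_example(self):
        s = sk.skill_metrics([1.0, 2.0, 3.0], [0.0, 2.0, 4.0])
        assert s.mb == pytest.approx(0.0)
        assert s.me == pytest.approx(2.0 / 3.0)
        assert s.rmse == pytest.approx(np.sqrt(2.0 / 3.0))
        assert s.r == pytest.approx(1.0)
        assert s.d == pytest.approx(8.0 / 9.0)
        assert s.nmb == pytest.approx(0.0)
        assert s.nme == pytest.approx(1.0 / 3.0)

    def test_perfect_agreement_limit(self):
        s = sk.skill_metrics([4.0, 5.0, 6.0], [4.0, 5.0, 6.0])
        assert s.mb == s.me == s.rmse == 0.0
        assert s.r == pytest.approx(1.0)
        assert s.d == 1.0

    def test_zero_variance_marks_r_undefined(self):
        s = sk.skill_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert np.isnan(s.r)
        assert np.isfinite(s.d)

    def test_zero_mean_observation_marks_normalised_undefined(self):
        s = sk.skill_metrics([1.0, 2.0], [-1.0, 1.0])
        assert np.isnan(s.nmb) and np.isnan(s.nme) and np.isnan(s.nrmse)

    @settings(deadline=None, max_examples=200)
    @given(
        hnp.arrays(np.float64, st.integers(2, 30),
                   elements=st.floats(-50, 50, allow_nan=False)),
        hnp.arrays(np.float64, st.integers(2, 30),
                   elements=st.floats(-50, 50, allow_nan=False)),
    )
    def test_power_mean_ordering_and_d_bounds(self, m, o):
        k = min(m.size, o.size)
        s = sk.skill_metrics(m[:k], o[:k])
        assert abs(s.mb) <= s.me + 1e-12
        assert s.me <= s.rmse + 1e-12
        if not np.isnan(s.d):
            assert 0.0 <= s.d <= 1.0


class TestStratifiedSkill:
    def test_zero_diff_group_scores_zero_everywhere(self):
        vt = _vt(1, 2016, 6, np.zeros(5))
        ens = sk.stratified_skill(vt, "month", n_sim=50, seed=1)
        assert ens.ensemble["mb"] == 0.0
        assert ens.ensemble["me"] == 0.0
        assert ens.ensemble["rmse"] == 0.0

    def test_group_of_exactly_5_forces_the_full_draw(self):
        diffs = [0.1, 0.2, 0.3, 0.4, 0.5]
        obs = [9.0, 10.0, 11.0, 12.0, 13.0]
        vt = _vt(1, 2016, 6, diffs, obs=obs)
        ens = sk.stratified_skill(vt, "month", n_sim=40, seed=2)
        direct = sk.skill_metrics(vt["mod_temp"], vt["obs_temp"])
        for name in ("mb", "me", "rmse", "r", "d"):
            assert ens.ensemble[name] == pytest.approx(getattr(direct, name))

    def test_two_groups_of_6_match_subset_enumeration(self):
        """Ensemble ME from many replicates lies inside the exact band implied
        by enumerating all C(6,5) subsamples of each cell.

        The per-cell estimator is the median over draws from 6 equally likely
        subset MEs, so its sampling limit is pinned between the 3rd and 4th
        order statistics of those 6 values."""
        d1 = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        d2 = np.array([-0.3, -0.1, 0.0, 0.2, 0.4, 0.7])
        vt = pd.concat([_vt(1, 2016, 6, d1), _vt(2, 2016, 6, d2)], ignore_index=True)
        ens = sk.stratified_skill(vt, "month", n_sim=20_000, seed=3)
        lo, hi = [], []
        for d in (d1, d2):
            mes = sorted(
                np.abs(d[list(keep)]).mean()
                for keep in itertools.combinations(range(6), 5)
            )
            lo.append(mes[2])
            hi.append(mes[3])
        assert np.mean(lo) - 1e-9 <= ens.ensemble["me"] <= np.mean(hi) + 1e-9

    def test_duplicating_a_group_leaves_scores_stable(self):
        rng = np.random.default_rng(4)
        vt = pd.concat(
            [_vt(n, 2016, 6, rng.normal(0.5, 0.2, 40)) for n in (1, 2, 3)],
            ignore_index=True,
        )
        base = sk.stratified_skill(vt, "month", n_sim=2000, seed=5)
        dup = pd.concat([vt, vt[vt["node_id"] == 2]], ignore_index=True)
        inflated = sk.stratified_skill(dup, "month", n_sim=2000, seed=6)
        # the algorithm's purpose: sample-size changes should not move scores
        assert inflated.ensemble["me"] == pytest.approx(base.ensemble["me"], abs=0.02)

    def test_seeded_runs_are_bit_identical(self):
        rng = np.random.default_rng(7)
        vt = pd.concat(
            [_vt(n, 2016, m, rng.normal(0.3, 0.3, 12)) for n in (1, 2) for m in (5, 6)],
            ignore_index=True,
        )
        a = sk.stratified_skill(vt, "node", n_sim=200, seed=8)
        b = sk.stratified_skill(vt, "node", n_sim=200, seed=8)
        assert a.ensemble == b.ensemble
        pd.testing.assert_frame_equal(a.per_cell, b.per_cell)

    def test_selection_threshold_excludes_small_cells(self):
        vt = pd.concat(
            [_vt(1, 2016, 6, np.zeros(8)), _vt(2, 2016, 6, np.ones(3))],
            ignore_index=True,
        )
        ens = sk.stratified_skill(vt, "month", floor=5, n_sim=20, seed=9)
        assert ens.per_cell["node_id"].tolist() == [1]

    def test_no_qualifying_cells_errors_with_threshold(self):
        vt = _vt(1, 2016, 6, np.zeros(3))
        with pytest.raises(ValueError, match="threshold"):
            sk.stratified_skill(vt, "month", floor=5, n_sim=10, seed=10)


class TestPercentageImprovement:
    @staticmethod
    def _monthly_ens(values_by_month, metric_defaults=None):
        """Minimal month-stratified EnsembleScores stub for given MB values."""
        rows = []
        for month, vals in values_by_month.items():
            row = {"year": vals.get("year", 2016), "month": month,
                   "mb": vals["mb"], "me": vals.get("me", abs(vals["mb"])),
                   "rmse": vals.get("rmse", abs(vals["mb"])),
                   "r": vals.get("r", 0.9), "d": vals.get("d", 0.9),
                   "nmb": 0.0, "nme": 0.0, "nrmse": 0.0, "n_cells": 1}
            rows.append(row)
        per = pd.DataFrame(rows)
        return sk.EnsembleScores(
            stratum="month", per_cell=per, per_stratum=per,
            ensemble={}, n_min=5, n_sample=5, n_sim=10, seed=0,
        )

    def test_exact_correction_scores_100(self):
        base = self._monthly_ens({3: {"mb": 0.5}})
        upd = self._monthly_ens({3: {"mb": 0.0, "me": 0.0, "rmse": 0.0}})
        rep = sk.percentage_improvement(base, upd, months=(3,))
        assert rep.mean_p["mb"] == pytest.approx(100.0)
        assert rep.mean_p["me"] == pytest.approx(100.0)

    def test_no_change_scores_zero(self):
        base = self._monthly_ens({3: {"mb": 0.5}})
        rep = sk.percentage_improvement(base, base, months=(3,))
        for name in ("mb", "me", "rmse", "r", "d"):
            assert rep.mean_p[name] == pytest.approx(0.0)

    def test_overshoot_past_zero_exceeds_100(self):
        # a 0.53 warm bias corrected to a -0.0452 cool bias: 108.53%
        base = self._monthly_ens({3: {"mb": 0.53}})
        upd = self._monthly_ens({3: {"mb": -0.0452}})
        rep = sk.percentage_improvement(base, upd, months=(3,))
        assert rep.mean_p["mb"] == pytest.approx(108.53, abs=0.01)

    def test_bounded_metric_uses_headroom(self):
        base = self._monthly_ens({3: {"mb": 0.5, "d": 0.8}})
        upd = self._monthly_ens({3: {"mb": 0.5, "d": 0.95}})
        rep = sk.percentage_improvement(base, upd, months=(3,))
        assert rep.mean_p["d"] == pytest.approx(75.0)

    def test_zero_baseline_month_is_flagged_and_excluded(self):
        base = self._monthly_ens({3: {"mb": 0.0}, 4: {"mb": 0.5}})
        upd = self._monthly_ens({3: {"mb": 0.1}, 4: {"mb": 0.25}})
        rep = sk.percentage_improvement(base, upd, months=(3, 4))
        assert (3, "mb", "zero or undefined baseline") in rep.excluded
        assert rep.mean_p["mb"] == pytest.approx(50.0)


class TestCorrelationAndRegression:
    def test_linear_me_vs_temperature_correlates_perfectly(self):
        frames = []
        for i, t in enumerate([8.0, 10.0, 12.0, 14.0]):
            err = 0.05 * t
            frames.append(_vt(i, 2016, 6, np.full(6, err), obs=t))
        vt = pd.concat(frames, ignore_index=True)
        out = sk.correlate_group_summaries(vt, "node")
        row = out[(out["predictor"] == "mean_obs") & (out["metric"] == "me")]
        assert row["r"].iloc[0] == pytest.approx(1.0)

    def test_relabelling_groups_leaves_correlations_unchanged(self):
        rng = np.random.default_rng(11)
        frames = [_vt(i, 2016, 6, rng.normal(0.3, 0.2, 10), obs=rng.uniform(8, 14))
                  for i in range(6)]
        vt = pd.concat(frames, ignore_index=True)
        out1 = sk.correlate_group_summaries(vt, "node")
        relabel = {i: 100 - i for i in range(6)}
        vt2 = vt.assign(node_id=vt["node_id"].map(relabel))
        out2 = sk.correlate_group_summaries(vt2, "node")
        np.testing.assert_allclose(out1["r"], out2["r"])

    def test_correlations_match_two_pass_oracle(self):
        rng = np.random.default_rng(12)
        frames = [_vt(i, 2016, 6, rng.normal(0.3, 0.2, rng.integers(5, 25)),
                      obs=rng.uniform(8, 14)) for i in range(20)]
        vt = pd.concat(frames, ignore_index=True)
        out = sk.correlate_group_summaries(vt, "node")
        # independent two-pass Pearson on (n, ME) pairs
        stats = vt.groupby("node_id").apply(
            lambda g: pd.Series({"n": len(g),
                                 "me": (g["mod_temp"] - g["obs_temp"]).abs().mean()}),
            include_groups=False)
        x, y = stats["n"].values, stats["me"].values
        r_oracle = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        row = out[(out["predictor"] == "n") & (out["metric"] == "me")]
        assert row["r"].iloc[0] == pytest.approx(r_oracle)

    def test_too_few_groups_errors(self):
        vt = pd.concat([_vt(1, 2016, 6, np.zeros(5)), _vt(2, 2016, 6, np.ones(5))],
                       ignore_index=True)
        with pytest.raises(ValueError):
            sk.correlate_group_summaries(vt, "node")

    def test_regression_recovers_exact_linear_scores(self):
        per_node = pd.DataFrame(
            {"node_id": [1, 2, 3, 4],
             "me": [0.5, 1.0, 1.5, 2.0], "mb": [0.3, 0.3, 0.3, 0.3]}
        )
        depths = {1: 50.0, 2: 100.0, 3: 150.0, 4: 200.0}
        fit = sk.regress_scores_on_depth(per_node, depths).set_index("metric")
        assert fit.loc["me", "slope"] == pytest.approx(0.01)
        assert fit.loc["me", "intercept"] == pytest.approx(0.0)
        assert fit.loc["mb", "slope"] == pytest.approx(0.0)

    def test_regression_matches_normal_equations(self):
        rng = np.random.default_rng(13)
        per_node = pd.DataFrame({"node_id": np.arange(10),
                                 "me": rng.normal(0.5, 0.2, 10)})
        depths = dict(zip(range(10), rng.uniform(20, 250, 10)))
        fit = sk.regress_scores_on_depth(per_node, depths).set_index("metric")
        x = np.array([depths[i] for i in range(10)])
        A = np.column_stack([x, np.ones(10)])
        beta = np.linalg.lstsq(A, per_node["me"].values, rcond=None)[0]
        assert fit.loc["me", "slope"] == pytest.approx(beta[0])
        assert fit.loc["me", "intercept"] == pytest.approx(beta[1])

    def test_constant_depth_errors(self):
        per_node = pd.DataFrame({"node_id": [1, 2, 3], "me": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="constant"):
            sk.regress_scores_on_depth(per_node, {1: 50.0, 2: 50.0, 3: 50.0})
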