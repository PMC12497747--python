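"""Group-level aggregation, Fisher exact test, and the mixed ANOVA."""

import numpy as np
import pandas as pd
import pytest

from monoconn.errors import SchemaError
from monoconn.group_stats import (
    aspl_anova,
    edge_weight_summary,
    group_average_trajectories,
    monotonic_proportion_test,
    node_trend_screen,
    trend_results_frame,
)
from monoconn.monotonicity import TrajectorySeries

from oracles import fisher_exact_two_sided


def bcro_table(records):
    return pd.DataFrame(
        records,
        columns=["participant", "group", "condition", "iteration", "node", "bc_ro"],
    )


class TestGroupAverageTrajectories:
    def test_single_participant_identity(self):
        records = [("p1", "control", "A", it, 0, float(it)) for it in range(1, 9)]
        trajs = group_average_trajectories(bcro_table(records), "control")
        np.testing.assert_array_equal(trajs[(0, "A")].values, np.arange(1, 9.0))

    def test_two_participants_average(self):
        records = []
        for pid, rank in [("p1", 10.0), ("p2", 20.0)]:
            records += [(pid, "control", "A", it, 0, rank) for it in range(1, 9)]
        trajs = group_average_trajectories(bcro_table(records), "control")
        np.testing.assert_array_equal(trajs[(0, "A")].values, np.full(8, 15.0))

    def test_matches_column_mean_oracle(self, rng):
        records = []
        values = rng.uniform(1, 20, size=(5, 8))
        for p in range(5):
            for it in range(1, 9):
                records.append((f"p{p}", "control", "A", it, 0, values[p, it - 1]))
        trajs = group_average_trajectories(bcro_table(records), "control")
        np.testing.assert_allclose(trajs[(0, "A")].values, values.mean(axis=0))

    def test_mismatched_node_sets_rejected(self):
        records = [("p1", "control", "A", 1, 0, 1.0), ("p2", "control", "A", 1, 1, 1.0)]
        with pytest.raises(SchemaError, match="node set"):
            group_average_trajectories(bcro_table(records), "control")


class TestNodeTrendScreen:
    def test_strictly_increasing_trajectory_flagged(self):
        trajs = {
            (0, "A"): TrajectorySeries(np.arange(1, 9.0), ids={"group": "control"}),
            (1, "A"): TrajectorySeries(
                np.array([4, 1, 5, 2, 6, 3, 5, 4.0]), ids={"group": "control"}
            ),
        }
        results = {r.node: r for r in node_trend_screen(trajs)}
        assert results[0].significant and results[0].direction == "increasing"
        assert results[0].rho == pytest.approx(1.0)
        assert not results[1].significant and results[1].direction == "none"

    def test_fdr_is_more_conservative(self, rng):
        trajs = {
            (i, "A"): TrajectorySeries(rng.normal(size=8), ids={"group": "g"})
            for i in range(40)
        }
        trajs[(99, "A")] = TrajectorySeries(np.arange(8.0), ids={"group": "g"})
        raw = trend_results_frame(node_trend_screen(trajs, alpha=0.05))
        fdr = trend_results_frame(node_trend_screen(trajs, alpha=0.05, fdr=True))
        assert fdr["significant"].sum() <= raw["significant"].sum()
        assert fdr.loc[fdr.node == 99, "significant"].iloc[0]


class TestMonotonicProportionTest:
    def test_identical_proportions_p_one(self):
        _, p = monotonic_proportion_test(10, 20, 10, 20)
        assert p == pytest.approx(1.0)

    def test_point_mass_extreme_table(self):
        # table (5,0 / 0,5): two extreme tables of 252 -> p = 1/126
        _, p = monotonic_proportion_test(5, 5, 0, 5)
        assert p == pytest.approx(1 / 126)

    def test_matches_enumeration_oracle(self):
        for k1, n1, k2, n2 in [(35, 39, 29, 49), (12, 20, 5, 18), (3, 9, 7, 9)]:
            _, p = monotonic_proportion_test(k1, n1, k2, n2)
            assert p == pytest.approx(
                fisher_exact_two_sided(k1, n1 - k1, k2, n2 - k2), rel=1e-9
            )

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            monotonic_proportion_test(0, 0, 1, 2)


def simulate_aspl_long(rng, n_control, n_patient, n_cond=4, n_iter=8,
                       group_effect=0.0, time_slope=0.0, noise=0.3, subj_sd=0.5):
    rows = []
    for g, n in [("control", n_control), ("patient", n_patient)]:
        for s in range(n):
            pid = f"{g[0]}{s}"
            subj = rng.normal(0, subj_sd)
            for ci in range(n_cond):
                for t in range(1, n_iter + 1):
                    y = (10 + (group_effect if g == "patient" else 0)
                         + 0.1 * ci + time_slope * t + subj + rng.normal(0, noise))
                    rows.append((pid, g, f"c{ci}", t, y))
    return pd.DataFrame(
        rows, columns=["participant", "group", "condition", "iteration", "aspl"]
    )


class TestAsplAnova:
    def test_df_shapes_at_published_design(self, rng):
        """Two groups of 39 and 49, 4 conditions x 8 iterations: Time is
        tested on (7, 602) and Group on (1, 86) degrees of freedom."""
        long = simulate_aspl_long(rng, 39, 49)
        tab = aspl_anova(long)
        time_row = tab.effect("Time")
        group_row = tab.effect("Group")
        assert (time_row["df_num"], time_row["df_den"]) == (7, 602)
        assert (group_row["df_num"], group_row["df_den"]) == (1, 86)

    def test_matches_r_aov_oracle(self):
        """Frozen oracle: R `aov(aspl ~ group*condition*iteration +
        Error(participant/(condition*iteration)))` on this exact dataset
        (7 subjects, unequal groups 3/4, 3 conditions x 4 iterations)."""
        rng = np.random.default_rng(42)
        rows = []
        for g, ns in [("control", 3), ("patient", 4)]:
            for s in range(ns):
                pid = f"{g[0]}{s}"
                subj = rng.normal(0, 0.5)
                for ci, c in enumerate(["A", "B", "C"]):
                    for t in range(1, 5):
                        y = (10 + (0.8 if g == "patient" else 0) + 0.1 * ci
                             + 0.05 * t + subj + rng.normal(0, 0.3))
                        rows.append((pid, g, c, t, y))
        long = pd.DataFrame(
            rows, columns=["participant", "group", "condition", "iteration", "aspl"]
        )
        tab = aspl_anova(long)
        expected_F = {
            "Group": 2.653,
            "Condition": 12.222,
            "Group x Condition": 0.744,
            "Time": 0.852,
            "Group x Time": 0.177,
            "Condition x Time": 0.403,
            "Group x Condition x Time": 1.262,
        }
        for effect, F in expected_F.items():
            assert tab.effect(effect)["F"] == pytest.approx(F, abs=6e-4), effect
        assert tab.effect("Condition")["p"] == pytest.approx(0.00206, abs=5e-6)

    def test_constant_response_reports_zero_variance(self):
        rng = np.random.default_rng(0)
        long = simulate_aspl_long(rng, 3, 3, noise=0.0, subj_sd=0.0)
        long["aspl"] = 1.0
        tab = aspl_anova(long)
        assert tab.zero_variance
        assert np.isnan(tab.effect("Time")["F"])

    def test_unbalanced_design_rejected(self, rng):
        long = simulate_aspl_long(rng, 3, 3).iloc[:-1]
        with pytest.raises(SchemaError, match="unbalanced"):
            aspl_anova(long)

    def test_group_offset_detected_time_near_null(self, rng):
        """Additive group offset, no time effect: Group F is large, Time F
        hovers near its null expectation of ~1 across simulations."""
        group_ps, time_fs = [], []
        for _ in range(20):
            long = simulate_aspl_long(rng, 8, 8, group_effect=1.0, subj_sd=0.2)
            tab = aspl_anova(long)
            group_ps.append(tab.effect("Group")["p"])
            time_fs.append(tab.effect("Time")["F"])
        assert np.median(group_ps) < 1e-4
        assert 0.6 < np.mean(time_fs) < 1.6


class TestEdgeWeightSummary:
    def test_identical_groups_identical_summaries(self, rng):
        z = rng.normal(size=300)
        tbl = pd.DataFrame({
            "group": ["control"] * 300 + ["patient"] * 300,
            "condition": "A",
            "z": np.concatenate([z, z]),
        })
        out = edge_weight_summary(tbl, condition="A").set_index("group")
        pd.testing.assert_series_equal(
            out.loc["control"], out.loc["patient"], check_names=False
        )

    def test_single_graph_matches_direct_statistics(self, rng):
        from monoconn.connectivity import compute_ufc

        g = compute_ufc(rng.normal(size=(10, 9)))
        z = g.edge_values()
        tbl = pd.DataFrame({"group": "control", "condition": "A", "z": z})
        row = edge_weight_summary(tbl, condition="A").iloc[0]
        assert row["n"] == 45
        assert row["mean"] == pytest.approx(z.mean())
        assert row["sd"] == pytest.approx(z.std(ddof=1))
        assert row["q50"] == pytest.approx(np.median(z))

    def test_patient_coupling_offset_shifts_left_over_seeds(self):
        """Reduced patient coupling lowers pooled Fisher-Z edge weights in
        every one of 20 replicate mini-cohorts."""
        from monoconn.connectivity import compute_ufc
        from monoconn.epochs import ParcellatedTimeSeries, segment
        from monoconn.synthetic import SynthConfig, generate_participant_timeseries

        shifts = []
        for seed in range(20):
            cfg = SynthConfig(n_regions=8, group_coupling_offset=0.15, seed=seed)
            design = cfg.design()
            means = {}
            for group in ("control", "patient"):
                zs = []
                for k in range(2):
                    ts = generate_participant_timeseries(cfg, group, 1000 * seed + k)
                    for win in segment(
                        ParcellatedTimeSeries(ts.matrix), design
                    ).values():
                        zs.append(compute_ufc(win).edge_values())
                means[group] = np.concatenate(zs).mean()
            shifts.append(means["patient"] - means["control"])
        assert (np.array(shifts) < 0).all()
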