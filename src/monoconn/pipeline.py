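"""End-to-end cohort analysis: epochs -> connectivity -> graph metrics ->
monotonicity -> group statistics.

The participant-level monotonicity table uses the violation-count classifier
(cheap, one verdict per node x condition trajectory); the group-level screen
uses the exact-permutation Spearman test on group-averaged BC_RO
trajectories. Behavioral monotonicity is classified on each participant's
proportion-correct trajectory and compared between groups with Fisher's
exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from monoconn.connectivity import compute_ufc
from monoconn.epochs import EpochDesign, epoch_mean_psc, percent_signal_change, segment
from monoconn.graph_metrics import aspl, betweenness
from monoconn.group_stats import (
    AnovaTable,
    aspl_anova,
    edge_weight_summary,
    group_average_trajectories,
    monotonic_proportion_test,
    node_trend_screen,
    trend_results_frame,
)
from monoconn.monotonicity import TrajectorySeries, classify
from monoconn.synthetic import GROUPS, Cohort


@dataclass
class CohortResults:
    bc_ro: pd.DataFrame          # participant, group, condition, iteration, node, bc, bc_ro
    aspl: pd.DataFrame           # participant, group, condition, iteration, aspl
    edges: pd.DataFrame          # group, condition, z (pooled unique edges)
    behavior: pd.DataFrame       # participant, group, iteration, proportion_correct
    participant_verdicts: pd.DataFrame
    group_trends: pd.DataFrame
    anova: AnovaTable | None
    behavior_monotone: pd.DataFrame  # participant, group, direction, monotone
    fisher: dict | None
    edge_summaries: dict[str, pd.DataFrame] = field(default_factory=dict)
    psc_verdicts: pd.DataFrame | None = None


def participant_graph_metrics(
    ts_matrix: np.ndarray,
    design: EpochDesign,
    participant_id: str = "",
    group: str = "",
    lag_volumes: int = 0,
    policy: str = "exclude_nonpositive",
    collect_edges: bool = True,
):
    """Per-epoch BC/BC_RO, ASPL and (optionally) pooled edge weights."""
    from monoconn.epochs import ParcellatedTimeSeries

    ts = ParcellatedTimeSeries(ts_matrix, participant_id=participant_id, group=group)
    windows = segment(ts, design, lag_volumes=lag_volumes)
    bc_rows, aspl_rows, edge_frames = [], [], []
    for (cond, it), win in windows.items():
        g = compute_ufc(win, condition=cond, iteration=it, participant_id=participant_id)
        prof = betweenness(g, policy=policy)
        for node in range(g.n_nodes):
            bc_rows.append(
                (participant_id, group, cond, it, node,
                 prof.bc[node], prof.bc_ro[node])
            )
        aspl_rows.append((participant_id, group, cond, it, aspl(g, policy=policy)))
        if collect_edges:
            edge_frames.append(
                pd.DataFrame({"group": group, "condition": cond, "z": g.edge_values()})
            )
    bc_df = pd.DataFrame(
        bc_rows,
        columns=["participant", "group", "condition", "iteration", "node", "bc", "bc_ro"],
    )
    aspl_df = pd.DataFrame(
        aspl_rows, columns=["participant", "group", "condition", "iteration", "aspl"]
    )
    edges = pd.concat(edge_frames, ignore_index=True) if edge_frames else pd.DataFrame(
        columns=["group", "condition", "z"]
    )
    return bc_df, aspl_df, edges


def _participant_bcro_verdicts(bc_df: pd.DataFrame, max_violations: int) -> pd.DataFrame:
    rows = []
    for (pid, group, cond, node), sub in bc_df.groupby(
        ["participant", "group", "condition", "node"]
    ):
        series = sub.sort_values("iteration")["bc_ro"].to_numpy()
        v = classify(series, max_violations=max_violations)
        rows.append(
            {"scope": "participant", "metric": "bc_ro", "participant": pid,
             "group": group, "condition": cond, "node": node,
             "direction": v.direction, "n_violations": v.n_violations,
             "strict": v.strict_flag}
        )
    return pd.DataFrame(rows)


def analyze_cohort(
    cohort: Cohort,
    lag_volumes: int = 0,
    policy: str = "exclude_nonpositive",
    max_violations: int = 1,
    alpha: float = 0.05,
    collect_edges: bool = True,
    psc_trajectories: bool = False,
) -> CohortResults:
    """Run the full analysis on an in-memory cohort."""
    from monoconn.synthetic import config_from_dict

    cfg = config_from_dict(cohort.manifest["config"])
    design = cohort.design if cohort.design is not None else cfg.design()
    bc_parts, aspl_parts, edge_parts, beh_rows, psc_rows = [], [], [], [], []
    for p in cohort.participants:
        bc_df, aspl_df, edges = participant_graph_metrics(
            p.timeseries.matrix, design,
            participant_id=p.participant_id, group=p.group,
            lag_volumes=lag_volumes, policy=policy, collect_edges=collect_edges,
        )
        bc_parts.append(bc_df)
        aspl_parts.append(aspl_df)
        if collect_edges:
            edge_parts.append(edges)
        for it, prop in enumerate(p.behavior.proportion_correct, start=1):
            beh_rows.append((p.participant_id, p.group, it, prop))
        if psc_trajectories:
            psc = percent_signal_change(p.timeseries)
            tra = epoch_mean_psc(psc, design, lag_volumes=lag_volumes)
            tra.insert(0, "participant", p.participant_id)
            tra.insert(1, "group", p.group)
            psc_rows.append(tra)
    bc_all = pd.concat(bc_parts, ignore_index=True)
    aspl_all = pd.concat(aspl_parts, ignore_index=True)
    edges_all = (
        pd.concat(edge_parts, ignore_index=True)
        if edge_parts else pd.DataFrame(columns=["group", "condition", "z"])
    )
    behavior = pd.DataFrame(
        beh_rows, columns=["participant", "group", "iteration", "proportion_correct"]
    )

    participant_verdicts = _participant_bcro_verdicts(bc_all, max_violations)

    trend_frames = []
    for group in GROUPS:
        if (bc_all["group"] == group).any():
            trajs = group_average_trajectories(bc_all, group)
            trend_frames.append(trend_results_frame(node_trend_screen(trajs, alpha=alpha)))
    group_trends = (
        pd.concat(trend_frames, ignore_index=True) if trend_frames else pd.DataFrame()
    )

    groups_present = sorted(aspl_all["group"].unique())
    anova = aspl_anova(aspl_all) if len(groups_present) > 1 else None

    beh_rows2 = []
    for (pid, group), sub in behavior.groupby(["participant", "group"]):
        series = sub.sort_values("iteration")["proportion_correct"].to_numpy()
        v = classify(series, max_violations=max_violations)
        beh_rows2.append(
            {"participant": pid, "group": group, "direction": v.direction,
             "n_violations": v.n_violations,
             "monotone": v.direction == "increasing"}
        )
    behavior_monotone = pd.DataFrame(beh_rows2)

    fisher = None
    if len(groups_present) > 1:
        counts = behavior_monotone.groupby("group")["monotone"].agg(["sum", "count"])
        orr, p = monotonic_proportion_test(
            int(counts.loc["control", "sum"]), int(counts.loc["control", "count"]),
            int(counts.loc["patient", "sum"]), int(counts.loc["patient", "count"]),
        )
        fisher = {
            "k_control": int(counts.loc["control", "sum"]),
            "n_control": int(counts.loc["control", "count"]),
            "k_patient": int(counts.loc["patient", "sum"]),
            "n_patient": int(counts.loc["patient", "count"]),
            "odds_ratio": orr, "p_two_sided": p,
        }

    edge_summaries = {}
    if collect_edges and not edges_all.empty:
        for cond in cfg.conditions:
            edge_summaries[cond] = edge_weight_summary(edges_all, condition=cond)

    psc_verdicts = None
    if psc_trajectories and psc_rows:
        psc_all = pd.concat(psc_rows, ignore_index=True)
        rows = []
        for (pid, group, region, cond), sub in psc_all.groupby(
            ["participant", "group", "region", "condition"]
        ):
            series = sub.sort_values("iteration")["mean_psc"].to_numpy()
            v = classify(series, max_violations=max_violations)
            rows.append(
                {"scope": "participant", "metric": "psc", "participant": pid,
                 "group": group, "condition": cond, "node": region,
                 "direction": v.direction, "n_violations": v.n_violations,
                 "strict": v.strict_flag}
            )
        psc_verdicts = pd.DataFrame(rows)

    return CohortResults(
        bc_ro=bc_all, aspl=aspl_all, edges=edges_all, behavior=behavior,
        participant_verdicts=participant_verdicts, group_trends=group_trends,
        anova=anova, behavior_monotone=behavior_monotone, fisher=fisher,
        edge_summaries=edge_summaries, psc_verdicts=psc_verdicts,
    )
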