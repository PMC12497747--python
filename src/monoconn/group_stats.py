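"""Group-level aggregation and inference.

Covers: averaging per-participant node-rank (BC_RO) trajectories within each
group, screening every node x condition for a monotone trend with the exact
Spearman test, comparing behavioral monotone proportions between groups with
Fisher's exact test, the three-way mixed ANOVA on network efficiency (ASPL),
and pooled edge-weight distribution summaries.

The mixed ANOVA treats Group as a between-subject factor and Condition and
Time (task iteration) as within-subject factors, using the classical
univariate split-plot sums of squares with no sphericity correction: each
within stratum is decomposed after projecting out subject means, and every
within effect is tested against its own effect-by-subject(group) error
stratum. With two groups totalling N participants, 4 conditions and 8
iterations this yields df (7, 7*(N-2)) for Time and (1, N-2) for Group —
(7, 602) and (1, 86) at N = 88.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from monoconn.errors import SchemaError
from monoconn.monotonicity import TrajectorySeries, spearman_trend

BCRO_COLUMNS = ("participant", "group", "condition", "iteration", "node", "bc_ro")


@dataclass
class GroupTrendResult:
    node: int
    condition: str
    group: str
    trajectory: np.ndarray
    rho: float
    p_exact: float
    significant: bool
    direction: str  # sign of rho when significant, else "none"


def group_average_trajectories(
    bc_ro_table: pd.DataFrame, group: str
) -> dict[tuple[int, str], TrajectorySeries]:
    """Average BC_RO across a group's participants per (node, condition).

    ``bc_ro_table`` is long-format with columns participant, group,
    condition, iteration, node, bc_ro. Ranks are averaged directly (the
    group-mean rank trajectory), not re-ranked.
    """
    missing = set(BCRO_COLUMNS) - set(bc_ro_table.columns)
    if missing:
        raise SchemaError(f"BC_RO table lacks columns {sorted(missing)}")
    sub = bc_ro_table[bc_ro_table["group"] == group]
    if sub.empty:
        raise SchemaError(f"no participants with group {group!r}")
    per_participant = sub.groupby("participant")["node"].agg(frozenset)
    if per_participant.nunique() != 1:
        raise SchemaError("participants do not share a common node set")
    iters = sorted(sub["iteration"].unique())
    out: dict[tuple[int, str], TrajectorySeries] = {}
    means = (
        sub.groupby(["node", "condition", "iteration"])["bc_ro"]
        .mean()
        .unstack("iteration")
        .reindex(columns=iters)
    )
    for (node, condition), row in means.iterrows():
        out[(int(node), condition)] = TrajectorySeries(
            row.to_numpy(float),
            metric="bc_ro",
            ids={"node": int(node), "condition": condition, "group": group},
        )
    return out


def node_trend_screen(
    trajectories: dict[tuple[int, str], TrajectorySeries],
    alpha: float = 0.05,
    fdr: bool = False,
) -> list[GroupTrendResult]:
    """Exact Spearman trend test per (node, condition) group trajectory.

    Significance is uncorrected p < alpha by default (the screening
    convention for this analysis); ``fdr=True`` applies Benjamini-Hochberg
    across the screened trajectories instead.
    """
    raw: list[tuple[tuple[int, str], TrajectorySeries, float, float]] = []
    for key, series in trajectories.items():
        rho, p = spearman_trend(series)
        raw.append((key, series, rho, p))
    if fdr and raw:
        ps = np.array([p for *_rest, p in raw])
        m = len(ps)
        order = np.argsort(ps)
        passed = np.zeros(m, dtype=bool)
        thresh = alpha * (np.arange(1, m + 1)) / m
        below = ps[order] <= thresh
        if below.any():
            k = np.max(np.nonzero(below)[0])
            passed[order[: k + 1]] = True
        sig_flags = passed
    else:
        sig_flags = np.array([p < alpha for *_rest, p in raw], dtype=bool)
    results = []
    for ((node, condition), series, rho, p), sig in zip(raw, sig_flags):
        direction = (
            ("increasing" if rho > 0 else "decreasing") if sig else "none"
        )
        results.append(
            GroupTrendResult(
                node=node,
                condition=condition,
                group=series.ids.get("group", ""),
                trajectory=series.values,
                rho=rho,
                p_exact=p,
                significant=bool(sig),
                direction=direction,
            )
        )
    return results


def trend_results_frame(results: list[GroupTrendResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "node": r.node,
                "condition": r.condition,
                "group": r.group,
                "rho": r.rho,
                "p_exact": r.p_exact,
                "significant": r.significant,
                "direction": r.direction,
            }
            for r in results
        ]
    )


def monotonic_proportion_test(
    k_control: int, n_control: int, k_patient: int, n_patient: int
) -> tuple[float, float]:
    """Fisher's exact test comparing monotone-performer proportions.

    Returns (odds_ratio, two_sided_p) for the 2x2 table of monotone vs
    non-monotone counts per group.
    """
    if n_control <= 0 or n_patient <= 0:
        raise ValueError("each group must contain at least one participant")
    if not 0 <= k_control <= n_control or not 0 <= k_patient <= n_patient:
        raise ValueError("monotone counts must satisfy 0 <= k <= n")
    table = [
        [k_control, n_control - k_control],
        [k_patient, n_patient - k_patient],
    ]
    res = stats.fisher_exact(table, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


@dataclass
class AnovaTable:
    """Mixed-ANOVA effect table with an explicit zero-variance flag."""

    table: pd.DataFrame
    zero_variance: bool = False

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if rows.empty:
            raise KeyError(name)
        return rows.iloc[0]


def aspl_anova(long: pd.DataFrame) -> AnovaTable:
    """Three-way mixed ANOVA of ASPL: Group x Condition x Time.

    ``long`` needs columns participant, group, condition, iteration, aspl,
    with every participant observed in every (condition, iteration) cell
    exactly once (unbalanced within-subject designs are rejected; group
    sizes may differ). Sums of squares follow the classical split-plot
    decomposition; no sphericity correction is applied.
    """
    required = {"participant", "group", "condition", "iteration", "aspl"}
    missing = required - set(long.columns)
    if missing:
        raise SchemaError(f"ASPL table lacks columns {sorted(missing)}")
    conditions = sorted(long["condition"].unique())
    iterations = sorted(long["iteration"].unique())
    C, T = len(conditions), len(iterations)
    counts = long.groupby(["participant", "condition", "iteration"]).size()
    if (counts != 1).any() or counts.groupby("participant").size().nunique() != 1 or (
        counts.groupby("participant").size().iloc[0] != C * T
    ):
        raise SchemaError(
            "unbalanced design: every participant needs exactly one observation "
            "per (condition, iteration) cell"
        )
    group_of = long.groupby("participant")["group"].agg(
        lambda s: s.unique()[0] if s.nunique() == 1 else None
    )
    if group_of.isna().any() or group_of.eq(None).any():
        raise SchemaError("each participant must belong to exactly one group")
    groups = sorted(long["group"].unique())
    g = len(groups)
    N = group_of.size
    if N <= g:
        raise SchemaError("need more participants than groups")

    # cube y[subject, condition, time] plus subject -> group mapping
    pivot = long.pivot_table(
        index="participant", columns=["condition", "iteration"], values="aspl"
    )
    cols = pd.MultiIndex.from_product([conditions, iterations])
    y = pivot.reindex(columns=cols).to_numpy(float).reshape(N, C, T)
    grp_idx = np.array([groups.index(group_of[p]) for p in pivot.index])
    n_i = np.array([(grp_idx == i).sum() for i in range(g)])

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))                       # subject means
    m_g = np.array([m_s[grp_idx == i].mean() for i in range(g)])

    ss_group = C * T * float((n_i * (m_g - grand) ** 2).sum())
    ss_subj = C * T * float(((m_s - m_g[grp_idx]) ** 2).sum())

    def within_one(axis_means: np.ndarray, n_levels: int, mult: int):
        """Decompose one within-factor stratum from subject-centered profiles."""
        d = axis_means - m_s[:, None]               # N x levels, rows sum to 0
        d_all = d.mean(axis=0)
        d_grp = np.stack([d[grp_idx == i].mean(axis=0) for i in range(g)])
        ss_main = mult * N * float((d_all**2).sum())
        ss_int = mult * float((n_i[:, None] * (d_grp - d_all) ** 2).sum())
        ss_err = mult * float(((d - d_grp[grp_idx]) ** 2).sum())
        return ss_main, ss_int, ss_err

    ss_cond, ss_gc, ss_cs = within_one(y.mean(axis=2), C, T)
    ss_time, ss_gt, ss_ts = within_one(y.mean(axis=1), T, C)

    # condition-by-time stratum: remove subject, subject-condition, subject-time
    e = y - y.mean(axis=2, keepdims=True) - y.mean(axis=1, keepdims=True) + m_s[:, None, None]
    e_all = e.mean(axis=0)
    e_grp = np.stack([e[grp_idx == i].mean(axis=0) for i in range(g)])
    ss_ct = N * float((e_all**2).sum())
    ss_gct = float((n_i[:, None, None] * (e_grp - e_all) ** 2).sum())
    ss_cts = float(((e - e_grp[grp_idx]) ** 2).sum())

    rows = []
    zero_var = False

    def add(effect, ss, df, ss_err, df_err, err_name):
        nonlocal zero_var
        ms = ss / df
        ms_err = ss_err / df_err
        if ms_err == 0:
            zero_var = True
            F = p = np.nan
        else:
            F = ms / ms_err
            p = float(stats.f.sf(F, df, df_err))
        rows.append(
            {"effect": effect, "df_num": df, "df_den": df_err,
             "ss": ss, "F": F, "p": p, "error_stratum": err_name}
        )

    add("Group", ss_group, g - 1, ss_subj, N - g, "Subject(Group)")
    add("Condition", ss_cond, C - 1, ss_cs, (C - 1) * (N - g), "Condition x Subject(Group)")
    add("Group x Condition", ss_gc, (g - 1) * (C - 1), ss_cs, (C - 1) * (N - g),
        "Condition x Subject(Group)")
    add("Time", ss_time, T - 1, ss_ts, (T - 1) * (N - g), "Time x Subject(Group)")
    add("Group x Time", ss_gt, (g - 1) * (T - 1), ss_ts, (T - 1) * (N - g),
        "Time x Subject(Group)")
    add("Condition x Time", ss_ct, (C - 1) * (T - 1), ss_cts,
        (C - 1) * (T - 1) * (N - g), "Condition x Time x Subject(Group)")
    add("Group x Condition x Time", ss_gct, (g - 1) * (C - 1) * (T - 1), ss_cts,
        (C - 1) * (T - 1) * (N - g), "Condition x Time x Subject(Group)")
    return AnovaTable(pd.DataFrame(rows), zero_variance=zero_var)


def edge_weight_summary(
    edge_table: pd.DataFrame,
    condition: str | None = None,
    deciles: tuple[float, ...] = tuple(np.arange(0.1, 1.0, 0.1)),
    ecdf_points: int = 101,
) -> pd.DataFrame:
    """Pooled per-group Fisher-Z edge-weight distribution summary.

    ``edge_table`` is long-format with columns group, condition, z (one row
    per unique edge per epoch graph, pooled across participants and
    iterations). Returns one row per group with mean, sd, n and deciles; the
    attached ``attrs['ecdf_grid']`` holds a shared grid and per-group ECDF
    values for distribution-shift plots.
    """
    required = {"group", "condition", "z"}
    missing = required - set(edge_table.columns)
    if missing:
        raise SchemaError(f"edge table lacks columns {sorted(missing)}")
    sub = edge_table if condition is None else edge_table[
        edge_table["condition"] == condition
    ]
    if sub.empty:
        raise SchemaError(f"no edges for condition {condition!r}")
    grid = np.linspace(sub["z"].min(), sub["z"].max(), ecdf_points)
    rows = []
    ecdfs = {}
    for group, vals in sub.groupby("group")["z"]:
        v = vals.to_numpy(float)
        row = {"group": group, "n": len(v), "mean": v.mean(), "sd": v.std(ddof=1)}
        for q in deciles:
            row[f"q{int(round(q * 100)):02d}"] = float(np.quantile(v, q))
        rows.append(row)
        ecdfs[group] = np.searchsorted(np.sort(v), grid, side="right") / len(v)
    out = pd.DataFrame(rows)
    out.attrs["ecdf_grid"] = {"z": grid, **ecdfs}
    return out
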