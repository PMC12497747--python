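"""Weak-monotonicity classification and exact-permutation Spearman trend test
for short (8-point) trajectories.

Weak monotonicity of a series D_1..D_T holds when

    (a) D_1 <= D_2 <= ... <= D_T   or   (b) D_1 >= D_2 >= ... >= D_T,

with unequal endpoints (D_1 != D_T). The classifier additionally supports a
liberal variant permitting up to ``max_violations`` adjacent-step violations
of the trend (default 1); e.g. D1<=D2<=D3 > D4<=D5<=...<=D8 is still
classified increasing. A "violation" is one adjacent pair strictly ordered
against the trend, regardless of magnitude; adjacent ties violate neither
direction. For the relaxed rule we also require the endpoints to agree with
the claimed direction (D_T > D_1 for increasing, D_T < D_1 for decreasing),
a net-trend condition that keeps sequences like (5,1,1,1,1,1,1,6) from being
labeled by violation count alone.

The trend test is Spearman's rho between iteration number 1..T and the
values, with an EXACT two-sided permutation p-value: with T = 8 the full
8! = 40,320 orderings of the observed values are enumerated, since the
large-sample t approximation is unreliable this far from asymptotia. A
perfectly monotone series gives rho = +/-1; the smallest significant
magnitude at alpha = 0.05 (two-sided, distinct values, T = 8) is
|rho| = 31/42 ~= 0.738.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal

import numpy as np
from scipy.stats import rankdata

_TIE_EPS = 1e-12  # relative tolerance when comparing permuted |rho| to observed


@dataclass
class TrajectorySeries:
    """An ordered trajectory of one metric across task iterations."""

    values: np.ndarray
    metric: str = ""
    ids: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    def __len__(self) -> int:
        return len(self.values)

    def reversed(self) -> "TrajectorySeries":
        return TrajectorySeries(self.values[::-1], metric=self.metric, ids=self.ids)


@dataclass
class MonotonicityVerdict:
    direction: Literal["increasing", "decreasing", "none"]
    n_violations: int
    strict_flag: bool  # zero-violation weak monotonicity also satisfied


def classify(
    series: TrajectorySeries | np.ndarray, max_violations: int = 1
) -> MonotonicityVerdict:
    """Classify a trajectory as weakly increasing, decreasing, or neither.

    Direction requires (i) at most ``max_violations`` adjacent steps strictly
    against the trend and (ii) endpoints strictly ordered in the trend's
    direction. When both directions qualify (possible only with
    max_violations high relative to the length), the endpoint sign decides.
    """
    values = series.values if isinstance(series, TrajectorySeries) else np.asarray(
        series, dtype=float
    ).ravel()
    if len(values) < 2:
        raise ValueError("monotonicity needs a series of length >= 2")
    diffs = np.diff(values)
    viol_inc = int((diffs < 0).sum())  # steps down break an increasing trend
    viol_dec = int((diffs > 0).sum())
    net = values[-1] - values[0]
    # the endpoint sign makes the two candidacies mutually exclusive
    inc_ok = viol_inc <= max_violations and net > 0
    dec_ok = viol_dec <= max_violations and net < 0
    if inc_ok:
        return MonotonicityVerdict("increasing", viol_inc, strict_flag=viol_inc == 0)
    if dec_ok:
        return MonotonicityVerdict("decreasing", viol_dec, strict_flag=viol_dec == 0)
    return MonotonicityVerdict("none", int(min(viol_inc, viol_dec)), strict_flag=False)


@lru_cache(maxsize=4)
def _permutation_indices(n: int) -> np.ndarray:
    """All n! permutations of 0..n-1 as an (n!, n) int8 array (n <= 10)."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def _rho_against_time(ranked: np.ndarray) -> float:
    """Pearson correlation of a rank vector against time 1..n."""
    n = len(ranked)
    t = np.arange(1, n + 1, dtype=float)
    tc = t - t.mean()
    rc = ranked - ranked.mean()
    denom = np.sqrt((rc**2).sum() * (tc**2).sum())
    return float((rc * tc).sum() / denom)


def spearman_trend(series: TrajectorySeries | np.ndarray) -> tuple[float, float]:
    """Spearman's rho of the series against iteration number, with exact p.

    Values are average-ranked (ties allowed as long as not all values are
    equal); the two-sided p-value is the fraction of all n! orderings of the
    observed values whose |rho| is at least |rho_observed| (within a 1e-12
    relative tolerance so float round-off cannot split exact ties). Requires
    series length <= 10; an all-tied series has undefined rho and raises.
    """
    values = series.values if isinstance(series, TrajectorySeries) else np.asarray(
        series, dtype=float
    ).ravel()
    n = len(values)
    if n < 3:
        raise ValueError("trend test needs a series of length >= 3")
    if n > 10:
        raise ValueError(f"exact permutation enumeration supports length <= 10, got {n}")
    if np.all(values == values[0]):
        raise ValueError("all values tied: Spearman's rho is undefined")
    ranked = rankdata(values)
    rho_obs = _rho_against_time(ranked)

    t = np.arange(1, n + 1, dtype=float)
    tc = t - t.mean()
    st = np.sqrt((tc**2).sum())
    rc = ranked - ranked.mean()
    sr = np.sqrt((rc**2).sum())
    perms = _permutation_indices(n)
    n_perms = len(perms)
    threshold = abs(rho_obs) * (1.0 - _TIE_EPS)
    count = 0
    chunk = 1_000_000
    for start in range(0, n_perms, chunk):
        block = ranked[perms[start:start + chunk]]
        rhos = ((block - ranked.mean()) @ tc) / (sr * st)
        count += int((np.abs(rhos) >= threshold).sum())
    p = count / n_perms
    return rho_obs, p


def significance_threshold(n: int = 8, alpha: float = 0.05) -> float:
    """Smallest |rho| whose exact two-sided p is below ``alpha`` for distinct
    values of length ``n`` (0.738 at n = 8, alpha = 0.05)."""
    ranked = np.arange(1, n + 1, dtype=float)
    t = np.arange(1, n + 1, dtype=float)
    tc = t - t.mean()
    st = np.sqrt((tc**2).sum())
    sr = st  # distinct ranks have the same spread as time
    perms = _permutation_indices(n)
    rhos = np.abs(((ranked[perms] - ranked.mean()) @ tc) / (sr * st))
    uniq = np.unique(np.round(rhos, 12))
    n_perms = len(rhos)
    for v in uniq:
        if (rhos >= v * (1.0 - _TIE_EPS)).sum() / n_perms < alpha:
            return float(v)
    return 1.0 + 1e-9  # nothing significant at this alpha
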