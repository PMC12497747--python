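"""Epoch handling: map parcel time series onto (condition, iteration) windows.

A block-design acquisition cycles through a fixed list of task conditions
(here Encoding, Post-Encoding Rest, Retrieval, Post-Retrieval Rest) over
several iterations; each (condition, iteration) cell is one epoch of a fixed
number of volumes. This module segments a regions x volumes matrix into
those windows and computes percent-signal-change (PSC) summaries per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from monoconn.errors import DegenerateSignalError, DesignError

DEFAULT_CONDITIONS = (
    "Encoding",
    "PostEncodingRest",
    "Retrieval",
    "PostRetrievalRest",
)


@dataclass
class ParcellatedTimeSeries:
    """A regions x volumes signal matrix with participant metadata.

    Values are in arbitrary scanner units; rows are parcels (regions),
    columns are volumes in acquisition order.
    """

    matrix: np.ndarray
    participant_id: str = ""
    group: str = ""
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("time series matrix must be 2-D (regions x volumes)")
        if np.isnan(self.matrix).any():
            raise ValueError("time series matrix contains missing values")

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[1]


@dataclass
class EpochDesign:
    """Per-volume assignment of condition and iteration.

    ``table`` has columns ``volume_index`` (0-based), ``condition`` and
    ``iteration`` (1-based). Every volume is assigned exactly once and every
    (condition, iteration) cell holds the same number of volumes.
    """

    table: pd.DataFrame
    conditions: tuple[str, ...] = field(default=DEFAULT_CONDITIONS)

    def __post_init__(self) -> None:
        required = {"volume_index", "condition", "iteration"}
        if not required.issubset(self.table.columns):
            raise DesignError(
                f"design table must have columns {sorted(required)}"
            )
        idx = self.table["volume_index"].to_numpy()
        if len(np.unique(idx)) != len(idx):
            raise DesignError("design assigns some volume more than once")
        expected = np.arange(len(idx))
        if not np.array_equal(np.sort(idx), expected):
            raise DesignError("design volume indices must cover 0..n_volumes-1")
        sizes = self.table.groupby(["condition", "iteration"]).size()
        if sizes.nunique() != 1:
            raise DesignError(
                "all (condition, iteration) cells must hold the same number of volumes; "
                f"got sizes {sorted(sizes.unique())}"
            )

    @property
    def n_volumes(self) -> int:
        return len(self.table)

    @property
    def iterations(self) -> list[int]:
        return sorted(self.table["iteration"].unique())

    @property
    def volumes_per_epoch(self) -> int:
        return int(self.table.groupby(["condition", "iteration"]).size().iloc[0])

    def cells(self) -> list[tuple[str, int]]:
        """All (condition, iteration) cells in condition-major, iteration order."""
        present = set(
            map(tuple, self.table[["condition", "iteration"]].drop_duplicates().values)
        )
        conds = [c for c in self.conditions if any(p[0] == c for p in present)]
        # conditions not in the declared order (user-supplied designs) go last
        extra = sorted({p[0] for p in present} - set(conds))
        out = []
        for c in list(conds) + extra:
            for it in self.iterations:
                if (c, it) in present:
                    out.append((c, int(it)))
        return out

    @classmethod
    def block_design(
        cls,
        conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
        n_iterations: int = 8,
        volumes_per_epoch: int = 9,
    ) -> "EpochDesign":
        """The canonical block design: iterations cycle through the conditions.

        Volume order is iteration-major: iteration 1 runs every condition in
        sequence (``volumes_per_epoch`` volumes each), then iteration 2, etc.
        Defaults give 8 x 4 x 9 = 288 volumes.
        """
        rows = []
        vol = 0
        for it in range(1, n_iterations + 1):
            for cond in conditions:
                for _ in range(volumes_per_epoch):
                    rows.append((vol, cond, it))
                    vol += 1
        return cls(
            pd.DataFrame(rows, columns=["volume_index", "condition", "iteration"]),
            conditions=tuple(conditions),
        )


def segment(
    ts: ParcellatedTimeSeries,
    design: EpochDesign,
    lag_volumes: int = 0,
) -> dict[tuple[str, int], np.ndarray]:
    """Slice the series into per-(condition, iteration) windows.

    ``lag_volumes`` shifts every window forward by that many volumes to
    compensate for hemodynamic delay; the shifted windows must stay in
    bounds. Returns a mapping (condition, iteration) -> regions x window
    matrix (views at lag 0 are copied so callers may mutate freely).
    """
    if design.n_volumes > ts.n_volumes:
        raise DesignError(
            f"design covers {design.n_volumes} volumes but series has only "
            f"{ts.n_volumes}"
        )
    if lag_volumes < 0:
        raise DesignError("lag_volumes must be non-negative")
    windows: dict[tuple[str, int], np.ndarray] = {}
    for (cond, it), sub in design.table.groupby(["condition", "iteration"], sort=False):
        idx = np.sort(sub["volume_index"].to_numpy()) + lag_volumes
        if idx[-1] >= ts.n_volumes:
            raise DesignError(
                f"lag {lag_volumes} pushes cell ({cond}, iteration {it}) "
                f"past the end of the acquisition ({ts.n_volumes} volumes)"
            )
        windows[(cond, int(it))] = ts.matrix[:, idx].copy()
    return windows


def percent_signal_change(ts: ParcellatedTimeSeries) -> np.ndarray:
    """Express each region's signal as percent change over its acquisition mean.

    psc[r, t] = 100 * (x[r, t] - mean_r) / mean_r. Each region's PSC series
    has mean zero by construction. A region whose acquisition-wide mean is
    zero has no defined percent scale and raises ``DegenerateSignalError``.
    """
    means = ts.matrix.mean(axis=1)
    bad = np.flatnonzero(np.isclose(means, 0.0))
    if bad.size:
        label = (
            ts.region_labels[bad[0]]
            if ts.region_labels is not None
            else f"region {bad[0]}"
        )
        raise DegenerateSignalError(
            f"{label} has zero acquisition-wide mean; percent signal change undefined"
        )
    return 100.0 * (ts.matrix - means[:, None]) / means[:, None]


def epoch_mean_psc(
    psc: np.ndarray,
    design: EpochDesign,
    lag_volumes: int = 0,
) -> pd.DataFrame:
    """Average PSC within each epoch window.

    Returns a long DataFrame with columns (region, condition, iteration,
    mean_psc); for each region and condition the iteration-ordered values
    form the 8-point trajectory screened for monotone signal drift.
    """
    psc_ts = ParcellatedTimeSeries(psc)
    windows = segment(psc_ts, design, lag_volumes=lag_volumes)
    rows = []
    for (cond, it), win in windows.items():
        means = win.mean(axis=1)
        for r, m in enumerate(means):
            rows.append((r, cond, it, m))
    return pd.DataFrame(rows, columns=["region", "condition", "iteration", "mean_psc"])
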