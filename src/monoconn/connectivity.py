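"""Per-epoch undirected weighted functional-connectivity graphs.

For one epoch window the edge weight between regions i and j is the Fisher-Z
transform (atanh) of their zero-lag Pearson correlation across the window's
volumes. The graph is kept FULL: all n(n-1)/2 edges are retained, with no
thresholding or binarization, so a 246-region parcellation yields 30,135
unique weighted edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from monoconn.errors import DegenerateSignalError

DEFAULT_R_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityGraph:
    """Symmetric Fisher-Z adjacency for one (condition, iteration) epoch."""

    weights: np.ndarray
    condition: str = ""
    iteration: int = 0
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, rtol=0, atol=0):
            raise ValueError("weights must be exactly symmetric")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    def edge_values(self) -> np.ndarray:
        """The n(n-1)/2 unique off-diagonal weights (upper triangle)."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.weights[iu]

    def to_long(self) -> pd.DataFrame:
        """Long-format edge table (participant, condition, iteration, i, j, z)."""
        i, j = np.triu_indices(self.n_nodes, k=1)
        return pd.DataFrame(
            {
                "participant": self.participant_id,
                "condition": self.condition,
                "iteration": self.iteration,
                "node_i": i,
                "node_j": j,
                "z": self.weights[i, j],
            }
        )


def compute_ufc(
    window: np.ndarray,
    r_clip: float = DEFAULT_R_CLIP,
    condition: str = "",
    iteration: int = 0,
    participant_id: str = "",
) -> ConnectivityGraph:
    """Full undirected functional connectivity for one epoch window.

    ``window`` is regions x volumes. Correlations are clipped to
    [-r_clip, r_clip] before atanh so that numerically perfect correlations
    (possible on synthetic or duplicated signals) map to a large finite
    Fisher Z rather than infinity. A region with zero variance inside the
    window has no defined correlation and raises ``DegenerateSignalError``.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2:
        raise ValueError("window must be 2-D (regions x volumes)")
    n, t = window.shape
    if t < 3:
        raise ValueError(f"window must have >= 3 volumes, got {t}")
    sd = window.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateSignalError(
            f"region {bad[0]} has zero variance in window "
            f"(condition={condition!r}, iteration={iteration}); "
            "correlation undefined"
        )
    r = np.corrcoef(window)
    np.clip(r, -r_clip, r_clip, out=r)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # exact symmetry despite float round-off
    return ConnectivityGraph(
        z, condition=condition, iteration=iteration, participant_id=participant_id
    )
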