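"""Dyadic association networks from co-detection at feeders (modSRI).

The modified Simple Ratio Index scores a dyad by the number of visits (by
either member) that have at least one detection of the partner within
``±tau`` seconds, divided by the dyad's total visit count at the feeder.
Classic SRI needs discrete grouping events; RFID visit streams at busy
feeders are too dense to segment reliably, so temporal proximity stands in
for co-membership of a grouping event.

Each visit contributes at most 1 to the numerator, so the index lies in
``[0, 1]``: 0 for a dyad never detected together, 1 for a dyad whose every
visit is matched by the partner within the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .visits import AP, PeriodWindow, in_window


@dataclass
class AssociationNetwork:
    """Symmetric modSRI matrix for one feeder x association period."""

    feeder_id: str
    ap_index: int
    ids: list[str]
    matrix: np.ndarray
    tau: float
    visit_counts: dict[str, int]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match ids")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if n and not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("matrix must be symmetric")
        if n and (self.matrix.min() < 0 or self.matrix.max() > 1):
            raise ValueError("modSRI entries must lie in [0, 1]")

    def submatrix(self, ids: list[str]) -> np.ndarray:
        idx = [self.ids.index(i) for i in ids]
        return self.matrix[np.ix_(idx, idx)]

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for a in range(len(self.ids)):
            for b in range(a + 1, len(self.ids)):
                rows.append(
                    (
                        self.feeder_id,
                        self.ap_index,
                        self.ids[a],
                        self.ids[b],
                        self.matrix[a, b],
                        self.tau,
                    )
                )
        return pd.DataFrame(
            rows,
            columns=["feeder_id", "ap_index", "id_a", "id_b", "modsri", "tau"],
        )

    def to_matrix_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def _n_paired(a: np.ndarray, b: np.ndarray, tau: float) -> int:
    """Count visits in sorted ``a`` with >=1 detection in sorted ``b`` within tau."""
    if a.size == 0 or b.size == 0:
        return 0
    idx = np.searchsorted(b, a)
    left_ok = np.zeros(a.size, dtype=bool)
    has_left = idx > 0
    left_ok[has_left] = (a[has_left] - b[idx[has_left] - 1]) <= tau
    right_ok = np.zeros(a.size, dtype=bool)
    has_right = idx < b.size
    right_ok[has_right] = (b[idx[has_right]] - a[has_right]) <= tau
    return int(np.count_nonzero(left_ok | right_ok))


def compute_modsri(times_a, times_b, tau: float) -> float:
    """modSRI for one dyad from the two sorted detection-time vectors.

    ``times_a``/``times_b`` are detection times in seconds (any common
    origin).  Returns 0 for a dyad with no visits at all (with a warning).
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    denom = a.size + b.size
    if denom == 0:
        warnings.warn("modSRI of a dyad with no visits is defined as 0")
        return 0.0
    num = _n_paired(a, b, tau) + _n_paired(b, a, tau)
    return num / denom


def build_network(
    visits: pd.DataFrame,
    window: PeriodWindow,
    tau: float = 20.0,
) -> AssociationNetwork:
    """modSRI network over all individuals seen at the feeder in one AP.

    The default co-detection threshold is ±20 s; ±30 s is the conventional
    sensitivity setting.  Dyads with no temporally proximate detections get
    edge weight 0 (no transmission pathway), not a missing value.
    """
    if window.role != AP:
        raise ValueError("build_network requires an AP window")
    sub = in_window(visits, window)
    origin = window.start
    times = {
        ind: np.sort(
            (grp["timestamp"] - origin).dt.total_seconds().to_numpy()
        )
        for ind, grp in sub.groupby("individual_id")
    }
    ids = sorted(times)
    n = len(ids)
    if n < 2:
        warnings.warn(
            f"feeder {window.feeder_id} AP{window.period_index}: fewer than 2"
            " individuals detected; network is degenerate"
        )
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            matrix[i, j] = matrix[j, i] = compute_modsri(
                times[ids[i]], times[ids[j]], tau
            )
    return AssociationNetwork(
        feeder_id=window.feeder_id,
        ap_index=window.period_index,
        ids=ids,
        matrix=matrix,
        tau=tau,
        visit_counts={i: int(times[i].size) for i in ids},
    )
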