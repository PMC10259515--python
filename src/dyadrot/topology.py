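"""Dynamic neighbor topology of the epithelium around a rotating pair.

Cells are nodes; a bond row at a frame makes two cells neighbors at
that frame.  The central statistic is the cumulative difference in the
number of neighbors of the two siblings, D(T) = sum_{t=1..T} (N_t -
M_t), where N_t counts the neighbors of the sibling that finishes the
recording on the anterior side (the Notch-off/Emx2-positive cell,
assigned retrospectively) and M_t those of its posterior-finishing
sibling.  Symmetric neighbor exchange keeps D near zero; a persistently
"popular" cell makes |D| grow roughly linearly.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import CellBondTables

__all__ = [
    "NeighborSeries",
    "build_dynamic_network",
    "neighbor_series_from_network",
    "label_anterior_posterior",
    "cumulative_neighbor_difference",
    "cumulative_difference_series",
    "popular_cell",
    "smooth_difference",
]


@dataclass
class NeighborSeries:
    """Per-frame neighbor counts (and optionally sets) of the siblings.

    Sibling A is the cell that finishes anterior, sibling B the one
    that finishes posterior.
    """

    frames: np.ndarray
    counts_a: np.ndarray
    counts_b: np.ndarray
    sets_a: list | None = None
    sets_b: list | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.counts_a = np.asarray(self.counts_a, dtype=int)
        self.counts_b = np.asarray(self.counts_b, dtype=int)
        if len(self.counts_a) != len(self.frames) or len(self.counts_b) != len(self.frames):
            raise ValueError("counts not aligned with frames")
        if np.any(self.counts_a < 0) or np.any(self.counts_b < 0):
            raise ValueError("neighbor counts must be >= 0")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def swapped(self) -> "NeighborSeries":
        """Exchange the sibling labels (negates D(T) exactly)."""
        return NeighborSeries(
            frames=self.frames.copy(),
            counts_a=self.counts_b.copy(),
            counts_b=self.counts_a.copy(),
            sets_a=self.sets_b,
            sets_b=self.sets_a,
        )


def build_dynamic_network(tables: CellBondTables) -> dict[int, nx.Graph]:
    """Per-frame adjacency graphs: cells adjacent iff a bond links them."""
    graphs: dict[int, nx.Graph] = {}
    for frame in tables.frames:
        g = nx.Graph()
        g.add_nodes_from(tables.cells_at(int(frame))["cell_id"])
        for _, row in tables.bonds_at(int(frame)).iterrows():
            g.add_edge(row["cell_id_a"], row["cell_id_b"], length_um=row["length_um"])
        graphs[int(frame)] = g
    return graphs


def label_anterior_posterior(track_table, id1, id2) -> tuple:
    """Retrospective sibling labels from final positions.

    The cell with the larger final x (posterior, since x increases
    posteriorly) is sibling B; the other, finishing anterior, is A.
    """
    x1 = track_table.positions(id1)[-1, 0]
    x2 = track_table.positions(id2)[-1, 0]
    return (id1, id2) if x1 <= x2 else (id2, id1)


def neighbor_series_from_network(
    graphs: dict[int, nx.Graph], cell_a, cell_b, include_sibling: bool = True
) -> NeighborSeries:
    """Neighbor sets of the two siblings over frames where both exist.

    Whether the sibling-sibling edge itself is counted is configurable;
    it enters both counts equally, so N_t - M_t (and hence D) is
    invariant to the choice.
    """
    cell_a, cell_b = str(cell_a), str(cell_b)
    frames, sets_a, sets_b = [], [], []
    for frame in sorted(graphs):
        g = graphs[frame]
        if cell_a not in g or cell_b not in g:
            continue
        na = set(g.neighbors(cell_a))
        nb = set(g.neighbors(cell_b))
        if not include_sibling:
            na.discard(cell_b)
            nb.discard(cell_a)
        frames.append(frame)
        sets_a.append(frozenset(na))
        sets_b.append(frozenset(nb))
    return NeighborSeries(
        frames=np.array(frames, dtype=int),
        counts_a=np.array([len(s) for s in sets_a], dtype=int),
        counts_b=np.array([len(s) for s in sets_b], dtype=int),
        sets_a=sets_a,
        sets_b=sets_b,
    )


def cumulative_difference_series(series: NeighborSeries) -> np.ndarray:
    """D(T) for T = 1..n_frames (D(T) = sum_{t<=T} (N_t - M_t))."""
    return np.cumsum(series.counts_a - series.counts_b)


def cumulative_neighbor_difference(series: NeighborSeries, T: int) -> int:
    """D(T) over the first T frames; T must lie in [1, n_frames]."""
    if not 1 <= T <= series.n_frames:
        raise IndexError(f"T={T} outside [1, {series.n_frames}]")
    return int(cumulative_difference_series(series)[T - 1])


def popular_cell(series: NeighborSeries, alpha: float = 0.05) -> tuple[str | None, float]:
    """Detect a persistently popular sibling.

    Requires >= 20 frames.  A sign test on the nonzero per-frame count
    differences decides whether the exchange is asymmetric at level
    ``alpha``; if so, the sign of the least-squares slope of D(T) vs T
    names the popular cell ("A" or "B"), otherwise ``(None, slope)``.
    """
    if series.n_frames < 20:
        raise ValueError("popularity detection requires at least 20 frames")
    diff = series.counts_a - series.counts_b
    d = cumulative_difference_series(series)
    t = np.arange(1, series.n_frames + 1, dtype=float)
    slope = float(np.polyfit(t, d, 1)[0])
    nonzero = diff[diff != 0]
    if len(nonzero) == 0:
        return None, slope
    k = int(np.sum(nonzero > 0))
    p = stats.binomtest(k, len(nonzero), 0.5, alternative="two-sided").pvalue
    if p >= alpha:
        return None, slope
    return ("A" if slope > 0 else "B"), slope


def smooth_difference(
    trajectories: dict[str, list[np.ndarray]] | list[np.ndarray],
    span: float = 0.3,
    absolute: bool = True,
) -> pd.DataFrame:
    """LOESS-smoothed |D(T)| (or signed D) per group of trajectories.

    ``trajectories`` maps a group label (e.g. "inverting") to a list of
    D-series; a bare list is treated as one unnamed group.  All series
    in a group are pooled on their frame index and locally weighted
    regression with fraction ``span`` is fitted.
    """
    if isinstance(trajectories, (list, tuple)):
        trajectories = {"all": list(trajectories)}
    rows = []
    for group, series_list in trajectories.items():
        ts, ds = [], []
        for d in series_list:
            d = np.asarray(d, dtype=float)
            ts.append(np.arange(1, len(d) + 1, dtype=float))
            ds.append(np.abs(d) if absolute else d)
        t = np.concatenate(ts)
        y = np.concatenate(ds)
        sm = lowess(y, t, frac=span, it=0, return_sorted=True)
        for ti, yi in sm:
            rows.append({"group": group, "T": ti, "smoothed": yi})
    return pd.DataFrame(rows).drop_duplicates(subset=["group", "T"]).reset_index(drop=True)
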