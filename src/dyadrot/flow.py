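"""Epithelium-wide movement correlation along the anteroposterior axis.

Each cell's frame-to-frame displacement along x (the A-P axis) is
correlated, pair by pair, after subtracting the displacement of a
reference (the organ center, held spatially fixed during tracking).
Displacements rather than positions are correlated: positions of
confined cells are trivially autocorrelated, whereas displacement
correlations isolate coherent movement.  Cell pairings are classed as
the rotating pair itself (HC-HC), a rotating cell against any other
cell (HC-other), or two bystander cells (other-other).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .io import TrackTable

__all__ = ["ap_displacement_series", "correlate_classes", "summarize_correlations"]

PAIR_CLASSES = ("HC-HC", "HC-other", "other-other")


def ap_displacement_series(
    frames: np.ndarray,
    x: np.ndarray,
    ref_frames: np.ndarray | None = None,
    ref_x: np.ndarray | None = None,
) -> np.ndarray:
    """Per-interval A-P displacement x(t+1) - x(t), minus the reference
    displacement if a reference track is supplied (grids must match)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 frames")
    dx = np.diff(x)
    if ref_x is not None:
        if ref_frames is None or not np.array_equal(
            np.asarray(frames), np.asarray(ref_frames)
        ):
            raise ValueError("reference track is not on the same frame grid")
        dx = dx - np.diff(np.asarray(ref_x, dtype=float))
    return dx


def correlate_classes(
    table: TrackTable,
    pair_ids: tuple,
    reference_id=None,
    min_frames: int = 3,
) -> pd.DataFrame:
    """Pearson R of A-P displacements for every unordered track pairing.

    Returns a long-format table (id_1, id_2, pair_class, r, n_frames);
    pairings with fewer than ``min_frames`` common intervals or a
    zero-variance displacement series are reported with NaN R and the
    skip reason.
    """
    pair_set = {str(p) for p in pair_ids}
    ids = [i for i in table.track_ids if i != reference_id]
    tracks = {i: table.track(i).set_index("frame") for i in ids}
    ref = table.track(reference_id).set_index("frame") if reference_id is not None else None
    rows = []
    for id1, id2 in combinations(ids, 2):
        t1, t2 = tracks[id1], tracks[id2]
        common = t1.index.intersection(t2.index)
        if ref is not None:
            common = common.intersection(ref.index)
        in_pair = (id1 in pair_set) + (id2 in pair_set)
        cls = PAIR_CLASSES[2 - in_pair]
        base = {"id_1": id1, "id_2": id2, "pair_class": cls}
        if len(common) < min_frames + 1:
            rows.append({**base, "r": np.nan, "n_frames": len(common),
                         "skipped": "fewer than min common frames"})
            continue
        fr = common.to_numpy()
        if ref is not None:
            rx = ref.loc[common, "x_um"].to_numpy()
            dx1 = ap_displacement_series(fr, t1.loc[common, "x_um"].to_numpy(), fr, rx)
            dx2 = ap_displacement_series(fr, t2.loc[common, "x_um"].to_numpy(), fr, rx)
        else:
            dx1 = ap_displacement_series(fr, t1.loc[common, "x_um"].to_numpy())
            dx2 = ap_displacement_series(fr, t2.loc[common, "x_um"].to_numpy())
        if np.std(dx1) == 0 or np.std(dx2) == 0:
            rows.append({**base, "r": np.nan, "n_frames": len(common),
                         "skipped": "zero-variance displacement series"})
            continue
        r = float(np.corrcoef(dx1, dx2)[0, 1])
        rows.append({**base, "r": r, "n_frames": len(common), "skipped": ""})
    return pd.DataFrame(rows)


def summarize_correlations(report: pd.DataFrame) -> pd.DataFrame:
    """Pooled-pair and median summaries of R per pairing class."""
    ok = report[report["r"].notna()]
    rows = []
    for cls in PAIR_CLASSES:
        sub = ok[ok["pair_class"] == cls]
        rows.append(
            {
                "pair_class": cls,
                "n_pairings": len(sub),
                "mean_r": float(sub["r"].mean()) if len(sub) else np.nan,
                "median_r": float(sub["r"].median()) if len(sub) else np.nan,
            }
        )
    return pd.DataFrame(rows)
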