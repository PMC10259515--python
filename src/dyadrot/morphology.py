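"""Pair morphology: circularity, junction series and interface shape.

The two siblings taken as a unit are scored by the isoperimetric
circularity C = 4*pi*A / P**2, where A is the summed cell area and P the
summed perimeter minus twice the shared membrane segment (the outline of
the fused pair).  C is 1 for a disc and decreases for any other shape.
The homotypic interface polyline is classified as straight (I), curved
(C) or one of the two chiral sigmoid forms (S / Ƨ) from its asymmetry
about the two axes after canonical alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CellBondTables, decode_polyline

__all__ = [
    "MorphSeries",
    "InterfaceShape",
    "pair_circularity",
    "circularity_series",
    "morph_series_from_tables",
    "junction_and_distance_series",
    "canonicalize_interface",
    "resample_arclength",
    "classify_interface_shape",
    "mirror_polyline",
    "shape_census",
]

SHAPE_CLASSES = ("I", "C", "S", "Ƨ")


@dataclass
class MorphSeries:
    """Per-frame geometry of one sibling pair."""

    frames: np.ndarray
    area1: np.ndarray
    area2: np.ndarray
    perimeter1: np.ndarray
    perimeter2: np.ndarray
    shared_length: np.ndarray  # 0 where the siblings share no bond
    distance: np.ndarray  # inter-centroid distance
    polylines: list | None = None  # per-frame interface polyline or None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        for name in ("area1", "area2", "perimeter1", "perimeter2", "shared_length", "distance"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.area1 <= 0) or np.any(self.area2 <= 0):
            raise ValueError("areas must be positive")
        if np.any(self.perimeter1 <= 0) or np.any(self.perimeter2 <= 0):
            raise ValueError("perimeters must be positive")
        limit = np.minimum(self.perimeter1, self.perimeter2)
        if np.any(self.shared_length > limit + 1e-9):
            raise ValueError("shared junction longer than a cell perimeter")


def pair_circularity(area1, area2, perimeter1, perimeter2, shared_length):
    """Isoperimetric circularity of the fused pair.

    ``C = 4 pi (A1 + A2) / (P1 + P2 - 2 L)**2``; defined only on frames
    where the siblings share a bond (``L > 0``), NaN elsewhere.  Values
    above 1 (possible with segmentation noise) are clamped to 1; the
    returned mask flags them.
    """
    a1 = np.asarray(area1, dtype=float)
    a2 = np.asarray(area2, dtype=float)
    p = (
        np.asarray(perimeter1, dtype=float)
        + np.asarray(perimeter2, dtype=float)
        - 2.0 * np.asarray(shared_length, dtype=float)
    )
    shared = np.asarray(shared_length, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = 4.0 * np.pi * (a1 + a2) / p**2
    c = np.where(shared > 0, c, np.nan)
    clamped = np.asarray(c > 1.0)
    c = np.where(clamped, 1.0, c)
    if np.ndim(area1) == 0:
        return float(c), bool(clamped)
    return c, clamped


def circularity_series(morph: MorphSeries) -> pd.DataFrame:
    """Per-frame circularity with the >1 clamp flag."""
    c, clamped = pair_circularity(
        morph.area1, morph.area2, morph.perimeter1, morph.perimeter2, morph.shared_length
    )
    return pd.DataFrame({"frame": morph.frames, "circularity": c, "clamped": clamped})


def morph_series_from_tables(tables: CellBondTables, id_a, id_b) -> MorphSeries:
    """Extract the pair's morphology series from segmentation exports.

    Frames are those where both cells are segmented; frames without a
    sibling-sibling bond carry a shared length of 0 and no polyline.
    """
    id_a, id_b = str(id_a), str(id_b)
    cells = tables.cells
    ca = cells[cells["cell_id"] == id_a].set_index("frame")
    cb = cells[cells["cell_id"] == id_b].set_index("frame")
    frames = np.intersect1d(ca.index.to_numpy(), cb.index.to_numpy())
    if len(frames) == 0:
        raise ValueError(f"cells {id_a!r}/{id_b!r} share no segmented frames")
    ca, cb = ca.loc[frames], cb.loc[frames]
    bonds = tables.bonds
    mask = ((bonds["cell_id_a"] == id_a) & (bonds["cell_id_b"] == id_b)) | (
        (bonds["cell_id_a"] == id_b) & (bonds["cell_id_b"] == id_a)
    )
    pair_bonds = bonds[mask].set_index("frame")
    shared = np.zeros(len(frames))
    polylines: list = [None] * len(frames)
    for i, f in enumerate(frames):
        if f in pair_bonds.index:
            row = pair_bonds.loc[f]
            if isinstance(row, pd.DataFrame):  # multiple segments: sum lengths
                shared[i] = float(row["length_um"].sum())
                poly = row["polyline"].dropna()
                polylines[i] = decode_polyline(poly.iloc[0]) if len(poly) else None
            else:
                shared[i] = float(row["length_um"])
                if isinstance(row["polyline"], str):
                    polylines[i] = decode_polyline(row["polyline"])
    dist = np.hypot(ca["cx_um"].to_numpy() - cb["cx_um"].to_numpy(),
                    ca["cy_um"].to_numpy() - cb["cy_um"].to_numpy())
    return MorphSeries(
        frames=frames,
        area1=ca["area_um2"].to_numpy(),
        area2=cb["area_um2"].to_numpy(),
        perimeter1=ca["perimeter_um"].to_numpy(),
        perimeter2=cb["perimeter_um"].to_numpy(),
        shared_length=shared,
        distance=dist,
        polylines=polylines,
    )


def junction_and_distance_series(morph: MorphSeries) -> pd.DataFrame:
    """Aligned per-frame (shared junction length, inter-centroid distance)."""
    return pd.DataFrame(
        {
            "frame": morph.frames,
            "shared_length_um": morph.shared_length,
            "distance_um": morph.distance,
        }
    )


def canonicalize_interface(polyline: np.ndarray) -> np.ndarray:
    """Rigidly move a polyline so its endpoints sit at (-L/2, 0), (+L/2, 0).

    L is the endpoint separation; the traversal orientation is
    preserved (rotation + translation only, no reflection).
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("polyline must be an (N>=2, 2) array")
    if not np.any(np.ptp(pts, axis=0) > 0):
        raise ValueError("polyline has no distinct points")
    v = pts[-1] - pts[0]
    length = float(np.hypot(*v))
    if length == 0.0:
        raise ValueError("coincident endpoints; interface has no axis")
    mid = 0.5 * (pts[0] + pts[-1])
    cos_t, sin_t = v / length
    rot = np.array([[cos_t, sin_t], [-sin_t, cos_t]])  # R(-theta)
    return (pts - mid) @ rot.T


def resample_arclength(polyline: np.ndarray, n_points: int = 64) -> np.ndarray:
    """Resample a polyline at arc-length-uniform parameter values."""
    pts = np.asarray(polyline, dtype=float)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        raise ValueError("degenerate polyline of zero length")
    si = np.linspace(0.0, s[-1], n_points)
    return np.column_stack([np.interp(si, s, pts[:, 0]), np.interp(si, s, pts[:, 1])])


def mirror_polyline(polyline: np.ndarray) -> np.ndarray:
    """Reflect about the x axis (swaps the two chiral classes)."""
    out = np.asarray(polyline, dtype=float).copy()
    out[:, 1] = -out[:, 1]
    return out


@dataclass
class InterfaceShape:
    shape_class: str  # one of I, C, S, Ƨ
    x_asymmetry: float  # odd-component score; chirality indicator
    y_asymmetry: float  # mean bowing away from the endpoint axis


def classify_interface_shape(
    polyline: np.ndarray,
    tau_s: float = 0.05,
    tau_c: float = 0.05,
    n_points: int = 64,
) -> InterfaceShape:
    """Classify a homotypic interface as I, C, S or Ƨ.

    The polyline is canonically aligned and resampled to ``n_points``
    arc-length-uniform points, decoupling the scores from vertex
    density.  With the arc parameter s centered on the midpoint, the
    x-asymmetry is the normalized mean |y(s) + y(-s)| / 2 (the odd
    component of the profile about the y axis) and the y-asymmetry the
    normalized mean |y|.  Precedence: a chiral S/Ƨ call (x-asymmetry
    over ``tau_s``, handedness from the sign of the trailing lobe),
    then C (y-asymmetry over ``tau_c``), else I.  Both thresholds are
    fractions of the endpoint separation.
    """
    canon = canonicalize_interface(polyline)
    pts = resample_arclength(canon, n_points)
    scale = float(np.hypot(*(pts[-1] - pts[0])))
    y = pts[:, 1]
    y_rev = y[::-1]
    # odd component of the profile about the y axis: zero for I and C
    # (both mirror-symmetric about the curve midpoint), positive for the
    # chiral sigmoids
    odd = 0.5 * (y - y_rev)
    x_asym = float(np.mean(np.abs(odd))) / scale
    y_asym = float(np.mean(np.abs(y))) / scale
    if x_asym > tau_s:
        # trailing (s > 0) lobe of the odd part decides the chirality:
        # positive for an S-curve like sin(pi x / L), negative mirrored
        half = len(y) // 2
        lobe = float(np.mean(odd[half:]))
        cls = "S" if lobe > 0 else "Ƨ"
    elif y_asym > tau_c:
        cls = "C"
    else:
        cls = "I"
    return InterfaceShape(cls, x_asym, y_asym)


def shape_census(shapes: list[InterfaceShape]) -> pd.DataFrame:
    """Frequency table of interface shape classes (percent of frames)."""
    counts = {c: 0 for c in SHAPE_CLASSES}
    for s in shapes:
        counts[s.shape_class] += 1
    total = max(1, len(shapes))
    return pd.DataFrame(
        {
            "shape": list(counts),
            "count": list(counts.values()),
            "percent": [100.0 * v / total for v in counts.values()],
        }
    )
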