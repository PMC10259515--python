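"""Synthetic fixtures with the statistical structure the analyses assume.

The generators emulate the videomicroscopy-derived tracking tables the
pipeline consumes: sibling-pair circular-arc trajectories whose angular
progression is logistic in time (inverting pairs) or sinusoidally
rocking (non-inverting pairs), with optional per-frame angular wobble;
phase-correlated area/perimeter/junction series; neighbor-exchange
event sequences; and uncorrelated background epithelial tracks.  Every
generator is a pure function of its parameters and seed.

Wobble is injected in angle space (not Cartesian) so that angular-path
statistics of the output can be set analytically.  Non-inverting pairs
rock sinusoidally about their initial angle with an amplitude kept
below the 90-degree inversion criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import CellBondTables, TrackTable, encode_polyline
from .topology import NeighborSeries
from .trajectory import logistic4

__all__ = [
    "PairSynthesisParams",
    "MorphSynthesisParams",
    "EpitheliumSynthesisParams",
    "generate_pair_tracks",
    "generate_morph_series",
    "generate_neighbor_series",
    "generate_epithelium",
    "generate_cohort",
]


@dataclass
class PairSynthesisParams:
    """Construction recipe for one sibling-pair track.

    For inverting pairs the noise-free positional angle follows the
    four-parameter logistic ``c + (d - c) / (1 + exp(-b (t - a)))``
    (midpoint ``a_min`` minutes after birth, steepness ``b_per_min``);
    non-inverting pairs oscillate about ``initial_angle_deg`` with
    amplitude ``rock_amplitude_deg`` and period ``rock_period_min``.
    ``wobble_sd_deg`` adds independent Gaussian angular noise per frame.
    The two cells sit mirror-symmetrically at ``pair_radius_um`` from a
    (possibly drifting) pair centroid.
    """

    inverting: bool = True
    a_min: float = 100.0
    b_per_min: float = 0.08
    c_deg: float = 0.0
    d_deg: float = 170.0
    wobble_sd_deg: float = 0.0
    rock_amplitude_deg: float = 30.0
    rock_period_min: float = 100.0
    pair_radius_um: float = 4.0
    initial_angle_deg: float = 0.0
    n_frames: int = 150
    frame_interval_s: float = 200.0
    drift_um_per_min: tuple[float, float] = (0.0, 0.0)
    origin_um: tuple[float, float] = (0.0, 0.0)
    track_ids: tuple[str, str] = ("cell_a", "cell_b")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wobble_sd_deg < 0:
            raise ValueError("wobble_sd_deg must be >= 0")
        if self.pair_radius_um <= 0:
            raise ValueError("pair_radius_um must be > 0")
        if self.inverting and self.b_per_min <= 0:
            raise ValueError("inverting pairs need steepness b_per_min > 0")
        if not self.inverting and not abs(self.rock_amplitude_deg) < 90.0:
            raise ValueError("rocking amplitude must stay below the 90 deg criterion")

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s / 60.0

    def clean_angle(self, t: np.ndarray) -> np.ndarray:
        """Noise-free positional angle of the cell-1 -> cell-2 axis."""
        if self.inverting:
            return self.initial_angle_deg + logistic4(
                t, self.a_min, self.b_per_min, self.c_deg, self.d_deg
            )
        return self.initial_angle_deg + self.rock_amplitude_deg * np.sin(
            2.0 * np.pi * t / self.rock_period_min
        )


def generate_pair_tracks(params: PairSynthesisParams) -> TrackTable:
    """Two mirror-symmetric sibling tracks about a drifting centroid."""
    rng = np.random.default_rng(params.seed)
    t = params.times_min
    alpha = params.clean_angle(t)
    if params.wobble_sd_deg > 0:
        alpha = alpha + rng.normal(0.0, params.wobble_sd_deg, size=len(t))
    rad = np.radians(alpha)
    u = np.column_stack([np.cos(rad), np.sin(rad)])
    center = np.asarray(params.origin_um) + np.outer(t, np.asarray(params.drift_um_per_min))
    xy1 = center - params.pair_radius_um * u
    xy2 = center + params.pair_radius_um * u
    frames = np.arange(params.n_frames)
    id1, id2 = params.track_ids
    df = pd.DataFrame(
        {
            "track_id": [id1] * params.n_frames + [id2] * params.n_frames,
            "frame": np.concatenate([frames, frames]),
            "time_min": np.concatenate([t, t]),
            "x_um": np.concatenate([xy1[:, 0], xy2[:, 0]]),
            "y_um": np.concatenate([xy1[:, 1], xy2[:, 1]]),
        }
    )
    return TrackTable(df)


@dataclass
class MorphSynthesisParams:
    """Morphology template anchored to the pair's rotation phases.

    Cell areas stay constant; perimeters and the shared junction are
    piecewise-smooth series whose peak falls inside the active-rotation
    phase [Ic, Id] implied by the pair's logistic parameters.  These
    are qualitative templates, not a mechanical model: only the
    phase-2 peak structure of real recordings is emulated.
    """

    area_um2: float = 30.0
    circularity_base: float = 0.6
    circularity_peak: float = 0.9
    junction_base_um: float = 1.0
    junction_peak_um: float = 5.0
    distance_dip_fraction: float = 0.3  # siblings close in during phase 2
    shape_class: str = "I"  # interface template: I, C, S or Ƨ
    shape_amplitude: float = 0.25  # bow/lobe height as fraction of length
    dropout_frames: tuple = ()  # frames with no sibling bond
    n_polyline_points: int = 33

    def __post_init__(self) -> None:
        if self.shape_class not in ("I", "C", "S", "Ƨ"):
            raise ValueError("shape_class must be one of I, C, S, Ƨ")
        if not 0 < self.circularity_base <= self.circularity_peak <= 1.0:
            raise ValueError("need 0 < circularity_base <= circularity_peak <= 1")


def _phase2_window(t: np.ndarray, ic: float, id_: float) -> np.ndarray:
    """Smooth bump supported on [Ic, Id], peaking at the midpoint."""
    w = np.zeros_like(t)
    inside = (t >= ic) & (t <= id_)
    if id_ > ic:
        w[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[inside] - ic) / (id_ - ic)))
    return w


def _interface_polyline(length: float, cls: str, amplitude: float, n: int) -> np.ndarray:
    x = np.linspace(-length / 2.0, length / 2.0, n)
    if cls == "I":
        y = np.zeros_like(x)
    elif cls == "C":
        # single bow, endpoints on the axis
        y = amplitude * length * np.cos(np.pi * x / length)
    else:
        # full-period sigmoid: one lobe each side of the midpoint
        y = amplitude * length * np.sin(2.0 * np.pi * x / length)
        if cls == "Ƨ":
            y = -y
    return np.column_stack([x, y])


def generate_morph_series(
    pair_params: PairSynthesisParams, morph_params: MorphSynthesisParams | None = None
) -> CellBondTables:
    """Cell/bond tables whose circularity and junction length peak in
    the rotation phase and whose interface polyline carries a chosen
    shape class."""
    morph_params = morph_params or MorphSynthesisParams()
    if not pair_params.inverting:
        raise ValueError("morphology templates are anchored to an inverting pair's phases")
    t = pair_params.times_min
    ic = pair_params.a_min - 2.0 / pair_params.b_per_min
    id_ = pair_params.a_min + 2.0 / pair_params.b_per_min
    w = _phase2_window(t, ic, id_)

    mp = morph_params
    area = mp.area_um2
    shared = mp.junction_base_um + (mp.junction_peak_um - mp.junction_base_um) * w
    circ = mp.circularity_base + (mp.circularity_peak - mp.circularity_base) * w
    # invert C = 4 pi (2A) / P_eff^2 for the fused-outline perimeter
    p_eff = np.sqrt(4.0 * np.pi * 2.0 * area / circ)
    perimeter = 0.5 * (p_eff + 2.0 * shared)

    alpha = np.radians(pair_params.clean_angle(t))
    u = np.column_stack([np.cos(alpha), np.sin(alpha)])
    radius = pair_params.pair_radius_um * (1.0 - mp.distance_dip_fraction * w)
    c1 = -radius[:, None] * u
    c2 = radius[:, None] * u

    frames = np.arange(pair_params.n_frames)
    id1, id2 = pair_params.track_ids
    cells = pd.DataFrame(
        {
            "cell_id": [id1] * len(frames) + [id2] * len(frames),
            "frame": np.concatenate([frames, frames]),
            "cx_um": np.concatenate([c1[:, 0], c2[:, 0]]),
            "cy_um": np.concatenate([c1[:, 1], c2[:, 1]]),
            "area_um2": np.full(2 * len(frames), area),
            "perimeter_um": np.concatenate([perimeter, perimeter]),
        }
    )
    dropout = set(int(f) for f in mp.dropout_frames)
    bond_rows = []
    for i, f in enumerate(frames):
        if int(f) in dropout:
            continue
        # interface perpendicular to the pair axis, through the midpoint
        poly = _interface_polyline(shared[i], mp.shape_class, mp.shape_amplitude, mp.n_polyline_points)
        phi = alpha[i] + np.pi / 2.0
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        bond_rows.append(
            {
                "frame": int(f),
                "cell_id_a": id1,
                "cell_id_b": id2,
                "length_um": float(shared[i]),
                "polyline": encode_polyline(poly @ rot.T),
            }
        )
    bonds = pd.DataFrame(bond_rows)
    if bonds.empty:
        bonds = pd.DataFrame(columns=["frame", "cell_id_a", "cell_id_b", "length_um", "polyline"])
    return CellBondTables(cells=cells, bonds=bonds)


def generate_neighbor_series(
    n_frames: int,
    bias: int = 0,
    p_exchange: float = 0.3,
    base_count: int = 5,
    seed: int = 0,
) -> NeighborSeries:
    """Neighbor-count sequences for the two siblings.

    With ``bias = 0`` exchanges are symmetric and alternate direction,
    so each temporary surplus of one sibling is compensated by the next
    event and the cumulative difference D(T) stays bounded near zero.
    With ``bias = +-1`` the corresponding sibling holds exactly that
    surplus on every frame (a persistently popular cell), making
    D(T) = bias * T exactly.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    counts_a = np.full(n_frames, base_count, dtype=int)
    counts_b = np.full(n_frames, base_count, dtype=int)
    if bias > 0:
        counts_a += bias
    elif bias < 0:
        counts_b += -bias
    else:
        sign = 1 if rng.integers(0, 2) else -1
        for i in range(n_frames):
            if rng.random() < p_exchange:
                if sign > 0:
                    counts_a[i] += 1
                else:
                    counts_b[i] += 1
                sign = -sign
    return NeighborSeries(frames=np.arange(n_frames), counts_a=counts_a, counts_b=counts_b)


@dataclass
class EpitheliumSynthesisParams:
    """Background epithelium: stationary cells with positional jitter."""

    n_cells: int = 12
    arena_radius_um: float = 20.0
    jitter_sd_um: float = 0.3
    n_frames: int = 100
    frame_interval_s: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def generate_epithelium(
    params: EpitheliumSynthesisParams,
    embedded_pair: PairSynthesisParams | None = None,
) -> TrackTable:
    """Independently jittered stationary tracks, optionally with one
    embedded mirror-rotating sibling pair."""
    rng = np.random.default_rng(params.seed)
    t = np.arange(params.n_frames) * params.frame_interval_s / 60.0
    frames = np.arange(params.n_frames)
    dfs = []
    # rejection-free uniform placement in the disc
    r = params.arena_radius_um * np.sqrt(rng.random(params.n_cells))
    phi = rng.uniform(0.0, 2.0 * np.pi, params.n_cells)
    centers = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    for j in range(params.n_cells):
        jitter = rng.normal(0.0, params.jitter_sd_um, size=(params.n_frames, 2))
        xy = centers[j] + jitter
        dfs.append(
            pd.DataFrame(
                {
                    "track_id": f"cell_{j:04d}",
                    "frame": frames,
                    "time_min": t,
                    "x_um": xy[:, 0],
                    "y_um": xy[:, 1],
                }
            )
        )
    if embedded_pair is not None:
        pair_tab = generate_pair_tracks(embedded_pair)
        dfs.append(pair_tab.df)
    return TrackTable(pd.concat(dfs, ignore_index=True))


def generate_cohort(
    n_pairs: int,
    fraction_inverting: float = 0.5,
    genotype: str = "synthetic",
    wobble_sd_deg: float = 2.0,
    final_turn_deg: float = 150.0,
    rock_amplitude_deg: float = 30.0,
    n_frames: int = 150,
    composition: str = "fixed",
    seed: int = 0,
    config: RunConfig | None = None,
) -> list:
    """A cohort of pair records of known composition.

    With ``composition="fixed"`` exactly ``round(n_pairs *
    fraction_inverting)`` pairs invert (final turn ``final_turn_deg``);
    with ``"bernoulli"`` each pair inverts independently with that
    probability, emulating the sampling variability of a real cohort.
    Non-inverting pairs rock with the given amplitude.  Initial angles
    are uniform on the circle, as observed for nascent pairs.  Returns
    a list of :class:`~dyadrot.trajectory.CellPairRecord`.
    """
    from .trajectory import CellPairRecord

    if composition not in ("fixed", "bernoulli"):
        raise ValueError("composition must be 'fixed' or 'bernoulli'")
    rng = np.random.default_rng(seed)
    n_invert = int(round(n_pairs * fraction_inverting))
    records = []
    for i in range(n_pairs):
        if composition == "fixed":
            inverting = i < n_invert
        else:
            inverting = bool(rng.random() < fraction_inverting)
        params = PairSynthesisParams(
            inverting=inverting,
            d_deg=final_turn_deg,
            wobble_sd_deg=wobble_sd_deg,
            rock_amplitude_deg=rock_amplitude_deg,
            initial_angle_deg=float(rng.uniform(0.0, 360.0)),
            n_frames=n_frames,
            seed=int(rng.integers(0, 2**31 - 1)),
            track_ids=(f"p{i}_a", f"p{i}_b"),
        )
        table = generate_pair_tracks(params)
        records.append(
            CellPairRecord.from_track_table(
                table, f"p{i}_a", f"p{i}_b", pair_id=f"pair_{i:03d}", genotype=genotype
            )
        )
    return records
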