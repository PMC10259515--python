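"""Kinematics of sibling-cell pair rotations.

A nascent hair-cell pair is tracked from its birth by the centroids of
the two siblings.  The pair is centered frame-by-frame on its own
centroid, the positional angle of the inter-cell axis against the
anteroposterior (+x) axis is unwrapped into a cumulative angle, and a
four-parameter logistic fitted to that cumulative angle segments the
movement into three phases: quiescence before the rotation (Phase 1),
the active rotation (Phase 2) and the settled period after it
(Phase 3).  Scalar statistics (turn, overshoot, wobbling, trajectory
noise, handedness) and genotype-level statistical comparisons follow.

Sign convention: positive angle changes are anti-clockwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import RunConfig

__all__ = [
    "CellPairRecord",
    "AngleSeries",
    "LogisticFit",
    "NoiseResult",
    "RotationMetrics",
    "center_pair",
    "positional_angle",
    "angle_series",
    "logistic4",
    "fit_phase_logistic",
    "phase_boundaries",
    "classify_inversion",
    "start_final_angles",
    "circular_mean_deg",
    "overshoot",
    "wobbling",
    "trajectory_noise",
    "handedness",
    "normalize_angle_0_180",
    "final_angle_first_quadrant",
    "compute_rotation_metrics",
    "metrics_table",
    "compare_genotypes",
    "render_report",
]

GENOTYPES = ("wild-type", "emx2-/-", "notch1a-/-", "synthetic")


class UndefinedAngleError(ValueError):
    """The two centroids coincide, so the pair axis has no direction."""


@dataclass
class CellPairRecord:
    """Two sibling centroid tracks on a shared frame grid."""

    pair_id: str
    genotype: str
    frames: np.ndarray
    times_min: np.ndarray
    xy1: np.ndarray  # (N, 2) micrometres
    xy2: np.ndarray
    birth_frame: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.xy1 = np.asarray(self.xy1, dtype=float)
        self.xy2 = np.asarray(self.xy2, dtype=float)
        n = len(self.frames)
        if n < 2:
            raise ValueError("a pair record needs at least 2 frames")
        for arr, name in ((self.times_min, "times_min"), (self.xy1, "xy1"), (self.xy2, "xy2")):
            if len(arr) != n:
                raise ValueError(f"{name} not on the shared frame grid")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def birth_time_min(self) -> float:
        i = np.searchsorted(self.frames, self.birth_frame)
        i = min(i, len(self.frames) - 1)
        return float(self.times_min[i])

    @classmethod
    def from_track_table(
        cls,
        table,
        id1,
        id2,
        pair_id: str | None = None,
        genotype: str = "synthetic",
        birth_frame: int = 0,
    ) -> "CellPairRecord":
        """Build a pair record from two tracks, restricted to shared frames."""
        t1, t2 = table.track(id1), table.track(id2)
        common = np.intersect1d(t1["frame"].to_numpy(), t2["frame"].to_numpy())
        if len(common) < 2:
            raise ValueError(f"tracks {id1!r}/{id2!r} share fewer than 2 frames")
        s1 = t1.set_index("frame").loc[common]
        s2 = t2.set_index("frame").loc[common]
        return cls(
            pair_id=pair_id or f"{id1}+{id2}",
            genotype=genotype,
            frames=common,
            times_min=s1["time_min"].to_numpy(),
            xy1=s1[["x_um", "y_um"]].to_numpy(),
            xy2=s2[["x_um", "y_um"]].to_numpy(),
            birth_frame=birth_frame,
        )


def center_pair(pair: CellPairRecord) -> CellPairRecord:
    """Center the pair on its per-frame centroid (translation removed)."""
    mid = 0.5 * (pair.xy1 + pair.xy2)
    return replace(pair, xy1=pair.xy1 - mid, xy2=pair.xy2 - mid)


def _wrap_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Map angles to the principal branch (-180, 180]."""
    wrapped = -((-np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0)
    return wrapped if np.ndim(angle) else float(wrapped)


def positional_angle(pair: CellPairRecord, index: int) -> float:
    """Angle (deg) of the cell-1 -> cell-2 axis vs +x at frame ``index``."""
    v = pair.xy2[index] - pair.xy1[index]
    if np.hypot(*v) == 0.0:
        raise UndefinedAngleError(f"coincident centroids at frame index {index}")
    return _wrap_deg(math.degrees(math.atan2(v[1], v[0])))


@dataclass
class AngleSeries:
    """Per-frame positional angle and its unwrapped cumulative statistics.

    ``dalpha[t]`` is the frame-to-frame change mapped to the minimal
    representative in (-180, 180] — no rotation is assumed to exceed
    180 deg between consecutive frames.  ``cumulative`` starts at 0,
    ``turn = |cumulative|`` and ``arc`` accumulates ``|dalpha|``, so
    ``turn <= arc`` everywhere with equality only for angularly
    monotone trajectories.
    """

    times_min: np.ndarray
    alpha: np.ndarray
    dalpha: np.ndarray
    cumulative: np.ndarray
    turn: np.ndarray
    arc: np.ndarray

    @property
    def final_cumulative(self) -> float:
        return float(self.cumulative[-1])

    @property
    def final_turn(self) -> float:
        return float(self.turn[-1])

    @property
    def final_arc(self) -> float:
        return float(self.arc[-1])


def angle_series(pair: CellPairRecord) -> AngleSeries:
    """Unwrap the positional angle of a (centered or raw) pair."""
    v = pair.xy2 - pair.xy1
    norms = np.hypot(v[:, 0], v[:, 1])
    if np.any(norms == 0.0):
        bad = int(np.argmax(norms == 0.0))
        raise UndefinedAngleError(f"coincident centroids at frame index {bad}")
    alpha = _wrap_deg(np.degrees(np.arctan2(v[:, 1], v[:, 0])))
    dalpha = _wrap_deg(np.diff(alpha))
    cumulative = np.concatenate([[0.0], np.cumsum(dalpha)])
    return AngleSeries(
        times_min=pair.times_min.copy(),
        alpha=alpha,
        dalpha=dalpha,
        cumulative=cumulative,
        turn=np.abs(cumulative),
        arc=np.concatenate([[0.0], np.cumsum(np.abs(dalpha))]),
    )


def logistic4(t, a, b, c, d):
    """Four-parameter logistic ``c + (d - c) / (1 + exp(-b (t - a)))``."""
    t = np.asarray(t, dtype=float)
    # clip the exponent for numerical safety far from the midpoint
    z = np.clip(-b * (t - a), -700.0, 700.0)
    return c + (d - c) / (1.0 + np.exp(z))


@dataclass
class LogisticFit:
    """Fitted 4PL with tangent-intersection phase boundaries.

    ``a`` is the midpoint time (min), ``b`` the steepness (1/min), ``c``
    and ``d_high`` the low and high asymptotes (deg).  ``ic``/``id_``
    are the times where the tangent through the inflection point meets
    the asymptotes; they delimit the active-rotation phase.
    """

    a: float
    b: float
    c: float
    d_high: float
    ic: float
    id_: float
    residual_rms: float
    success: bool = True
    clamped: bool = False
    message: str = ""


def phase_boundaries(fit: LogisticFit | tuple, t_range: tuple[float, float] | None = None):
    """Tangent-intersection phase boundary times ``(Ic, Id)``.

    The tangent at the inflection point ``t = a`` has slope
    ``b (d - c) / 4``; intersecting it with the asymptotes ``y = c`` and
    ``y = d`` gives ``Ic = a - 2/b`` and ``Id = a + 2/b``.  When a time
    range is supplied the boundaries are clamped to it and flagged.
    """
    if isinstance(fit, LogisticFit):
        a, b = fit.a, fit.b
    else:
        a, b = fit[0], fit[1]
    if b <= 0:
        raise ValueError("phase boundaries require steepness b > 0")
    ic, id_ = a - 2.0 / b, a + 2.0 / b
    clamped = False
    if t_range is not None:
        lo, hi = t_range
        ic_c, id_c = min(max(ic, lo), hi), min(max(id_, lo), hi)
        clamped = (ic_c != ic) or (id_c != id_)
        ic, id_ = ic_c, id_c
    return ic, id_, clamped


_B_STARTS = (0.01, 0.05, 0.1, 0.5)


def fit_phase_logistic(series: AngleSeries, times: np.ndarray | None = None) -> LogisticFit:
    """Least-squares 4PL fit to the cumulative angle.

    Deterministic multi-start: midpoint ``a`` over the observed time
    quartiles, steepness ``b`` over a fixed grid, asymptotes from the
    first/last decile means.  The best fit is the lowest residual RMS,
    ties broken by the lowest ``b``.  Degenerate series (no angular
    range) are reported as failures rather than fitted.
    """
    t = np.asarray(series.times_min if times is None else times, dtype=float)
    y = np.asarray(series.cumulative, dtype=float)
    if len(t) < 10:
        return LogisticFit(*(np.nan,) * 7, success=False, message="fewer than 10 frames")
    span = float(np.max(y) - np.min(y))
    if span < 1e-9:
        return LogisticFit(*(np.nan,) * 7, success=False, message="constant series; b unidentifiable")

    k = max(1, len(y) // 10)
    c0, d0 = float(np.mean(y[:k])), float(np.mean(y[-k:]))
    if abs(d0 - c0) < 1e-9:  # ends coincide; fall back to extremes
        c0, d0 = float(y[0]), float(y[np.argmax(np.abs(y - y[0]))])
    t_lo, t_hi = float(np.min(t)), float(np.max(t))
    a_starts = np.quantile(t, (0.25, 0.5, 0.75))

    sign = 1.0 if d0 >= c0 else -1.0
    # bounds keep b positive (orientation carried by c/d) and a in range
    lower = [t_lo - (t_hi - t_lo), 1e-6, -np.inf, -np.inf]
    upper = [t_hi + (t_hi - t_lo), 100.0, np.inf, np.inf]

    best: LogisticFit | None = None
    for a0 in a_starts:
        for b0 in _B_STARTS:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", optimize.OptimizeWarning)
                    popt, _ = optimize.curve_fit(
                        logistic4,
                        t,
                        y,
                        p0=[float(a0), b0, c0, d0],
                        bounds=(lower, upper),
                        maxfev=5000,
                    )
            except (RuntimeError, ValueError):
                continue
            a, b, c, d = (float(v) for v in popt)
            rms = float(np.sqrt(np.mean((logistic4(t, a, b, c, d) - y) ** 2)))
            cand = LogisticFit(a, b, c, d, np.nan, np.nan, rms)
            if (
                best is None
                or rms < best.residual_rms - 1e-12
                or (abs(rms - best.residual_rms) <= 1e-12 and b < best.b)
            ):
                best = cand
    if best is None:
        return LogisticFit(*(np.nan,) * 7, success=False, message="no start converged")
    ic, id_, clamped = phase_boundaries(best, (t_lo, t_hi))
    best.ic, best.id_, best.clamped = ic, id_, clamped
    # orientation sanity: asymptote order must match the rotation sense
    if sign * (best.d_high - best.c) < 0:
        best.message = "asymptote order opposite to rotation sense"
    return best


def classify_inversion(series: AngleSeries, critical_angle_deg: float = 90.0) -> bool:
    """Inversion iff the final absolute cumulative angle strictly exceeds
    the critical angle (90 deg by default; exactly 90 is not an inversion)."""
    return abs(series.final_cumulative) > critical_angle_deg


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Unit-vector mean direction in (-180, 180]."""
    rad = np.radians(np.asarray(angles_deg, dtype=float))
    return _wrap_deg(math.degrees(math.atan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))))


def start_final_angles(series: AngleSeries, n_obs: int = 10) -> tuple[float, float, bool]:
    """Circular means of the first/last ``n_obs`` positional angles.

    Returns ``(starting, final, short)``; ``short`` flags series with
    fewer than ``n_obs`` observations, for which all frames were used.
    """
    short = len(series.alpha) < n_obs
    k = len(series.alpha) if short else n_obs
    return circular_mean_deg(series.alpha[:k]), circular_mean_deg(series.alpha[-k:]), short


def overshoot(series: AngleSeries) -> float:
    """Maximal turn minus final turn (deg, >= 0)."""
    return float(np.max(series.turn) - series.final_turn)


def wobbling(series: AngleSeries) -> float:
    """Arc length minus final turn (deg, >= 0): the summed back-and-forth
    swings superimposed on the net rotation."""
    return float(series.final_arc - series.final_turn)


@dataclass
class NoiseResult:
    value: float | None
    excluded: bool
    reason: str = ""
    path_um: tuple[float, float] = (np.nan, np.nan)
    chord_um: tuple[float, float] = (np.nan, np.nan)


def trajectory_noise(pair: CellPairRecord, config: RunConfig | None = None) -> NoiseResult:
    """Path/chord ratio of the centered sibling trajectories (>= 1).

    Only the first ``noise_frame_cap`` frames enter; pairs where either
    cell's net displacement over that window is below
    ``min_displacement_um`` are excluded.  Aggregation over the two
    cells follows ``config.noise_aggregation`` (pooled ratio of summed
    paths to summed chords by default; per-cell-ratio mean optional).
    """
    config = config or RunConfig()
    n = min(pair.n_frames, config.noise_frame_cap)
    paths, chords = [], []
    for xy in (pair.xy1, pair.xy2):
        seg = np.diff(xy[:n], axis=0)
        paths.append(float(np.sum(np.hypot(seg[:, 0], seg[:, 1]))))
        chords.append(float(np.hypot(*(xy[n - 1] - xy[0]))))
    for j, chord in enumerate(chords):
        if chord < config.min_displacement_um:
            return NoiseResult(
                None,
                True,
                f"cell {j + 1} net displacement {chord:.3g} um < "
                f"{config.min_displacement_um:g} um",
                tuple(paths),
                tuple(chords),
            )
    total_chord = sum(chords)
    if total_chord == 0:
        raise ZeroDivisionError("zero total chord on a non-excluded pair")
    if config.noise_aggregation == "pooled":
        value = sum(paths) / total_chord
    else:
        value = 0.5 * (paths[0] / chords[0] + paths[1] / chords[1])
    return NoiseResult(float(value), False, "", tuple(paths), tuple(chords))


def handedness(series: AngleSeries) -> str | None:
    """``"CCW"`` for a positive final cumulative angle, ``"CW"`` for a
    negative one, ``None`` when the net rotation is exactly zero."""
    s = series.final_cumulative
    if s > 0:
        return "CCW"
    if s < 0:
        return "CW"
    return None


def normalize_angle_0_180(angle_deg: float | np.ndarray):
    """Undirected-axis reduction of an angle to [0, 180)."""
    out = np.asarray(angle_deg, dtype=float) % 180.0
    return out if np.ndim(angle_deg) else float(out)


def final_angle_first_quadrant(pos_cell0, pos_cell1) -> float:
    """Deviation (deg, in [0, 90]) of the undirected inter-cell axis from
    the anteroposterior axis, via absolute vector components — the cell
    labelling is irrelevant."""
    v = np.asarray(pos_cell0, dtype=float) - np.asarray(pos_cell1, dtype=float)
    if np.hypot(*v) == 0.0:
        raise UndefinedAngleError("coincident positions give no axis")
    return math.degrees(math.atan2(abs(v[1]), abs(v[0])))


@dataclass
class RotationMetrics:
    """All per-pair scalar rotation statistics."""

    pair_id: str
    genotype: str
    starting_angle: float
    final_angle: float
    final_turn: float
    final_cumulative: float
    max_turn: float
    overshoot: float
    wobbling: float
    noise: float | None
    noise_excluded: bool
    handedness: str | None
    inverting: bool
    final_angle_axis: float  # first-quadrant deviation of the final axis
    onset: float | None = None  # Ic - birth time
    duration: float | None = None  # Id - Ic
    termination: float | None = None  # Id
    fit: LogisticFit | None = field(default=None, repr=False)
    short_angle_window: bool = False

    def to_row(self) -> dict:
        row = {
            k: getattr(self, k)
            for k in (
                "pair_id",
                "genotype",
                "starting_angle",
                "final_angle",
                "final_turn",
                "final_cumulative",
                "max_turn",
                "overshoot",
                "wobbling",
                "noise",
                "noise_excluded",
                "handedness",
                "inverting",
                "final_angle_axis",
                "onset",
                "duration",
                "termination",
                "short_angle_window",
            )
        }
        if self.fit is not None and self.fit.success:
            row.update(
                fit_a=self.fit.a,
                fit_b=self.fit.b,
                fit_c=self.fit.c,
                fit_d=self.fit.d_high,
                fit_ic=self.fit.ic,
                fit_id=self.fit.id_,
                fit_rms=self.fit.residual_rms,
                fit_clamped=self.fit.clamped,
            )
        else:
            row.update(
                fit_a=np.nan, fit_b=np.nan, fit_c=np.nan, fit_d=np.nan,
                fit_ic=np.nan, fit_id=np.nan, fit_rms=np.nan, fit_clamped=False,
            )
        return row


def compute_rotation_metrics(pair: CellPairRecord, config: RunConfig | None = None) -> RotationMetrics:
    """Run the full kinematic pipeline on one pair."""
    config = config or RunConfig()
    centered = center_pair(pair)
    series = angle_series(centered)
    inverting = classify_inversion(series, config.critical_angle_deg)
    start, final, short = start_final_angles(series)
    noise = trajectory_noise(centered, config)
    fit = fit_phase_logistic(series) if inverting else None
    onset = duration = termination = None
    if fit is not None and fit.success:
        onset = fit.ic - pair.birth_time_min
        duration = fit.id_ - fit.ic
        termination = fit.id_
    return RotationMetrics(
        pair_id=pair.pair_id,
        genotype=pair.genotype,
        starting_angle=start,
        final_angle=final,
        final_turn=series.final_turn,
        final_cumulative=series.final_cumulative,
        max_turn=float(np.max(series.turn)),
        overshoot=overshoot(series),
        wobbling=wobbling(series),
        noise=noise.value,
        noise_excluded=noise.excluded,
        handedness=handedness(series),
        inverting=inverting,
        final_angle_axis=final_angle_first_quadrant(centered.xy1[-1], centered.xy2[-1]),
        onset=onset,
        duration=duration,
        termination=termination,
        fit=fit,
        short_angle_window=short,
    )


def metrics_table(metrics: list[RotationMetrics]) -> pd.DataFrame:
    return pd.DataFrame([m.to_row() for m in metrics])


def _clean(values) -> np.ndarray:
    arr = np.asarray(pd.to_numeric(pd.Series(values), errors="coerce"), dtype=float)
    return arr[np.isfinite(arr)]


def compare_genotypes(
    tables: dict[str, pd.DataFrame], reference: str = "wild-type", min_n: int = 3
) -> dict:
    """Pairwise statistical comparison of per-genotype metrics tables.

    Against the reference group, each other group is compared with:

    * inversion frequency — two-sided exact binomial test of the group's
      inversion count against the reference frequency;
    * trajectory noise — k=2 Anderson-Darling test (two-sided) and a
      one-sided Wilcoxon-Mann-Whitney test of the alternative that the
      reference noise is stochastically less than the group's;
    * onset / duration / final turn — unpaired two-sided Student t-tests;
    * final axis angle — two-sided two-sample Kolmogorov-Smirnov test.

    Groups with fewer than ``min_n`` observations for a quantity are
    skipped for that comparison, with the reason recorded.
    """
    if reference not in tables:
        raise KeyError(f"reference group {reference!r} not among {list(tables)}")
    if len(tables) < 2:
        raise ValueError("need at least two groups to compare")
    ref = tables[reference]
    report: dict = {"reference": reference, "comparisons": {}}
    ref_inv = ref["inverting"].astype(bool)
    ref_freq = float(ref_inv.mean()) if len(ref_inv) else np.nan
    report["inversion_frequency"] = {
        g: float(df["inverting"].astype(bool).mean()) if len(df) else np.nan
        for g, df in tables.items()
    }
    for group, df in tables.items():
        if group == reference:
            continue
        comp: dict = {}
        inv = df["inverting"].astype(bool)
        if len(inv) >= min_n and len(ref_inv) >= min_n and 0.0 < ref_freq < 1.0:
            bt = stats.binomtest(int(inv.sum()), len(inv), ref_freq, alternative="two-sided")
            comp["inversion_binomial"] = {
                "test": "two-sided exact binomial vs reference frequency",
                "k": int(inv.sum()),
                "n": len(inv),
                "p_null": ref_freq,
                "p_value": float(bt.pvalue),
            }
        else:
            comp["inversion_binomial"] = {"skipped": "insufficient group size or degenerate reference"}
        a, b = _clean(ref.get("noise", [])), _clean(df.get("noise", []))
        if len(a) >= min_n and len(b) >= min_n:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ad = stats.anderson_ksamp([a, b])
            wmw = stats.mannwhitneyu(a, b, alternative="less")
            comp["noise"] = {
                "anderson_darling": {
                    "test": "k-sample Anderson-Darling (two-sided)",
                    "statistic": float(ad.statistic),
                    "p_value": float(ad.significance_level),
                },
                "wilcoxon_mann_whitney": {
                    "test": "one-sided WMW, alternative: reference stochastically less",
                    "statistic": float(wmw.statistic),
                    "p_value": float(wmw.pvalue),
                },
            }
        else:
            comp["noise"] = {"skipped": f"need >= {min_n} noise values per group"}
        for col in ("onset", "duration", "final_turn"):
            a, b = _clean(ref.get(col, [])), _clean(df.get(col, []))
            if len(a) >= min_n and len(b) >= min_n:
                tt = stats.ttest_ind(a, b)
                comp[col] = {
                    "test": "unpaired two-sided Student t-test",
                    "statistic": float(tt.statistic),
                    "p_value": float(tt.pvalue),
                }
            else:
                comp[col] = {"skipped": f"need >= {min_n} values per group"}
        a, b = _clean(ref.get("final_angle_axis", [])), _clean(df.get("final_angle_axis", []))
        if len(a) >= min_n and len(b) >= min_n:
            ks = stats.ks_2samp(a, b)
            comp["final_angle"] = {
                "test": "two-sided two-sample Kolmogorov-Smirnov",
                "statistic": float(ks.statistic),
                "p_value": float(ks.pvalue),
            }
        else:
            comp["final_angle"] = {"skipped": f"need >= {min_n} values per group"}
        report["comparisons"][group] = comp
    return report


def render_report(report: dict) -> str:
    """Human-readable text rendering of a `compare_genotypes` report."""
    lines = [f"Reference group: {report['reference']}", ""]
    lines.append("Inversion frequency:")
    for g, f in report["inversion_frequency"].items():
        lines.append(f"  {g}: {f:.3f}" if np.isfinite(f) else f"  {g}: n/a")
    for group, comp in report["comparisons"].items():
        lines.append("")
        lines.append(f"{report['reference']} vs {group}:")
        for name, res in comp.items():
            if "skipped" in res:
                lines.append(f"  {name}: skipped ({res['skipped']})")
            elif name == "noise":
                ad, wmw = res["anderson_darling"], res["wilcoxon_mann_whitney"]
                lines.append(f"  noise AD ({ad['test']}): p = {ad['p_value']:.4g}")
                lines.append(f"  noise WMW ({wmw['test']}): p = {wmw['p_value']:.4g}")
            else:
                lines.append(f"  {name} ({res['test']}): p = {res['p_value']:.4g}")
    return "\n".join(lines) + "\n"
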