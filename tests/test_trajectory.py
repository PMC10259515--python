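import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dyadrot import trajectory as T
from dyadrot.config import RunConfig
from dyadrot.synth import PairSynthesisParams, generate_pair_tracks


def make_pair(xy1, xy2, times=None):
    xy1, xy2 = np.atleast_2d(xy1), np.atleast_2d(xy2)
    n = len(xy1)
    return T.CellPairRecord(
        pair_id="p",
        genotype="synthetic",
        frames=np.arange(n),
        times_min=np.arange(n, dtype=float) * 10 / 3 if times is None else np.asarray(times),
        xy1=xy1,
        xy2=xy2,
    )


def pair_from_angles(alpha_deg, radius=4.0):
    rad = np.radians(np.asarray(alpha_deg, dtype=float))
    u = np.column_stack([np.cos(rad), np.sin(rad)])
    return make_pair(-radius * u, radius * u)


class TestCenterPair:
    def test_simple_example(self):
        c = T.center_pair(make_pair([[1, 0], [1, 0]], [[3, 0], [3, 0]]))
        np.testing.assert_allclose(c.xy1, [[-1, 0], [-1, 0]])
        np.testing.assert_allclose(c.xy2, [[1, 0], [1, 0]])

    def test_centered_positions_sum_to_zero(self, rng):
        p = make_pair(rng.normal(size=(20, 2)), rng.normal(size=(20, 2)))
        c = T.center_pair(p)
        np.testing.assert_allclose(c.xy1 + c.xy2, 0.0, atol=1e-12)

    def test_translation_invariance(self, rng):
        xy1, xy2 = rng.normal(size=(15, 2)), rng.normal(size=(15, 2))
        drift = np.outer(np.arange(15), [0.3, -0.2])
        c0 = T.center_pair(make_pair(xy1, xy2))
        c1 = T.center_pair(make_pair(xy1 + drift, xy2 + drift))
        np.testing.assert_allclose(c0.xy1, c1.xy1, atol=1e-12)


class TestPositionalAngle:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [((-1, 0), (1, 0), 0.0), ((0, -1), (0, 1), 90.0), ((1, 1), (-1, -1), -135.0)],
    )
    def test_examples(self, p1, p2, expected):
        pair = make_pair([p1, p1], [p2, p2])
        assert T.positional_angle(pair, 0) == pytest.approx(expected)

    def test_coincident_centroids_raise(self):
        pair = make_pair([[1, 1], [0, 0]], [[1, 1], [2, 2]])
        with pytest.raises(T.UndefinedAngleError):
            T.positional_angle(pair, 0)


def wrap_oracle(prev, cur):
    """Enumerate candidate representatives of cur-prev; keep |d| < 180
    (or exactly 180 on the positive branch)."""
    cands = [cur - prev + k * 360.0 for k in (-2, -1, 0, 1, 2)]
    ok = [d for d in cands if -180.0 < d <= 180.0]
    assert len(ok) == 1
    return ok[0]


class TestAngleSeries:
    def test_monotone_example(self):
        s = T.angle_series(pair_from_angles([0, 10, 20]))
        np.testing.assert_allclose(s.dalpha, [10, 10])
        assert s.final_cumulative == pytest.approx(20.0)

    def test_branch_crossing_wraps_small(self):
        s = T.angle_series(pair_from_angles([175, -175]))
        assert s.dalpha[0] == pytest.approx(wrap_oracle(175, -175)) == pytest.approx(10.0)

    def test_clockwise_sign(self):
        s = T.angle_series(pair_from_angles([20, 10, 0]))
        assert s.final_cumulative == pytest.approx(-20.0)

    @given(st.lists(st.floats(-720, 720), min_size=2, max_size=30))
    def test_wrap_matches_oracle_and_turn_bounded_by_arc(self, angles):
        s = T.angle_series(pair_from_angles(angles))
        for i, d in enumerate(s.dalpha):
            a_prev = np.radians(angles[i])
            a_cur = np.radians(angles[i + 1])
            # compare on the circle: representative angles mod 360
            expect = wrap_oracle(np.degrees(a_prev) % 360.0, np.degrees(a_cur) % 360.0)
            assert d == pytest.approx(expect, abs=1e-9)
        assert np.all(s.turn <= s.arc + 1e-12)

    def test_rigid_rotation_shifts_angles_only(self, rng):
        angles = np.cumsum(rng.normal(0, 15, size=40))
        base = T.angle_series(pair_from_angles(angles))
        rot = T.angle_series(pair_from_angles(angles + 77.0))
        assert rot.final_turn == pytest.approx(base.final_turn)
        assert T.wobbling(rot) == pytest.approx(T.wobbling(base))
        assert T.overshoot(rot) == pytest.approx(T.overshoot(base))

    def test_mirror_reflection_negates_cumulative(self, rng):
        angles = np.cumsum(rng.normal(0, 20, size=30)) + 5.0
        p = pair_from_angles(angles)
        mirrored = make_pair(p.xy1 * [1, -1], p.xy2 * [1, -1])
        s, sm = T.angle_series(p), T.angle_series(mirrored)
        np.testing.assert_allclose(sm.cumulative, -s.cumulative, atol=1e-9)
        if T.handedness(s) is not None:
            assert {T.handedness(s), T.handedness(sm)} == {"CW", "CCW"}


class TestLogisticFit:
    def test_noise_free_round_trip(self):
        t = np.arange(150) * 10 / 3
        y = T.logistic4(t, 100.0, 0.08, 0.0, 170.0)
        series = T.angle_series(pair_from_angles(y))
        # the cumulative series is the curve shifted to start at 0
        fit = T.fit_phase_logistic(series, t)
        assert fit.success
        assert fit.a == pytest.approx(100.0, rel=0.01)
        assert fit.b == pytest.approx(0.08, rel=0.01)
        offset = float(y[0])
        assert fit.c + offset == pytest.approx(0.0, abs=0.01 * 170)
        assert fit.d_high + offset == pytest.approx(170.0, rel=0.01)

    def test_negative_rotation_fits(self):
        t = np.arange(120) * 10 / 3
        y = T.logistic4(t, 90.0, 0.1, 0.0, -160.0)
        fit = T.fit_phase_logistic(T.angle_series(pair_from_angles(y)), t)
        assert fit.success
        assert fit.d_high - fit.c == pytest.approx(-160.0, rel=0.02)

    def test_constant_series_flags_failure(self):
        series = T.angle_series(pair_from_angles(np.full(30, 12.0)))
        fit = T.fit_phase_logistic(series)
        assert not fit.success
        assert "unidentifiable" in fit.message

    def test_deterministic_restarts(self, rng):
        t = np.arange(100) * 10 / 3
        y = T.logistic4(t, 120.0, 0.06, 0.0, 150.0) + rng.normal(0, 3, size=len(t))
        s = T.angle_series(pair_from_angles(y))
        f1, f2 = T.fit_phase_logistic(s, t), T.fit_phase_logistic(s, t)
        assert (f1.a, f1.b, f1.c, f1.d_high) == (f2.a, f2.b, f2.c, f2.d_high)

    def test_short_series_rejected(self):
        s = T.angle_series(pair_from_angles([0, 10, 30, 60, 90]))
        assert not T.fit_phase_logistic(s).success


class TestPhaseBoundaries:
    def tangent_oracle(self, a, b, c, d):
        """Numerically intersect the inflection tangent with the asymptotes."""
        slope = b * (d - c) / 4.0
        f_a = c + (d - c) / 2.0
        ic = a + (c - f_a) / slope
        id_ = a + (d - f_a) / slope
        return ic, id_

    @pytest.mark.parametrize("a,b", [(100.0, 0.1), (100.0, 0.05), (40.0, 0.02), (250.0, 0.5)])
    def test_closed_form_matches_tangent_intersection(self, a, b):
        ic, id_, _ = T.phase_boundaries((a, b))
        oic, oid = self.tangent_oracle(a, b, 0.0, 170.0)
        assert ic == pytest.approx(oic, rel=1e-9)
        assert id_ == pytest.approx(oid, rel=1e-9)
        assert ic == pytest.approx(a - 2.0 / b, rel=1e-12)

    def test_duration_is_four_over_b(self):
        ic, id_, _ = T.phase_boundaries((100.0, 0.05))
        assert id_ - ic == pytest.approx(80.0)

    def test_step_limit(self):
        ic, id_, _ = T.phase_boundaries((100.0, 1e9))
        assert ic == pytest.approx(100.0, abs=1e-6)
        assert id_ == pytest.approx(100.0, abs=1e-6)

    def test_nonpositive_steepness_rejected(self):
        with pytest.raises(ValueError):
            T.phase_boundaries((100.0, 0.0))

    def test_clamping_flag(self):
        ic, id_, clamped = T.phase_boundaries((100.0, 0.01), t_range=(0.0, 150.0))
        assert clamped and ic == 0.0 and id_ == 150.0


class TestClassification:
    @pytest.mark.parametrize("final,expected", [(150, True), (60, False), (-120, True)])
    def test_critical_angle(self, final, expected):
        s = T.angle_series(pair_from_angles(np.linspace(0, final, 60)))
        assert T.classify_inversion(s) is expected

    def test_exactly_ninety_is_not_inverting(self):
        # strict ">" at the critical angle: build the cumulative exactly
        cum = np.linspace(0.0, 90.0, 10)
        cum[-1] = 90.0
        s = T.AngleSeries(
            times_min=np.arange(10.0),
            alpha=cum,
            dalpha=np.diff(cum),
            cumulative=cum,
            turn=np.abs(cum),
            arc=np.abs(cum),
        )
        assert s.final_cumulative == 90.0
        assert T.classify_inversion(s) is False
        s.cumulative[-1] = np.nextafter(90.0, 100.0)
        assert T.classify_inversion(s) is True

    @pytest.mark.parametrize("cum,expected", [(150, "CCW"), (-150, "CW")])
    def test_handedness(self, cum, expected):
        s = T.angle_series(pair_from_angles(np.linspace(0, cum, 40)))
        assert T.handedness(s) == expected

    def test_zero_net_rotation_has_no_handedness(self):
        s = T.angle_series(pair_from_angles([0, 30, 0]))
        assert T.handedness(s) is None


class TestStartFinalAngles:
    def test_constant_series(self):
        s = T.angle_series(pair_from_angles(np.full(25, 30.0)))
        start, final, short = T.start_final_angles(s)
        assert (start, final) == (pytest.approx(30.0), pytest.approx(30.0))
        assert not short

    def test_start_from_first_ten(self):
        angles = np.concatenate([np.zeros(10), np.linspace(0, 150, 40)])
        start, _, _ = T.start_final_angles(T.angle_series(pair_from_angles(angles)))
        assert start == pytest.approx(0.0, abs=1e-9)

    def test_circular_mean_at_branch(self):
        angles = np.tile([178.0, -178.0], 10)
        start, final, _ = T.start_final_angles(T.angle_series(pair_from_angles(angles)))
        # unit-vector averaging: near 180, never near 0
        assert abs(abs(start) - 180.0) < 1.0
        assert abs(abs(final) - 180.0) < 1.0

    def test_short_series_flagged(self):
        _, _, short = T.start_final_angles(T.angle_series(pair_from_angles([0, 5, 10])))
        assert short


class TestOvershootWobbling:
    def test_monotone_rise_no_overshoot(self):
        s = T.angle_series(pair_from_angles(np.concatenate([np.linspace(0, 180, 50), np.full(20, 180.0)])))
        assert T.overshoot(s) == pytest.approx(0.0, abs=1e-9)
        assert T.wobbling(s) == pytest.approx(0.0, abs=1e-9)

    def test_rise_and_settle(self):
        angles = np.concatenate([np.linspace(0, 200, 50), np.linspace(200, 180, 10)])
        s = T.angle_series(pair_from_angles(angles))
        assert T.overshoot(s) == pytest.approx(20.0)

    def test_full_reversal(self):
        angles = np.concatenate([np.linspace(0, 180, 40), np.linspace(180, 0, 40)])
        s = T.angle_series(pair_from_angles(angles))
        assert T.overshoot(s) == pytest.approx(180.0)
        assert T.wobbling(s) == pytest.approx(360.0)  # arc 360, turn 0

    def test_wobble_example(self):
        s = T.angle_series(pair_from_angles(np.cumsum([0, 10, -10, 180])))
        assert s.final_arc == pytest.approx(200.0)
        assert s.final_turn == pytest.approx(180.0)
        assert T.wobbling(s) == pytest.approx(20.0)


class TestTrajectoryNoise:
    def test_straight_lines_give_exactly_one(self, config):
        t = np.arange(50, dtype=float)
        pair = make_pair(np.column_stack([t * 0.1, t * 0.0]), np.column_stack([-t * 0.1, t * 0.0]))
        res = T.trajectory_noise(pair, config)
        assert res.value == 1.0 and not res.excluded

    def test_zigzag_doubles_path(self, config):
        # each cell advances 0.2 um in x per two frames via +-0.1 um in y:
        # per-frame segment length 0.1*sqrt(2) ... construct exact doubling:
        # move x by +0.1 with alternating y +-d so path = 2 * chord
        n = 101
        x = np.arange(n) * 0.1
        d = np.sqrt(3) * 0.05  # segment 0.1*2 => path double the x-advance
        y = np.where(np.arange(n) % 2 == 1, d * 2, 0.0)
        xy = np.column_stack([x, y - y.mean()])
        seg = np.hypot(np.diff(x), np.diff(y))
        assert np.allclose(seg, 0.2)  # independent summation oracle
        pair = make_pair(xy, -xy)
        res = T.trajectory_noise(pair, config)
        assert res.value == pytest.approx(2.0, rel=1e-9)

    def test_small_displacement_excluded(self, config):
        t = np.arange(30, dtype=float)
        big = np.column_stack([t * 0.2, 0 * t])
        small = np.column_stack([t * 0.05, 0 * t])  # net 1.45 um < 2 um
        res = T.trajectory_noise(make_pair(big, small), config)
        assert res.excluded and res.value is None
        assert "net displacement" in res.reason

    def test_frame_cap_limits_window(self):
        cfg = RunConfig(noise_frame_cap=10)
        t = np.arange(200, dtype=float)
        xy = np.column_stack([t, 0 * t])
        res = T.trajectory_noise(make_pair(xy, -xy), cfg)
        assert res.chord_um[0] == pytest.approx(9.0)  # frames 0..9

    def test_mean_ratio_mode(self):
        cfg = RunConfig(noise_aggregation="mean_ratio")
        t = np.arange(40, dtype=float)
        xy = np.column_stack([t * 0.2, 0 * t])
        res = T.trajectory_noise(make_pair(xy, -xy), cfg)
        assert res.value == pytest.approx(1.0)


class TestAngleHelpers:
    @pytest.mark.parametrize("angle,expected", [(210.0, 30.0), (350.0, 170.0), (90.0, 90.0)])
    def test_normalize_0_180(self, angle, expected):
        assert T.normalize_angle_0_180(angle) == pytest.approx(expected)
        assert T.normalize_angle_0_180(angle) == pytest.approx(angle % 180.0)

    @pytest.mark.parametrize(
        "p0,p1,expected",
        [((1, 0), (-1, 0), 0.0), ((0, 1), (0, -1), 90.0), ((1, 1), (-1, -1), 45.0)],
    )
    def test_first_quadrant_angle(self, p0, p1, expected):
        assert T.final_angle_first_quadrant(p0, p1) == pytest.approx(expected)
        # the labelling of the two cells must not matter
        assert T.final_angle_first_quadrant(p1, p0) == pytest.approx(expected)


def _metrics_frame(noise, inverting=None, **cols):
    import pandas as pd

    n = len(noise)
    data = {"noise": noise, "inverting": inverting if inverting is not None else [True] * n}
    data.update(cols)
    return pd.DataFrame(data)


def exact_wmw_p(a, b):
    """Exact p-value for the alternative "a stochastically less than b":
    the permutation probability of #{a_i < b_j} at least as large as
    observed, by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    n = len(a)
    u_obs = sum(1 for x in a for y in b if x < y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        grp = pooled[list(comb)]
        rest = np.delete(pooled, list(comb))
        u = sum(1 for x in grp for y in rest if x < y) + 0.5 * sum(
            1 for x in grp for y in rest if x == y
        )
        count += u >= u_obs
        total += 1
    return count / total


class TestCompareGenotypes:
    def test_identical_samples_ks_one(self, rng):
        vals = rng.uniform(0, 90, size=20)
        tabs = {
            "wild-type": _metrics_frame(rng.uniform(1, 2, 20), final_angle_axis=vals),
            "emx2-/-": _metrics_frame(rng.uniform(1, 2, 20), final_angle_axis=vals),
        }
        rep = T.compare_genotypes(tabs)
        assert rep["comparisons"]["emx2-/-"]["final_angle"]["statistic"] == 0.0
        assert rep["comparisons"]["emx2-/-"]["final_angle"]["p_value"] == pytest.approx(1.0)

    def test_shifted_sample_wmw_small_p(self, rng):
        a = rng.uniform(1.0, 1.5, size=20)
        b = a + 5.0  # shift beyond the range
        tabs = {"wild-type": _metrics_frame(a), "notch1a-/-": _metrics_frame(b)}
        rep = T.compare_genotypes(tabs)
        p = rep["comparisons"]["notch1a-/-"]["noise"]["wilcoxon_mann_whitney"]["p_value"]
        assert p < 0.01

    def test_wmw_matches_exact_enumeration_small_n(self, rng):
        a = rng.normal(0, 1, size=6)
        b = rng.normal(1.0, 1, size=6)
        from scipy import stats

        p_scipy = stats.mannwhitneyu(a, b, alternative="less", method="exact").pvalue
        assert p_scipy == pytest.approx(exact_wmw_p(a, b), rel=1e-9)

    def test_binomial_point_at_null(self):
        ref = _metrics_frame([1.2] * 40, inverting=[True] * 20 + [False] * 20)
        other = _metrics_frame([1.3] * 40, inverting=[True] * 20 + [False] * 20)
        rep = T.compare_genotypes({"wild-type": ref, "emx2-/-": other})
        assert rep["comparisons"]["emx2-/-"]["inversion_binomial"]["p_value"] == pytest.approx(1.0)

    def test_small_groups_skipped_with_reason(self):
        tabs = {"wild-type": _metrics_frame([1.0, 1.1]), "emx2-/-": _metrics_frame([1.2, 1.3])}
        rep = T.compare_genotypes(tabs)
        assert "skipped" in rep["comparisons"]["emx2-/-"]["noise"]

    def test_report_renders(self, rng):
        tabs = {
            "wild-type": _metrics_frame(rng.uniform(1, 2, 10)),
            "emx2-/-": _metrics_frame(rng.uniform(1, 3, 10)),
        }
        text = T.render_report(T.compare_genotypes(tabs))
        assert "wild-type vs emx2-/-" in text
        assert "WMW" in text


class TestCohortPipeline:
    def test_synthetic_pair_metrics_end_to_end(self, config):
        params = PairSynthesisParams(wobble_sd_deg=2.0, seed=4)
        table = generate_pair_tracks(params)
        rec = T.CellPairRecord.from_track_table(table, "cell_a", "cell_b")
        m = T.compute_rotation_metrics(rec, config)
        assert m.inverting
        assert m.final_turn > 150
        assert m.noise is not None and m.noise >= 1.0
        assert m.fit is not None and m.fit.success
        assert m.onset is not None and m.duration == pytest.approx(
            4.0 / m.fit.b, rel=1e-6
        )
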