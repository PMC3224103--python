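"""Dial planning: inverse equation, feasibility search, curves, surfaces."""

import warnings

import numpy as np
import pytest

from washin import (
    DialSolveError,
    TargetSpec,
    ValidityWarning,
    fa_surface,
    iso_target_curve,
    min_feasible_fgf,
    predict_fa,
    round_to_dial,
    solve_dial,
)


class TestSolveDial:
    def test_printed_hand_evaluations(self):
        # frozen hand evaluations of the published dial expression
        target = TargetSpec(fat=4.5, time_min=5.0, height_cm=176.0)
        assert solve_dial(0.8, target, mode="printed") == pytest.approx(
            17.105308, abs=1e-5)
        assert solve_dial(0.7, target, mode="printed") == pytest.approx(
            19.200107, abs=1e-5)  # > 18: infeasible at this flow

    def test_derived_round_trip_is_identity_on_dial(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            fgf = rng.uniform(0.5, 5.0)
            dial = rng.uniform(6.0, 18.0)
            t = rng.uniform(1.0, 5.0)
            ht = rng.uniform(150.0, 200.0)
            fat = predict_fa(fgf, dial, t, ht, check_validity=False)
            if not 0 < fat <= 8:
                continue
            target = TargetSpec(fat=fat, time_min=t, height_cm=ht)
            assert solve_dial(fgf, target, mode="derived") == pytest.approx(
                dial, abs=1e-9)

    def test_printed_vs_derived_agreement_over_domain(self):
        # the only difference is the rounding of the lumped constants
        fgf = np.arange(0.5, 5.0 + 1e-9, 0.05)
        worst = 0.0
        for t in np.arange(1.0, 5.0 + 1e-9, 0.25):
            for fat in (2.0, 4.5, 8.0):
                for ht in (150.0, 176.0, 200.0):
                    target = TargetSpec(fat=fat, time_min=t, height_cm=ht)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", ValidityWarning)
                        dp = solve_dial(fgf, target, mode="printed")
                        dd = solve_dial(fgf, target, mode="derived")
                    worst = max(worst, float(np.max(np.abs(dp - dd))))
        assert worst <= 0.15

    def test_degenerate_inputs_unsolvable(self):
        target = TargetSpec(fat=4.5, time_min=5.0, height_cm=176.0)
        with pytest.raises(DialSolveError):
            solve_dial(0.0, target)
        with pytest.raises(DialSolveError):
            solve_dial(-1.0, target)

    def test_negative_dial_warns_target_exceeded(self):
        # near-zero target with little time: the carrier term alone overshoots
        target = TargetSpec(fat=0.015, time_min=1.0, height_cm=150.0)
        with pytest.warns(ValidityWarning, match="already exceeded"):
            dial = solve_dial(1.0, target)
        assert dial < 0

    def test_unknown_mode_rejected(self):
        target = TargetSpec(fat=4.5, time_min=5.0, height_cm=176.0)
        with pytest.raises(ValueError):
            solve_dial(1.0, target, mode="exact")


class TestRoundToDial:
    @pytest.mark.parametrize("raw,expected", [
        (17.37, 17.5), (17.24, 17.0), (17.25, 17.5),  # ties round half up
        (0.0, 0.0), (6.74, 6.5), (6.76, 7.0),
    ])
    def test_nearest_half_percent(self, raw, expected):
        assert round_to_dial(raw) == expected

    def test_vectorized(self):
        out = round_to_dial(np.array([17.37, 17.24, 17.25]))
        assert np.array_equal(out, [17.5, 17.0, 17.5])

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            round_to_dial(-0.5)


class TestMinFeasibleFgf:
    def test_reference_target_bound(self):
        # lowest flow able to reach 4.5% at 5 min in a 176 cm patient
        target = TargetSpec(fat=4.5, time_min=5.0, height_cm=176.0)
        mff = min_feasible_fgf(target, mode="printed")
        assert 0.7 <= mff <= 0.8

    def test_unbounded_dial_makes_everything_feasible(self):
        target = TargetSpec(fat=4.5, time_min=5.0, height_cm=176.0,
                            dial_max=np.inf)
        assert min_feasible_fgf(target) == 0.5

    def test_absent_when_target_unreachable(self):
        # 8% after 1 min needs a dial above the ceiling at every flow
        target = TargetSpec(fat=8.0, time_min=1.0, height_cm=176.0)
        assert min_feasible_fgf(target) is None

    def test_monotone_in_target_and_time(self):
        def mff(fat, t):
            return min_feasible_fgf(TargetSpec(fat=fat, time_min=t,
                                               height_cm=176.0))
        # higher target concentration -> needs at least as much flow
        for t in (3.0, 5.0):
            values = [mff(fat, t) for fat in (3.0, 4.0, 5.0)]
            assert all(v is not None for v in values)
            assert values == sorted(values)
        # more time available -> lower (or equal) minimum flow
        for fat in (3.5, 4.5):
            assert mff(fat, 3.0) >= mff(fat, 5.0)

    def test_reported_flow_is_always_feasible(self):
        target = TargetSpec(fat=4.5, time_min=5.0, height_cm=176.0)
        mff = min_feasible_fgf(target)
        assert solve_dial(mff, target) <= target.dial_max


class TestIsoTargetCurve:
    def test_points_round_trip_to_target(self):
        target = TargetSpec(fat=4.5, time_min=5.0, height_cm=176.0)
        curve = iso_target_curve(target, fgf_grid=np.arange(0.8, 5.01, 0.2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ValidityWarning)
            fa = predict_fa(curve.fgf, curve.dial, 5.0, 176.0,
                            check_validity=False)
        assert np.allclose(fa, 4.5, atol=1e-6)

    def test_less_time_requires_higher_dial(self):
        grid = np.arange(1.2, 5.01, 0.2)
        c3 = iso_target_curve(TargetSpec(4.5, 3.0, 176.0), fgf_grid=grid)
        c5 = iso_target_curve(TargetSpec(4.5, 5.0, 176.0), fgf_grid=grid)
        assert np.all(c3.dial > c5.dial)

    def test_curve_turns_upward_at_high_flow(self):
        # required dial bottoms out in the low-4 L/min range, then rises
        # again as the flow term cuts delivered agent
        curve = iso_target_curve(TargetSpec(4.5, 5.0, 176.0),
                                 fgf_grid=np.arange(3.0, 5.01, 0.1))
        low = int(np.argmin(curve.dial))
        assert 0 < low < curve.dial.size - 1
        assert curve.dial[-1] > curve.dial[low]

    def test_feasibility_flags_and_min_flow_attached(self):
        curve = iso_target_curve(TargetSpec(4.5, 5.0, 176.0),
                                 fgf_grid=np.arange(0.5, 5.01, 0.1),
                                 mode="printed")
        assert curve.min_feasible_fgf == pytest.approx(0.76, abs=0.011)
        assert np.array_equal(curve.feasible, curve.dial <= 18.0)
        assert not curve.feasible[0]  # 0.5 L/min cannot reach the target


class TestFaSurface:
    def test_single_cell_equals_scalar(self):
        surf = fa_surface(3.0, 176.0, [2.0], [10.0])
        assert surf.fa_matrix.shape == (1, 1)
        assert surf.fa_matrix[0, 0] == predict_fa(2.0, 10.0, 3.0, 176.0)

    def test_shape_and_dial_monotonicity(self):
        fgf = np.arange(0.5, 5.01, 0.5)
        dial = np.arange(6.0, 18.01, 1.0)
        surf = fa_surface(3.0, 176.0, fgf, dial)
        assert surf.fa_matrix.shape == (fgf.size, dial.size)
        assert np.all(np.diff(surf.fa_matrix, axis=1) > 0)

    def test_pointwise_nondecreasing_in_time(self):
        fgf = np.arange(0.5, 5.01, 0.5)
        dial = np.arange(6.0, 18.01, 1.0)
        prev = fa_surface(1.0, 176.0, fgf, dial).fa_matrix
        for t in (2.0, 3.0, 4.0, 5.0):
            cur = fa_surface(t, 176.0, fgf, dial).fa_matrix
            assert np.all(cur > prev)
            prev = cur

    def test_surface_intersection_matches_iso_curve(self):
        # slicing the surface at the target reproduces the iso-target curve
        target = TargetSpec(fat=4.5, time_min=3.0, height_cm=176.0)
        fgf = np.arange(1.2, 5.01, 0.2)
        dial = np.arange(6.0, 30.0, 0.01)  # fine dial grid
        surf = fa_surface(3.0, 176.0, fgf, dial)
        curve = iso_target_curve(target, fgf_grid=fgf)
        for i in range(fgf.size):
            j = int(np.argmin(np.abs(surf.fa_matrix[i] - 4.5)))
            assert dial[j] == pytest.approx(curve.dial[i], abs=0.01)

    def test_rejects_empty_grids(self):
        with pytest.raises(ValueError):
            fa_surface(3.0, 176.0, [], [10.0])
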