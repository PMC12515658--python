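"""Virtual segmentation and the volumetric/spatial validation metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gliosim as g
from gliosim.metrics import threshold_summary


class TestClassifyState:
    def test_window_boundaries_are_inclusive(self, row1):
        u = np.array([0.16, 0.80, 0.012, 0.03, 0.02, 0.90, 0.10, 0.0])
        state = g.StateFields(p=u.reshape(-1, 1, 1), q=np.zeros((8, 1, 1)))
        enh, ede = g.classify_state(state, row1)
        assert enh.ravel().tolist() == [True, True, False, False, False, False, False, False]
        assert ede.ravel().tolist() == [False, False, True, True, True, False, False, False]

    def test_masks_are_disjoint(self, row1):
        rng = np.random.default_rng(3)
        state = g.StateFields(p=rng.uniform(0, 1.2, (6, 6, 3)), q=np.zeros((6, 6, 3)))
        enh, ede = g.classify_state(state, row1)
        assert not np.any(enh & ede)


class TestRelativeChange:
    def test_printed_growth_example(self):
        # 1629 -> 2175 enhancing voxels is a 33.5% increase
        assert round(100 * g.relative_change(2175, 1629), 1) == 33.5

    def test_disappearance_and_doubling(self):
        assert g.relative_change(0, 1700) == -1.0
        assert g.relative_change(3400, 1700) == 1.0
        assert g.relative_change(1700, 1700) == 0.0

    def test_zero_baseline_undefined(self):
        with pytest.raises(ValueError):
            g.relative_change(10, 0)


class TestBestScenario:
    def test_close_match_example(self):
        # closest simulated volume 2167 against observed 2175: ~0.37% error
        v_sims = [1169, 2167, 3495]
        pos, r = g.best_scenario(v_sims, 2175)
        assert pos == 2
        assert abs(r) * 100 == pytest.approx(0.37, abs=0.01)

    def test_large_error_example(self):
        # simulations spanning 2075-7246 against an observed 500: best is
        # still 315% too large
        pos, r = g.best_scenario([2075, 3000, 7246], 500)
        assert pos == 1
        assert r == pytest.approx(3.15)

    def test_tie_breaks_to_lowest_position(self):
        pos, r = g.best_scenario([400, 600], 500)
        assert pos == 1 and r == pytest.approx(-0.2)

    @given(
        st.lists(st.integers(0, 5000), min_size=1, max_size=18),
        st.integers(1, 5000),
    )
    def test_agrees_with_brute_force(self, v_sims, v_obs):
        pos, r = g.best_scenario(v_sims, v_obs)
        best = min(range(len(v_sims)), key=lambda i: (abs(v_sims[i] - v_obs), i))
        assert pos == best + 1
        assert r == pytest.approx((v_sims[best] - v_obs) / v_obs)


def _masks_from_sets(s, r, shape=(40, 5, 2)):
    S = np.zeros(shape, bool)
    R = np.zeros(shape, bool)
    S.ravel()[list(s)] = True
    R.ravel()[list(r)] = True
    return S, R


class TestOverlapScores:
    def test_containing_mask_twice_as_large(self):
        S, R = _masks_from_sets(range(200), range(100), shape=(20, 10, 2))
        sc = g.overlap_scores(S, R)
        assert sc.containment == 1.0
        assert sc.agreement == 0.5

    def test_equal_size_half_overlap(self):
        # equal sizes overlapping in half of each: the union has 3n/2
        # voxels, so agreement is 1/3 while containment is 1/2
        S, R = _masks_from_sets(range(0, 100), range(50, 150), shape=(20, 10, 2))
        sc = g.overlap_scores(S, R)
        assert sc.containment == 0.5
        assert sc.agreement == pytest.approx(1 / 3)

    def test_scores_coincide_only_for_contained_masks(self):
        # A = C < 1 forces S ⊂ R; covering half of R gives A = C = 0.5
        S, R = _masks_from_sets(range(50), range(100), shape=(20, 10, 2))
        sc = g.overlap_scores(S, R)
        assert sc.agreement == sc.containment == 0.5

    def test_perfect_match(self):
        S, R = _masks_from_sets(range(30), range(30))
        sc = g.overlap_scores(S, R)
        assert sc.agreement == 1.0 and sc.containment == 1.0

    def test_empty_observed_mask_rejected(self):
        S, R = _masks_from_sets(range(5), [])
        with pytest.raises(ValueError):
            g.overlap_scores(S, R)

    @given(
        st.sets(st.integers(0, 39), min_size=0, max_size=30),
        st.sets(st.integers(0, 39), min_size=1, max_size=30),
    )
    def test_matches_set_enumeration(self, s, r):
        S, R = _masks_from_sets(s, r, shape=(8, 5, 1))
        sc = g.overlap_scores(S, R)
        inter, union = len(s & r), len(s | r)
        assert sc.intersection == inter and sc.union == union
        assert sc.containment == pytest.approx(inter / len(r))
        assert sc.agreement == pytest.approx(inter / union)
        # algebraic identity linking the two scores
        assert sc.agreement * sc.union == pytest.approx(sc.containment * sc.size_obs)
        assert 0 <= sc.agreement <= sc.containment <= 1


class TestThresholdSummary:
    def test_signed_threshold_directions(self):
        df = threshold_summary([-0.6, -0.3, 0.1, 1.2], thresholds=[-0.25, 1.0])
        by_tau = {row["threshold"]: row["fraction"] for _, row in df.iterrows()}
        assert by_tau["<= -25%"] == 0.5
        assert by_tau[">= +100%"] == 0.25
        assert by_tau["< +0%"] + by_tau[">= +0%"] == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            threshold_summary([])

    @given(
        st.lists(st.floats(-1, 5, allow_nan=False), min_size=1, max_size=20),
        st.integers(2, 4),
    )
    def test_invariant_under_permutation_and_duplication(self, deltas, k):
        base = threshold_summary(deltas)["fraction"].to_numpy()
        shuffled = threshold_summary(list(reversed(deltas)))["fraction"].to_numpy()
        duplicated = threshold_summary(deltas * k)["fraction"].to_numpy()
        assert np.allclose(base, shuffled)
        assert np.allclose(base, duplicated)


class TestEvaluateInterval:
    def test_identity_interval(self, baseline32, scenario_set):
        """A follow-up equal to the baseline over a vanishing interval is
        matched perfectly by the ensemble's initial classifications."""
        followup = g.ImagingStudy(
            grid=baseline32.grid,
            t1c=baseline32.t1c,
            t2=baseline32.t2,
            enhancing_mask=baseline32.enhancing_mask,
            edema_mask=baseline32.edema_mask,
            necrotic_mask=baseline32.necrotic_mask,
            day=30,
        )
        pair = g.StudyPair(baseline32, followup)
        subset = scenario_set.subset([1, 9, 17])  # widest-window scenarios
        results = g.run_ensemble(baseline32, 1e-6, subset)
        report = g.evaluate_interval(pair, results)
        assert report.delta_obs == 0.0
        assert len(report.overlaps) == 3
        # scenario 1 windows generated this phantom: zero-time classification
        # returns exactly the baseline enhancing mask
        assert report.R_best == 0.0
        assert report.best_index == 1
        best = report.overlaps[0]
        assert best.agreement == 1.0 and best.containment == 1.0
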