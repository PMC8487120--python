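import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arcview import (
    AngleProfile,
    adaptive_fs_set,
    adaptive_select,
    no_overlap_set,
    select_for_scene,
    standard_select,
)
from arcview.viewmetrics import default_theta_grid, random_profile

from ._oracles import bruteforce_adaptive


def profile_of(thetas, p_overlap, p_fs):
    return AngleProfile(np.asarray(thetas, float), np.asarray(p_overlap, float),
                        np.asarray(p_fs, float))


TOY = profile_of([0, 45, 90], [0.2, 0.0, 0.1], [0.9, 0.8, 0.7])


class TestStandardSelect:
    def test_corrected_toy_profile(self):
        sel = standard_select(TOY, "corrected")
        # objective = p_overlap + (1 - p_fs) = {0.3, 0.2, 0.4}
        assert sel.theta_standard == 45.0
        assert sel.objective_value == pytest.approx(0.2)

    def test_literal_toy_profile_tie_breaks_low(self):
        # dyadic values so the tie is float-exact:
        # objective = p_overlap + p_fs = {1.0, 0.75, 0.75}: tie at 45 and 90
        dyadic = profile_of([0, 45, 90], [0.5, 0.0, 0.25], [0.5, 0.75, 0.5])
        sel = standard_select(dyadic, "literal")
        assert sel.theta_standard == 45.0
        assert sel.objective_variant == "literal"

    def test_single_active_term(self):
        thetas = np.arange(0.0, 91.0, 1.0)
        p_fs = 1.0 - np.abs(thetas - 40.0) / 100.0
        sel = standard_select(profile_of(thetas, np.zeros_like(thetas), p_fs))
        assert sel.theta_standard == 40.0

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            standard_select(TOY, "bogus")


class TestNoOverlapSet:
    def test_all_zero_returns_whole_grid(self):
        thetas = np.arange(0.0, 91.0, 10.0)
        profile = profile_of(thetas, np.zeros_like(thetas), np.ones_like(thetas))
        assert no_overlap_set(profile) == set(thetas)

    def test_all_positive_returns_empty(self):
        thetas = np.arange(0.0, 91.0, 10.0)
        profile = profile_of(thetas, np.full_like(thetas, 0.01),
                             np.ones_like(thetas))
        assert no_overlap_set(profile) == set()

    def test_contiguous_zero_window(self):
        thetas = np.arange(0.0, 91.0, 1.0)
        p_ov = np.where((thetas >= 30) & (thetas <= 60), 0.0, 0.05)
        profile = profile_of(thetas, p_ov, np.ones_like(thetas))
        assert no_overlap_set(profile) == set(np.arange(30.0, 61.0))


class TestAdaptiveFsSet:
    def test_unique_peak_below_50_gives_singleton(self):
        thetas = np.arange(0.0, 91.0, 1.0)
        p_fs = 1.0 - ((thetas - 45.0) / 90.0) ** 2
        fs_set, fsmin, fsmax, branch = adaptive_fs_set(
            profile_of(thetas, np.zeros_like(thetas), p_fs)
        )
        assert (fs_set, fsmin, branch) == ({45.0}, 45.0, "<=50")
        assert fsmax == p_fs.max()

    def test_peak_between_50_and_60_uses_98_percent_tier(self):
        thetas = np.arange(0.0, 91.0, 1.0)
        p_fs = np.cos(np.radians(thetas - 55.0)) ** 2
        fs_set, fsmin, fsmax, branch = adaptive_fs_set(
            profile_of(thetas, np.zeros_like(thetas), p_fs)
        )
        assert (fsmin, branch) == (55.0, "50-60")
        expected = {float(t) for t, f in zip(thetas, p_fs) if f > 0.98 * fsmax}
        assert fs_set == expected

    def test_peak_above_60_uses_95_percent_tier(self):
        thetas = np.arange(0.0, 91.0, 1.0)
        p_fs = np.cos(np.radians(thetas - 70.0)) ** 2
        fs_set, fsmin, fsmax, branch = adaptive_fs_set(
            profile_of(thetas, np.zeros_like(thetas), p_fs)
        )
        assert (fsmin, branch) == (70.0, ">60")
        assert fs_set == {
            float(t) for t, f in zip(thetas, p_fs) if f > 0.95 * fsmax
        }

    def test_constant_profile_ties_to_smallest_angle(self):
        thetas = np.arange(0.0, 91.0, 1.0)
        fs_set, fsmin, _, branch = adaptive_fs_set(
            profile_of(thetas, np.zeros_like(thetas), np.full_like(thetas, 0.9))
        )
        assert (fs_set, fsmin, branch) == ({0.0}, 0.0, "<=50")


class TestAdaptiveSelect:
    def test_singleton_intersection(self):
        thetas = np.arange(0.0, 91.0, 1.0)
        p_fs = 1.0 - ((thetas - 45.0) / 90.0) ** 2
        sel = adaptive_select(profile_of(thetas, np.zeros_like(thetas), p_fs))
        assert (sel.theta_optimal, sel.fallback_used) == (45.0, "none")

    def test_minimum_of_interval_intersection(self):
        thetas = np.arange(0.0, 91.0, 1.0)
        p_fs = np.where((thetas >= 52) & (thetas <= 58), 1.0, 0.5)
        p_ov = np.where((thetas >= 55) & (thetas <= 70), 0.0, 0.05)
        sel = adaptive_select(profile_of(thetas, p_ov, p_fs))
        # fs tier = {52..58} (fsmin 52, 50-60 branch), no-overlap = {55..70}
        assert sel.theta_optimal == 55.0
        assert sel.fallback_used == "none"

    def test_min_overlap_fallback_tie_rules(self):
        thetas = np.array([0.0, 10.0, 20.0, 30.0])
        p_ov = np.array([0.30, 0.10, 0.10, 0.20])
        p_fs = np.array([0.90, 0.70, 0.80, 0.60])
        sel = adaptive_select(profile_of(thetas, p_ov, p_fs))
        # min overlap tied at 10 and 20; larger p_fs wins
        assert sel.theta_optimal == 20.0
        assert sel.fallback_used == "min-overlap"

    def test_singleton_miss_relaxes_to_tier(self):
        thetas = np.arange(0.0, 91.0, 1.0)
        p_fs = 1.0 - ((thetas - 40.0) / 90.0) ** 2
        p_ov = np.where(thetas == 40.0, 0.1, 0.0)  # only the peak overlaps
        sel = adaptive_select(profile_of(thetas, p_ov, p_fs))
        assert sel.fallback_used == "tier-relaxation"
        assert sel.theta_optimal != 40.0
        assert sel.theta_optimal in sel.theta_no_overlap

    def test_hard_constraint_where_standard_violates_it(self):
        thetas = np.arange(0.0, 91.0, 1.0)
        p_fs = np.exp(-((thetas - 30.0) / 25.0) ** 2)
        p_ov = np.where((thetas >= 60) & (thetas <= 70), 0.0, 0.01)
        profile = profile_of(thetas, p_ov, p_fs)
        std = standard_select(profile)
        ada = adaptive_select(profile)
        i_std = int(np.nonzero(thetas == std.theta_standard)[0][0])
        i_ada = int(np.nonzero(thetas == ada.theta_optimal)[0][0])
        assert profile.p_overlap[i_std] > 0.0  # joint minimum tolerates overlap
        assert profile.p_overlap[i_ada] == 0.0  # adaptive never does

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_bruteforce_oracle(self, seed):
        profile = random_profile(np.random.default_rng(seed))
        sel = adaptive_select(profile)
        theta, fallback, branch = bruteforce_adaptive(
            profile.thetas, profile.p_overlap, profile.p_fs
        )
        assert sel.theta_optimal == theta
        assert sel.fallback_used == fallback
        assert sel.branch == branch

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_overlap_free_whenever_possible_and_tier_bound(self, seed):
        profile = random_profile(np.random.default_rng(seed))
        sel = adaptive_select(profile)
        i = int(np.nonzero(profile.thetas == sel.theta_optimal)[0][0])
        if sel.theta_no_overlap:
            assert sel.fallback_used != "min-overlap"
            assert profile.p_overlap[i] == 0.0
        if sel.fallback_used == "none" and sel.branch in ("50-60", ">60"):
            tier = 0.98 if sel.branch == "50-60" else 0.95
            assert profile.p_fs[i] > tier * sel.p_fsmax


class TestSelectForScene:
    def test_separated_phantom_gives_overlap_free_angle(self, small_scene):
        grid = default_theta_grid(5.0)
        adaptive, standard, profile = select_for_scene(
            small_scene, theta_grid=grid
        )
        i = int(np.nonzero(profile.thetas == adaptive.theta_optimal)[0][0])
        assert profile.p_overlap[i] == 0.0
        assert adaptive.theta_fsmin == 45.0

    def test_coincident_phantom_falls_back_to_min_overlap(self, coincident_scene):
        adaptive, _, _ = select_for_scene(
            coincident_scene, theta_grid=default_theta_grid(1.0)
        )
        assert adaptive.fallback_used == "min-overlap"

    def test_rerun_is_bit_identical(self, small_scene):
        grid = default_theta_grid(10.0)
        a1, s1, p1 = select_for_scene(small_scene, theta_grid=grid)
        a2, s2, p2 = select_for_scene(small_scene, theta_grid=grid)
        assert a1 == a2
        assert s1 == s2
        np.testing.assert_array_equal(p1.p_overlap, p2.p_overlap)
        np.testing.assert_array_equal(p1.p_fs, p2.p_fs)
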