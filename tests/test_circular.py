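"""Circular statistics: resultant vectors, projections, Moore's test, CIs."""

import math

import numpy as np
import pytest
from scipy import special, stats

from fishgaze.circular import (
    ResultantVector,
    bootstrap_direction_ci,
    ci_width_degrees,
    group_mean_vector,
    mean_resultant_vector,
    moore_rank_statistic,
    moores_rayleigh_test,
    project_onto_direction,
)
from fishgaze.errors import InsufficientDataError, ValidationError


class TestMeanResultantVector:
    def test_identical_angles_fully_concentrated(self):
        rv = mean_resultant_vector([90.0, 90.0, 90.0])
        assert rv.alpha == pytest.approx(90.0)
        assert rv.R == pytest.approx(1.0)

    def test_symmetric_angles_flag_undefined_direction(self):
        rv = mean_resultant_vector([0.0, 90.0, 180.0, 270.0])
        assert rv.R == 0.0
        assert not rv.defined

    def test_von_mises_length_matches_bessel_ratio(self):
        # closed form: E[R] -> I1(k)/I0(k) for a von Mises sample
        rng = np.random.default_rng(42)
        draws = np.degrees(rng.vonmises(math.pi, 2.0, size=100_000)) % 360.0
        expected = special.iv(1, 2.0) / special.iv(0, 2.0)
        assert mean_resultant_vector(draws).R == pytest.approx(expected, abs=0.01)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            mean_resultant_vector([])

    @pytest.mark.parametrize("phi", [17.0, 123.4, 300.0])
    def test_rotation_equivariance(self, phi):
        rng = np.random.default_rng(7)
        base = rng.uniform(0, 360, size=50)
        rv0 = mean_resultant_vector(base)
        rv1 = mean_resultant_vector((base + phi) % 360.0)
        assert rv1.R == pytest.approx(rv0.R)
        assert (rv1.alpha - rv0.alpha) % 360.0 == pytest.approx(phi, abs=1e-6)


class TestHypothesisProperties:
    """Invariants over arbitrary angle samples (derandomised)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    angles = st.lists(
        st.floats(min_value=0.0, max_value=359.999), min_size=1, max_size=40
    )

    @given(angles=angles, phi=st.floats(min_value=0.0, max_value=360.0))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_rotation_equivariance_and_bounds(self, angles, phi):
        rv0 = mean_resultant_vector(angles)
        rv1 = mean_resultant_vector([(a + phi) % 360.0 for a in angles])
        assert 0.0 <= rv0.R <= 1.0
        assert rv1.R == pytest.approx(rv0.R, abs=1e-9)
        if rv0.defined and rv0.R > 1e-6:
            assert abs(
                ((rv1.alpha - rv0.alpha - phi) + 180.0) % 360.0 - 180.0
            ) < 1e-3

    @given(angles=angles, direction=st.floats(min_value=0.0, max_value=360.0))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_projection_bounded_by_resultant_length(self, angles, direction):
        rv = mean_resultant_vector(angles)
        proj = project_onto_direction(rv, direction)
        assert abs(proj) <= rv.R + 1e-12


class TestProjection:
    def test_aligned_and_anti_aligned(self):
        assert project_onto_direction(ResultantVector(180.0, 0.5, 10), 180.0) == pytest.approx(0.5)
        assert project_onto_direction(ResultantVector(0.0, 0.5, 10), 180.0) == pytest.approx(-0.5)

    def test_near_aligned_group_vector(self):
        # a group vector at 182.59 deg with R = 0.25 projects to ~0.25
        assert project_onto_direction(ResultantVector(182.59, 0.25, 11), 180.0) == pytest.approx(
            0.2497, abs=5e-4
        )

    def test_undefined_vector_projects_to_zero(self):
        assert project_onto_direction(ResultantVector(None, 0.0, 4), 180.0) == 0.0

    def test_extrema_at_alignment(self):
        rv = ResultantVector(37.0, 0.8, 5)
        projs = [project_onto_direction(rv, d) for d in np.arange(0, 360, 1.0)]
        assert max(projs) == pytest.approx(rv.R, abs=1e-3)
        assert np.argmax(projs) == 37
        assert min(projs) == pytest.approx(-rv.R, abs=1e-3)


class TestGroupMeanVector:
    def test_single_member_identity(self):
        gv = group_mean_vector([ResultantVector(30.0, 0.4, 100)])
        assert gv.alpha_g == pytest.approx(30.0)
        assert gv.R_g == pytest.approx(0.4)

    def test_opposed_members_cancel(self):
        gv = group_mean_vector(
            [ResultantVector(0.0, 1.0, 10), ResultantVector(180.0, 1.0, 10)]
        )
        assert gv.R_g == pytest.approx(0.0, abs=1e-12)

    def test_same_direction_lengths_average(self):
        gv = group_mean_vector(
            [ResultantVector(0.0, 0.2, 10), ResultantVector(0.0, 0.6, 10)]
        )
        assert gv.alpha_g == pytest.approx(0.0)
        assert gv.R_g == pytest.approx(0.4)

    def test_weighting_never_exceeds_largest_member(self):
        rng = np.random.default_rng(11)
        members = [
            ResultantVector(float(rng.uniform(0, 360)), float(rng.uniform(0, 1)), 10)
            for _ in range(8)
        ]
        gv = group_mean_vector(members)
        assert gv.R_g <= max(m.R for m in members) + 1e-12

    def test_matches_pooled_frames_for_equal_counts(self):
        # brute force: with equal frame counts the length-weighted group mean
        # equals the resultant of the pooled per-frame angles
        rng = np.random.default_rng(5)
        frames = [rng.uniform(0, 360, size=40) for _ in range(6)]
        members = [mean_resultant_vector(f) for f in frames]
        gv = group_mean_vector(members)
        pooled = mean_resultant_vector(np.concatenate(frames))
        assert gv.alpha_g == pytest.approx(pooled.alpha, abs=1e-9)
        assert gv.R_g == pytest.approx(pooled.R, abs=1e-12)


class TestMooresTest:
    @staticmethod
    def brute_force_r_star(alphas, lengths):
        # independent recomputation of the rank-weighted statistic
        order = sorted(range(len(lengths)), key=lambda i: lengths[i])
        ranks = [0.0] * len(lengths)
        for rank, i in enumerate(order, start=1):
            ranks[i] = float(rank)
        X = sum(r * math.cos(math.radians(a)) for r, a in zip(ranks, alphas))
        Y = sum(r * math.sin(math.radians(a)) for r, a in zip(ranks, alphas))
        return math.sqrt(X**2 + Y**2) / len(alphas) ** 1.5

    def test_statistic_matches_brute_force(self):
        alphas = np.array([10.0, 200.0, 185.0, 170.0, 355.0, 90.0])
        lengths = np.array([0.3, 0.8, 0.5, 0.9, 0.1, 0.6])
        assert moore_rank_statistic(alphas, lengths) == pytest.approx(
            self.brute_force_r_star(alphas.tolist(), lengths.tolist())
        )

    def test_tied_lengths_use_average_ranks(self):
        alphas = np.array([0.0, 90.0, 180.0, 270.0])
        lengths = np.array([0.5, 0.5, 0.5, 0.5])
        ranks = stats.rankdata(lengths)
        assert np.all(ranks == 2.5)
        # symmetric directions with equal ranks cancel exactly
        assert moore_rank_statistic(alphas, lengths) == pytest.approx(0.0, abs=1e-12)

    def test_concentrated_sample_is_significant(self):
        rng = np.random.default_rng(3)
        members = [
            ResultantVector(180.0, float(r), 50)
            for r in rng.uniform(0.2, 0.9, size=20)
        ]
        res = moores_rayleigh_test(members, n_mc=9999, seed=1)
        assert res.p <= 0.001

    def test_too_few_members_rejected(self):
        members = [ResultantVector(10.0 * i, 0.5, 5) for i in range(3)]
        with pytest.raises(InsufficientDataError):
            moores_rayleigh_test(members)

    def test_rotation_leaves_statistic_and_p_unchanged(self):
        rng = np.random.default_rng(9)
        alphas = rng.uniform(0, 360, size=12)
        lengths = rng.uniform(0.1, 0.9, size=12)
        m0 = [ResultantVector(float(a), float(r), 5) for a, r in zip(alphas, lengths)]
        m1 = [ResultantVector(float((a + 77.0) % 360), float(r), 5) for a, r in zip(alphas, lengths)]
        r0 = moores_rayleigh_test(m0, n_mc=999, seed=4)
        r1 = moores_rayleigh_test(m1, n_mc=999, seed=4)
        assert r1.R_star == pytest.approx(r0.R_star)
        assert r1.p == r0.p

    def test_p_floor_respects_replicate_count(self):
        members = [ResultantVector(180.0, 0.1 * (i + 1), 5) for i in range(8)]
        res = moores_rayleigh_test(members, n_mc=999, seed=0)
        assert res.p >= 1.0 / (999 + 1)


class TestBootstrapCI:
    @staticmethod
    def _clustered_members(kappa, n, seed):
        rng = np.random.default_rng(seed)
        return [
            ResultantVector(float(np.degrees(rng.vonmises(math.pi, kappa)) % 360),
                            float(rng.uniform(0.5, 0.9)), 50)
            for _ in range(n)
        ]

    def test_tight_cluster_gives_narrow_interval_containing_truth(self):
        members = self._clustered_members(kappa=20.0, n=50, seed=21)
        lo, hi = bootstrap_direction_ci(members, conf=0.95, reps=2000, seed=0)
        width = ci_width_degrees((lo, hi))
        assert width < 10.0
        # interval brackets the point estimate and sits near the generative 180
        point = group_mean_vector(members).alpha_g
        assert (point - lo) % 360.0 <= width
        mid = (lo + ((hi - lo) % 360.0) / 2.0) % 360.0
        assert abs((mid - 180.0 + 180.0) % 360.0 - 180.0) < 10.0

    def test_zero_confidence_collapses_to_point(self):
        members = self._clustered_members(kappa=20.0, n=8, seed=22)
        lo, hi = bootstrap_direction_ci(members, conf=0.0, reps=100, seed=0)
        assert lo == hi

    def test_uniform_members_give_unreliably_wide_interval(self):
        rng = np.random.default_rng(23)
        members = [
            ResultantVector(float(rng.uniform(0, 360)), float(rng.uniform(0.3, 0.7)), 50)
            for _ in range(12)
        ]
        lo, hi = bootstrap_direction_ci(members, conf=0.95, reps=2000, seed=0)
        assert ci_width_degrees((lo, hi)) > 90.0
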