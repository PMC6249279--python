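"""Tests for the RMSMD/MSMD metric core: worked example, oracles, properties."""

import math
import warnings

import numpy as np
import pytest
from scipy.stats import ortho_group

from rmsmd import (
    PointSet,
    kernel_msmd,
    kernel_pairs,
    min_dist_decomposition,
    min_sq_dists,
    msmd,
    msmd_via_voronoi,
    rmsmd,
    voronoi_assignment,
)
from rmsmd.metrics import far_point_removal, naive_msmd, sample_triangle_inequality
from rmsmd.experiments import worked_example_sets


@pytest.fixture
def demo():
    s, x = worked_example_sets()
    return s, x


def random_pair(rng, dim=None, max_size=50, scale=1000.0):
    dim = dim or int(rng.integers(1, 5))
    nx, ns = rng.integers(1, max_size + 1, size=2)
    return (
        PointSet(rng.uniform(0, scale, size=(int(nx), dim))),
        PointSet(rng.uniform(0, scale, size=(int(ns), dim))),
    )


class TestWorkedExample:
    """Closed-form values of the 4-emitter / 6-estimate example."""

    def test_directional_min_distances(self, demo):
        s, x = demo
        d2, arg = min_sq_dists(s, x)
        assert d2 == pytest.approx([13600, 14900, 97600, 20000])
        assert list(arg) == [0, 3, 4, 5]

    def test_msmd_value(self, demo):
        s, x = demo
        assert msmd(x, s) == pytest.approx(40740.0)
        assert rmsmd(x, s) == pytest.approx(math.sqrt(40740.0))

    def test_removal_of_far_points(self, demo):
        s, x = demo
        assert msmd(x.remove([1, 2]), s) == pytest.approx(31775.0)

    def test_removal_conditions_and_strict_decrease(self, demo):
        s, x = demo
        dec = min_dist_decomposition(x, s)
        removed_mean = dec.sq_dist_x_to_s[[1, 2]].mean()
        assert removed_mean == pytest.approx(76600.0)
        ok, before, after = far_point_removal(x, s, [1, 2])
        assert ok and after < before
        assert (before, after) == (pytest.approx(40740.0), pytest.approx(31775.0))

    def test_kernel_pairs_and_sets(self, demo):
        s, x = demo
        kp = kernel_pairs(x, s)
        assert kp.pairs == ((0, 0), (3, 1), (5, 3))
        assert kp.kernel_x == (0, 3, 5)
        assert kp.kernel_s == (0, 1, 3)

    def test_kernel_msmd(self, demo):
        s, x = demo
        kp = kernel_pairs(x, s)
        val = kernel_msmd(kp, x, s)
        assert val == pytest.approx(48500.0 / 3.0)
        # equals the plain MSMD of the extracted kernel sets
        assert val == pytest.approx(msmd(x.subset(kp.kernel_x), s.subset(kp.kernel_s)))

    def test_voronoi_memberships(self, demo):
        s, x = demo
        cell_of_x = voronoi_assignment(s, x)  # which s-cell each x is in
        assert [list(np.flatnonzero(cell_of_x == i)) for i in range(len(s))] == [
            [0, 1], [2, 3, 4], [], [5],
        ]
        cell_of_s = voronoi_assignment(x, s)  # which x-cell each s is in
        assert list(cell_of_s) == [0, 3, 4, 5]


class TestSmallCases:
    def test_1d_hand_enumeration(self):
        a = PointSet.from_points([[0.0]])
        b = PointSet.from_points([[1.0], [3.0]])
        d2, arg = min_sq_dists(a, b)
        assert d2 == pytest.approx([1.0]) and arg[0] == 0
        assert msmd(a, b) == pytest.approx(11.0 / 3.0)
        kp = kernel_pairs(a, b)
        assert kp.pairs == ((0, 0),)

    def test_identity(self):
        rng = np.random.default_rng(7)
        x = PointSet(rng.uniform(0, 100, size=(9, 3)))
        assert msmd(x, x) == 0.0
        d2, arg = min_sq_dists(x, x)
        assert np.all(d2 == 0) and list(arg) == list(range(9))
        kp = kernel_pairs(x, x)
        assert kp.pairs == tuple((i, i) for i in range(9))
        assert kernel_msmd(kp, x, x) == 0.0

    def test_duplicates_and_zero_distances_legal(self):
        x = PointSet.from_points([[1, 1], [1, 1], [5, 5]])
        s = PointSet.from_points([[1, 1]])
        assert msmd(x, s) == pytest.approx(32.0 / 4.0)

    def test_voronoi_self_assignment(self):
        s = PointSet.from_points([[0, 0], [10, 0], [0, 10]])
        assert list(voronoi_assignment(s, s)) == [0, 1, 2]

    def test_empty_and_dim_mismatch_errors(self):
        x = PointSet.from_points([[0, 0]])
        s3 = PointSet.from_points([[0, 0, 0]])
        with pytest.raises(ValueError, match="dimension"):
            msmd(x, s3)
        with pytest.raises(ValueError, match="non-empty"):
            msmd(PointSet(np.empty((0, 2))), x)

    def test_removal_cannot_empty_x(self):
        s, x = worked_example_sets()
        with pytest.raises(ValueError, match="empty"):
            far_point_removal(x, s, list(range(len(x))))

    def test_empty_removal_is_vacuous(self):
        s, x = worked_example_sets()
        ok, before, after = far_point_removal(x, s, [])
        assert not ok and before == after


class TestOracleEquivalence:
    """Fast path == naive double loop == Voronoi decomposition."""

    def test_hundred_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            x, s = random_pair(rng)
            ref = naive_msmd(x, s)
            assert msmd(x, s) == pytest.approx(ref, rel=1e-12)
            assert msmd_via_voronoi(x, s) == pytest.approx(ref, rel=1e-12)

    def test_voronoi_assignment_vs_brute_force(self):
        rng = np.random.default_rng(3)
        sites = PointSet(rng.uniform(0, 100, size=(20, 3)))
        pts = PointSet(rng.uniform(0, 100, size=(40, 3)))
        assign = voronoi_assignment(sites, pts)
        for k, p in enumerate(pts.coords):
            d2 = ((sites.coords - p) ** 2).sum(axis=1)
            assert d2[assign[k]] == d2.min()

    def test_kernel_msmd_equals_restricted_msmd_random(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x, s = random_pair(rng, max_size=25)
            kp = kernel_pairs(x, s)
            assert kernel_msmd(kp, x, s) == pytest.approx(
                msmd(x.subset(kp.kernel_x), s.subset(kp.kernel_s)), rel=1e-12
            )


class TestMetricProperties:
    def test_nonnegative_and_zero_on_coincident(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x, s = random_pair(rng, max_size=20)
            assert msmd(x, s) >= 0.0
        # every point of each set coincides with a point of the other
        base = PointSet.from_points([[0, 0], [3, 4]])
        rep = PointSet.from_points([[3, 4], [0, 0], [0, 0]])
        assert msmd(base, rep) == 0.0

    def test_symmetry_exact(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            x, s = random_pair(rng, max_size=20)
            assert msmd(x, s) == msmd(s, x)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            dim = int(rng.integers(2, 5))
            x, s = random_pair(rng, dim=dim, max_size=20)
            q = ortho_group.rvs(dim, random_state=np.random.default_rng(rng.integers(2**31)))
            t = rng.uniform(-500, 500, size=dim)
            xr = PointSet(x.coords @ q.T + t)
            sr = PointSet(s.coords @ q.T + t)
            assert rmsmd(xr, sr) == pytest.approx(rmsmd(x, s), rel=1e-9)

    def test_continuity_bound(self):
        """Perturbing one point by eps moves RMSMD by at most the analytic
        Lipschitz bound (2*Dmax*eps + eps^2) / (r + r'), with no jump at
        Voronoi-cell boundaries."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            x, s = random_pair(rng, dim=2, max_size=20)
            eps = 1e-6 * 1000.0
            x2 = x.coords.copy()
            x2[0] += eps / math.sqrt(2)
            r1, r2 = rmsmd(x, s), rmsmd(PointSet(x2), s)
            dmax = math.sqrt(
                max(((x.coords[:, None, :] - s.coords[None, :, :]) ** 2).sum(-1).max(), 1e-30)
            )
            bound = (2 * dmax * eps + eps**2) / max(r1 + r2, 1e-12)
            assert abs(r1 - r2) <= bound + 1e-12

    def test_tie_invariance(self):
        """Exact nearest-neighbor ties: the value is identical however the
        argmin is broken, and under any reordering of the points."""
        s = PointSet.from_points([[0.0, 0.0]])
        x = PointSet.from_points([[1, 0], [-1, 0], [0, 1]])  # all tied at distance 1
        assert msmd(x, s) == pytest.approx(1.0)
        rng = np.random.default_rng(10)
        for _ in range(20):
            pts = rng.integers(0, 4, size=(12, 2)).astype(float)  # many exact ties
            sites = rng.integers(0, 4, size=(6, 2)).astype(float)
            x1 = PointSet(pts)
            s1 = PointSet(sites)
            perm_x = PointSet(pts[rng.permutation(12)])
            perm_s = PointSet(sites[rng.permutation(6)])
            assert msmd(perm_x, perm_s) == pytest.approx(msmd(x1, s1), rel=1e-12)
            assert msmd_via_voronoi(x1, s1) == pytest.approx(msmd(x1, s1), rel=1e-12)

    def test_triangle_inequality_sampled(self):
        """Sampled search for triangle-inequality counterexamples; any found
        are surfaced as warnings, not hidden."""
        violations = sample_triangle_inequality(n_trials=200, seed=0)
        for v in violations:
            assert v["excess"] > 0  # each report is a genuine violation
        if violations:
            warnings.warn(
                f"{len(violations)} sampled triangle-inequality violations: "
                f"worst excess {max(v['excess'] for v in violations):.3g} nm"
            )
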