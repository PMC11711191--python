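"""Crossing detection, the independent geometric oracle, and densities."""

import numpy as np
import pytest
from scipy.optimize import minimize

from fiberweave.core import FiberSet
from fiberweave.entanglement import crossing_density, detect_crossings, multi_roi_density


def _fiber(p0, p1):
    return np.array([p0, p1], dtype=float)


def _set(fibers, radius=5.0):
    return FiberSet(fibers=fibers, radius_um=np.full(len(fibers), radius))


# ---------------------------------------------------------------------------
# independent oracle: per-pair minimum distance by numerical optimization
# ---------------------------------------------------------------------------

def _oracle_pair_in_contact(a0, a1, b0, b1, contact):
    """Exact contact decision for two segments, independent of the
    analytic closest-point formula.

    A dense parameter grid gives an upper bound on the minimum distance;
    the distance is 1-Lipschitz in arc length along each segment, so
    grid_min − (h_a + h_b)/2 is a certified lower bound.  Only the
    ambiguous band falls through to numerical optimization.
    """
    grid = np.linspace(0.0, 1.0, 21)
    P = a0 + grid[:, None] * (a1 - a0)
    Q = b0 + grid[:, None] * (b1 - b0)
    d = np.linalg.norm(P[:, None, :] - Q[None, :, :], axis=-1)
    gmin = d.min()
    slack = (np.linalg.norm(a1 - a0) + np.linalg.norm(b1 - b0)) / 2 / 20
    if gmin <= contact:
        return True
    if gmin - slack > contact:
        return False

    def fun(x):
        p = a0 + x[0] * (a1 - a0)
        q = b0 + x[1] * (b1 - b0)
        return float(np.sum((p - q) ** 2))

    k = np.unravel_index(np.argmin(d), d.shape)
    res = minimize(fun, (grid[k[0]], grid[k[1]]), bounds=[(0, 1), (0, 1)])
    return np.sqrt(res.fun) <= contact


def oracle_count(fs: FiberSet, contact: float, min_angle: float = 15.0) -> int:
    """Exhaustive all-pairs crossing count for straight 2-point fibers."""
    n = len(fs)
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = fs.fibers[i], fs.fibers[j]
            ta = np.degrees(np.arctan2(a[1, 2] - a[0, 2], a[1, 1] - a[0, 1])) % 180
            tb = np.degrees(np.arctan2(b[1, 2] - b[0, 2], b[1, 1] - b[0, 1])) % 180
            d = abs(ta - tb) % 180
            if min(d, 180 - d) < min_angle:
                continue
            # axis-aligned bounding boxes give a certified lower bound
            gap = np.maximum(0.0, np.maximum(a.min(0) - b.max(0),
                                             b.min(0) - a.max(0)))
            if np.linalg.norm(gap) > contact:
                continue
            if _oracle_pair_in_contact(a[0], a[1], b[0], b[1], contact):
                count += 1
    return count


def _random_instance(rng, n_fibers):
    fibers = []
    for _ in range(n_fibers):
        z = rng.integers(0, 5) * 10.62
        c = rng.uniform(50, 450, size=2)
        theta = rng.uniform(0, np.pi)
        d = np.array([np.cos(theta), np.sin(theta)])
        half = rng.uniform(40, 150)
        fibers.append(_fiber([z, *(c - half * d)], [z, *(c + half * d)]))
    return _set(fibers)


class TestDetect:
    def test_two_orthogonal_fibers_one_crossing(self):
        fs = _set([_fiber([0, 250, 50], [0, 250, 450]),
                   _fiber([0, 50, 250], [0, 450, 250])])
        res = detect_crossings(fs)
        assert res.crossing_count == 1
        z, y, x = res.crossing_locations[0]
        assert (y, x) == pytest.approx((250, 250), abs=1.0)

    def test_parallel_fibers_no_crossing(self):
        fs = _set([_fiber([0, 100, 0], [0, 100, 400]),
                   _fiber([0, 150, 0], [0, 150, 400])])
        assert detect_crossings(fs).crossing_count == 0

    def test_near_parallel_contact_is_bundling_not_crossing(self):
        # 10° apart, touching: below the 15° transversality threshold
        fs = _set([_fiber([0, 250, 50], [0, 250, 450]),
                   _fiber([0, 215, 50], [0, 285, 447])])
        assert detect_crossings(fs).crossing_count == 0

    def test_different_planes_no_crossing(self):
        # orthogonal in-plane but one z step (10.62 μm) apart > contact
        fs = _set([_fiber([0, 250, 50], [0, 250, 450]),
                   _fiber([10.62, 50, 250], [10.62, 450, 250])])
        assert detect_crossings(fs).crossing_count == 0

    def test_declustering_merges_repeated_contacts(self):
        # a shallow V touching a straight fiber twice within the
        # declustering radius counts once
        straight = _fiber([0, 100, 0], [0, 100, 300])
        vee = np.array([[0, 130, 140], [0, 98, 150], [0, 130, 160]])
        fs = FiberSet(fibers=[straight, vee], radius_um=np.array([5.0, 5.0]))
        res = detect_crossings(fs, min_cross_angle_deg=15)
        assert res.crossing_count == 1

    def test_missing_radii_requires_explicit_contact(self):
        fs = FiberSet(fibers=[_fiber([0, 0, 0], [0, 0, 100])],
                      radius_um=np.array([np.nan]))
        with pytest.raises(ValueError, match="contact_dist_um"):
            detect_crossings(fs)
        assert detect_crossings(fs, contact_dist_um=10.0).crossing_count == 0

    def test_enumeration_order_invariance(self):
        rng = np.random.default_rng(5)
        fs = _random_instance(rng, 20)
        a = detect_crossings(fs).crossing_count
        order = rng.permutation(len(fs))
        b = detect_crossings(fs.subset(order)).crossing_count
        assert a == b

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        fs = _random_instance(rng, 25)
        assert detect_crossings(fs).crossing_count == oracle_count(fs, 10.0)


class TestDensity:
    def test_empty_fiberset_zero_density(self):
        res = crossing_density(FiberSet(), contact_dist_um=10.0)
        assert res.crossing_count == 0
        assert res.density_per_um3 == 0.0

    def test_stated_roi_geometry_volume(self):
        # 200×200 px at 1.21 μm/px, 100 μm depth → 5,856,400 μm³
        fs = _set([_fiber([5, 120, 50], [5, 120, 190]),
                   _fiber([5, 50, 120], [5, 190, 120])])
        res = crossing_density(fs, roi_px=(200, 200), depth_um=100.0)
        assert res.roi_volume_um3 == pytest.approx((200 * 1.21) ** 2 * 100)
        assert res.crossing_count == 1
        assert res.density_per_um3 == pytest.approx(1 / 5856400, rel=1e-6)

    def test_degenerate_roi_rejected(self):
        with pytest.raises(ValueError):
            crossing_density(_set([_fiber([0, 0, 0], [0, 0, 10])]), depth_um=0.0)

    def test_halfopen_additivity_across_adjacent_boxes(self):
        rng = np.random.default_rng(9)
        fs = _random_instance(rng, 30)
        kw = dict(roi_px=(200, 200), depth_um=60.0, contact_dist_um=10.0)
        whole = crossing_density(fs, roi_px=(400, 200), depth_um=60.0,
                                 origin_um=(0, 0, 0), contact_dist_um=10.0)
        left = crossing_density(fs, origin_um=(0, 0, 0), **kw)
        right = crossing_density(fs, origin_um=(0, 200 * 1.21, 0), **kw)
        assert whole.crossing_count == left.crossing_count + right.crossing_count

    def test_density_halves_when_depth_doubles(self):
        fs = _set([_fiber([5, 120, 50], [5, 120, 190]),
                   _fiber([5, 50, 120], [5, 190, 120])])
        d1 = crossing_density(fs, depth_um=50.0)
        d2 = crossing_density(fs, depth_um=100.0)
        assert d1.crossing_count == d2.crossing_count == 1
        assert d2.density_per_um3 == pytest.approx(d1.density_per_um3 / 2)

    def test_multi_roi_mean_sd(self):
        rng = np.random.default_rng(10)
        fs = _random_instance(rng, 30)
        summ = multi_roi_density(fs, field_extent_um=(60, 500, 500), n_rois=4,
                                 roi_px=(150, 150), depth_um=40.0,
                                 contact_dist_um=10.0, seed=3)
        dens = [r.density_per_um3 for r in summ.per_roi]
        assert summ.mean_density_per_um3 == pytest.approx(np.mean(dens))
        assert summ.sd_density_per_um3 == pytest.approx(np.std(dens, ddof=1))
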