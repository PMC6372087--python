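"""Circle-dilation clustering, union-of-disks areas and AZ assembly."""

import math

import numpy as np
import pytest

from synaptiq.core_io import CHANNEL_CLASS, REPORTER_CLASS, PointPattern
from synaptiq.replica_cluster import (assemble_az, cluster_area,
                                      cluster_particles, pattern_summary)
from synaptiq.stats_harness import select_and_compare
from synaptiq.synthdata import ThomasProcessParams, gen_point_pattern


def _pattern(points, classes=None, area=10.0):
    pts = np.asarray(points, dtype=float)
    classes = classes if classes is not None \
        else np.full(len(pts), CHANNEL_CLASS)
    return PointPattern(pts, classes, area)


def brute_force_components(points, threshold):
    """O(n^2) union-find oracle: link iff distance <= threshold."""
    n = len(points)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if math.dist(points[i], points[j]) <= threshold:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return sorted(sorted(c) for c in comps.values())


class TestClusterParticles:
    def test_boundary_touching_pair_is_one_cluster(self):
        clusters, singles = cluster_particles(_pattern([[0, 0], [59, 0]]), 30.0)
        assert len(clusters) == 1 and clusters[0].n == 2 and not singles

    def test_separated_pair_stays_single(self):
        clusters, singles = cluster_particles(_pattern([[0, 0], [61, 0]]), 30.0)
        assert not clusters and sorted(singles) == [0, 1]

    def test_empty_pattern(self):
        pat = PointPattern(np.empty((0, 2)), np.empty(0), 1.0)
        assert cluster_particles(pat, 30.0) == ([], [])

    def test_reporter_class_excluded(self):
        pat = _pattern([[0, 0], [40, 0], [20, 5]],
                       classes=[CHANNEL_CLASS, CHANNEL_CLASS, REPORTER_CLASS])
        clusters, singles = cluster_particles(pat, 30.0)
        assert len(clusters) == 1 and clusters[0].n == 2

    def test_matches_brute_force_union_find(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 200))
            side = max(math.sqrt(n) * 60.0, 100.0)
            pts = rng.uniform(0.0, side, (n, 2))
            clusters, singles = cluster_particles(_pattern(pts), 30.0)
            got = sorted([sorted(c.member_indices.tolist()) for c in clusters]
                         + [[s] for s in singles])
            assert got == brute_force_components(pts, 60.0)

    def test_conservation_and_radius_monotonicity(self, rng):
        pts = rng.uniform(0.0, 800.0, (120, 2))
        pat = _pattern(pts)
        prev_components = None
        prev_max = 0
        for radius in (10.0, 20.0, 30.0, 50.0, 80.0):
            clusters, singles = cluster_particles(pat, radius)
            assert sum(c.n for c in clusters) + len(singles) == 120
            n_comp = len(clusters) + len(singles)
            if prev_components is not None:
                assert n_comp <= prev_components
            prev_components = n_comp
            biggest = max((c.n for c in clusters), default=1)
            assert biggest >= prev_max
            prev_max = biggest


class TestClusterArea:
    def test_single_disk_analytic(self):
        # two coincident points: union of 30 nm disks = one disk area
        pat = _pattern([[0.0, 0.0], [1e-9, 0.0]])
        clusters, _ = cluster_particles(pat, 30.0)
        assert cluster_area(pat, clusters[0], 30.0) == pytest.approx(
            math.pi * 0.03 ** 2, rel=5e-3)

    def test_two_disk_lens_closed_form(self):
        r, d = 30.0, 30.0
        pat = _pattern([[0, 0], [d, 0]])
        clusters, _ = cluster_particles(pat, r)
        # union = 2*pi*r^2 - lens; lens = 2 r^2 acos(d/2r) - (d/2) sqrt(4r^2-d^2)
        lens = 2 * r * r * math.acos(d / (2 * r)) \
            - (d / 2.0) * math.sqrt(4 * r * r - d * d)
        expected = (2 * math.pi * r * r - lens) * 1e-6
        assert cluster_area(pat, clusters[0], r) == pytest.approx(expected,
                                                                  rel=1e-3)

    def test_monte_carlo_oracle_random_five_disk_unions(self, rng):
        r = 30.0
        for _ in range(5):
            pts = rng.uniform(0.0, 120.0, (5, 2))
            pat = _pattern(pts)
            clusters, singles = cluster_particles(pat, r)
            geom = sum(c.area for c in clusters) \
                + len(singles) * math.pi * (r * 1e-3) ** 2
            lo = pts.min(axis=0) - r
            hi = pts.max(axis=0) + r
            samples = rng.uniform(lo, hi, (400_000, 2))
            inside = np.zeros(len(samples), dtype=bool)
            for p in pts:
                inside |= np.sum((samples - p) ** 2, axis=1) <= r * r
            mc = inside.mean() * np.prod(hi - lo) * 1e-6
            assert geom == pytest.approx(mc, rel=0.01)

    def test_area_bounds(self, rng):
        pts = rng.uniform(0.0, 300.0, (40, 2))
        pat = _pattern(pts)
        clusters, _ = cluster_particles(pat, 30.0)
        disk = math.pi * 0.03 ** 2
        for c in clusters:
            assert disk * (1 - 1e-3) <= c.area <= c.n * disk * (1 + 1e-3)


class TestAssembleAZ:
    def test_tight_group_single_az_single_cluster(self):
        pts = [[0, 0], [40, 10], [20, 45], [55, 40], [10, 55]]
        regions = assemble_az(_pattern(pts))
        assert len(regions) == 1
        assert regions[0].contained_clusters == 1
        assert regions[0].contained_singles == 0

    def test_two_groups_beyond_az_reach(self):
        pts = [[0, 0], [40, 0], [290, 0], [330, 0]]
        regions = assemble_az(_pattern(pts))
        assert len(regions) == 2
        assert all(r.contained_clusters == 1 for r in regions)

    def test_lone_particle_is_an_az_with_one_single(self):
        regions = assemble_az(_pattern([[50, 50]]))
        assert len(regions) == 1
        assert regions[0].contained_clusters == 0
        assert regions[0].contained_singles == 1
        assert regions[0].region_area == pytest.approx(math.pi * 0.1 ** 2,
                                                       rel=5e-3)

    def test_nesting_every_cluster_in_exactly_one_region(self, rng):
        pts = rng.uniform(0.0, 1500.0, (150, 2))
        pat = _pattern(pts)
        clusters, singles = cluster_particles(pat, 30.0)
        regions = assemble_az(pat)
        assert sum(r.contained_clusters for r in regions) == len(clusters)
        assert sum(r.contained_singles for r in regions) == len(singles)


class TestPatternSummary:
    def test_single_fraction(self):
        pts = [[0, 0], [30, 0], [60, 0], [500, 500]]
        out = pattern_summary([_pattern(pts)])
        assert out["single_fraction"] == pytest.approx(0.25)

    def test_thomas_process_mean_cluster_size_tracks_offspring(self):
        sizes = []
        for seed in range(50):
            pat, truth = gen_point_pattern(ThomasProcessParams(
                parent_intensity=0.2, offspring_mean=5.0, sigma=10.0,
                face_area=50.0, seed=seed))
            clusters, _ = cluster_particles(pat, 30.0)
            sizes += [c.n for c in clusters]
        # tight scatter: each parent's brood forms one cluster; small-size
        # truncation (singletons dropped) raises the mean slightly above 5
        assert np.mean(sizes) == pytest.approx(5.0, abs=0.6)

    def test_identical_groups_fisher_p_one(self):
        pts = [[0, 0], [30, 0], [60, 0], [500, 500]]
        a = pattern_summary([_pattern(pts)])
        table = [[int(a["n_singles"]), int(a["n_particles"] - a["n_singles"])]] * 2
        res = select_and_compare(table, design="binned")
        assert res.p_value == 1.0
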