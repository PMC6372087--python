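"""Immunogold point-pattern clustering on freeze-fracture replica P-faces.

Channel-class gold particles are grouped by circle dilation: disks of a given
radius are extended from each particle and particles whose disks intersect
(center distance ≤ 2·radius, boundary-touching inclusive) join the same
component.  Components of ≥2 particles are clusters at the 30 nm radius;
the same construction at 100 nm defines putative active-zone regions.
Single particles are counted but are not clusters.  Areas are the union of
member disks, in μm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from shapely.geometry import Point
from shapely.ops import unary_union

from .core_io import PointPattern

__all__ = ["ParticleCluster", "AZRegion", "cluster_particles", "cluster_area",
           "assemble_az", "pattern_summary"]

NM2_PER_UM2 = 1e6
_QUAD_SEGS = 64  # 256 segments/circle: polygonal area error ~1e-4 relative


@dataclass
class ParticleCluster:
    member_indices: np.ndarray  # indices into the pattern
    n: int
    area: float        # μm², union of member disks at the clustering radius
    density: float     # particles/μm²
    centroid: tuple[float, float]  # nm

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a cluster has at least 2 particles")
        if not self.area > 0:
            raise ValueError("cluster area must be > 0")


@dataclass
class AZRegion:
    region_area: float        # μm², union of 100 nm disks
    contained_clusters: int   # 30 nm clusters with centroid inside
    contained_singles: int
    member_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __post_init__(self) -> None:
        if not self.region_area > 0:
            raise ValueError("region area must be > 0")
        if self.contained_clusters < 0 or self.contained_singles < 0:
            raise ValueError("counts must be >= 0")


def _components(xy: np.ndarray, link_dist: float) -> list[np.ndarray]:
    """Connected components under center-distance ≤ link_dist (inclusive)."""
    m = len(xy)
    if m == 0:
        return []
    pairs = cKDTree(xy).query_pairs(link_dist, output_type="ndarray")
    if pairs.size:
        data = np.ones(len(pairs))
        graph = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(m, m))
    else:
        graph = coo_matrix((m, m))
    n_comp, labels = connected_components(graph, directed=False)
    return [np.flatnonzero(labels == k) for k in range(n_comp)]


def _disk_union_area_um2(xy_nm: np.ndarray, radius_nm: float) -> float:
    union = unary_union([Point(p).buffer(radius_nm, quad_segs=_QUAD_SEGS)
                         for p in xy_nm])
    return union.area / NM2_PER_UM2


def cluster_particles(pattern: PointPattern, radius_nm: float = 30.0
                      ) -> tuple[list[ParticleCluster], list[int]]:
    """Circle-dilation clustering of channel-class particles.

    Returns (clusters, singles): components of ≥2 particles as
    :class:`ParticleCluster` and singleton particle indices separately.
    Reporter-class particles are excluded from clustering.
    """
    if not radius_nm > 0:
        raise ValueError("radius must be > 0")
    chan = pattern.channel_indices()
    xy = pattern.points[chan]
    clusters: list[ParticleCluster] = []
    singles: list[int] = []
    for comp in _components(xy, 2.0 * radius_nm):
        idx = chan[comp]
        if comp.size == 1:
            singles.append(int(idx[0]))
            continue
        area = _disk_union_area_um2(pattern.points[idx], radius_nm)
        centroid = pattern.points[idx].mean(axis=0)
        clusters.append(ParticleCluster(
            member_indices=idx, n=int(comp.size), area=area,
            density=comp.size / area,
            centroid=(float(centroid[0]), float(centroid[1]))))
    clusters.sort(key=lambda c: tuple(c.member_indices[:1]))
    singles.sort()
    return clusters, singles


def cluster_area(pattern: PointPattern, cluster: ParticleCluster,
                 radius_nm: float = 30.0) -> float:
    """Union-of-disks area (μm²) of a cluster at the given radius."""
    if cluster.n == 0:
        raise ValueError("empty cluster")
    return _disk_union_area_um2(pattern.points[cluster.member_indices],
                                radius_nm)


def assemble_az(pattern: PointPattern, az_radius_nm: float = 100.0,
                cluster_radius_nm: float = 30.0) -> list[AZRegion]:
    """Putative active-zone regions from 100 nm circle dilation.

    Each AZ region is a connected component at the AZ radius; its area is the
    union of the AZ-radius disks.  The 30 nm clusters and singles are assigned
    to the region containing their centroid (nesting is guaranteed because
    30 nm components refine 100 nm components when radii are nested).
    """
    if not (az_radius_nm > 0 and cluster_radius_nm > 0):
        raise ValueError("radii must be > 0")
    chan = pattern.channel_indices()
    xy = pattern.points[chan]
    comps = _components(xy, 2.0 * az_radius_nm)
    clusters, singles = cluster_particles(pattern, cluster_radius_nm)

    regions = []
    for comp in comps:
        idx = chan[comp]
        members = set(int(i) for i in idx)
        n_clusters = sum(1 for c in clusters
                         if int(c.member_indices[0]) in members)
        n_singles = sum(1 for s in singles if s in members)
        regions.append(AZRegion(
            region_area=_disk_union_area_um2(pattern.points[idx], az_radius_nm),
            contained_clusters=n_clusters,
            contained_singles=n_singles,
            member_indices=idx))
    return regions


def pattern_summary(patterns: list[PointPattern],
                    cluster_radius_nm: float = 30.0,
                    az_radius_nm: float = 100.0) -> dict:
    """Pooled cluster metrics across patterns (one experimental group).

    Returns per-cluster particle counts, areas and densities, clusters per
    putative AZ, the single-particle fraction, and cumulative-frequency
    tables for each metric, ready for between-group comparison.
    """
    import pandas as pd

    if not patterns:
        raise ValueError("at least one pattern required")
    sizes, areas, dens, per_az = [], [], [], []
    n_singles = n_particles = 0
    for pat in patterns:
        clusters, singles = cluster_particles(pat, cluster_radius_nm)
        sizes += [c.n for c in clusters]
        areas += [c.area for c in clusters]
        dens += [c.density for c in clusters]
        per_az += [r.contained_clusters
                   for r in assemble_az(pat, az_radius_nm, cluster_radius_nm)]
        n_singles += len(singles)
        n_particles += len(pat.channel_indices())

    def ecdf(values):
        v = np.sort(np.asarray(values, dtype=float))
        return pd.DataFrame({"value": v,
                             "cum_freq": np.arange(1, v.size + 1) / max(v.size, 1)})

    return {
        "particles_per_cluster": np.asarray(sizes),
        "cluster_area_um2": np.asarray(areas),
        "cluster_density_per_um2": np.asarray(dens),
        "clusters_per_az": np.asarray(per_az),
        "single_fraction": (n_singles / n_particles) if n_particles else float("nan"),
        "n_particles": n_particles,
        "n_singles": n_singles,
        "cumfreq": {name: ecdf(vals) for name, vals in [
            ("particles_per_cluster", sizes), ("cluster_area_um2", areas),
            ("cluster_density_per_um2", dens), ("clusters_per_az", per_az)]},
    }
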