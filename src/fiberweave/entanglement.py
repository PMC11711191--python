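"""Fiber-crossing ("entanglement") counting and crossing density per μm³.

A crossing is an event where the polylines of two *distinct* fibers
approach within a contact distance (sum of the two tube radii by
default) while their local in-plane tangents differ by at least a
transversality threshold (15° by default — closer than that is treated
as bundling, not crossing).  Contact events between the same fiber pair
within a declustering radius (2 × contact distance by default) are
merged into one crossing, so a single geometric intersection is counted
once no matter how finely the polylines are sampled.

Density is crossings per μm³ of a half-open ROI box (200 × 200 px ×
100 μm depth by default); half-open boxes make counts additive across
adjacent ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import FiberSet, angle_diff_deg
from .geometry import bbox_gap, polyline_pair_events


@dataclass
class CrossingResult:
    """Crossing count, locations (z, y, x μm) and density for one ROI/volume."""

    crossing_count: int
    roi_volume_um3: float
    crossing_locations: list = field(default_factory=list)
    pair_ids: list = field(default_factory=list)

    @property
    def density_per_um3(self) -> float:
        return self.crossing_count / self.roi_volume_um3


def _inplane_angle(tangent: np.ndarray) -> float:
    """Undirected in-plane orientation (degrees) of a (z, y, x) tangent."""
    return float(np.rad2deg(np.arctan2(tangent[2], tangent[1])) % 180.0)


def _cluster_events(points: np.ndarray, radius: float) -> list[np.ndarray]:
    """Single-linkage clustering of event locations within ``radius``."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        d = np.linalg.norm(points[i + 1:] - points[i], axis=1)
        for j in np.nonzero(d <= radius)[0]:
            a, b = find(i), find(i + 1 + j)
            if a != b:
                parent[b] = a
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [points[idx].mean(axis=0) for idx in groups.values()]


def detect_crossings(
    f: FiberSet,
    contact_dist_um: float | None = None,
    min_cross_angle_deg: float = 15.0,
    decluster_factor: float = 2.0,
    roi_volume_um3: float | None = None,
    decluster_scope: str = "pair",
    interior_margin_um: float = 0.0,
) -> CrossingResult:
    """Count transversal contacts between all distinct fiber pairs.

    ``contact_dist_um`` defaults, per pair, to the sum of the two fibers'
    radii; an explicit value overrides this (and is required when the
    FiberSet carries no radii, e.g. traces from images).  Contacts of the
    same pair within ``decluster_factor × contact`` of each other merge
    into one crossing whose location is the cluster centroid.

    ``decluster_scope`` is ``"pair"`` for exact fiber sets (events merge
    only within one fiber pair) or ``"spatial"`` for fibers traced from
    images, where one physical fiber may be traced as several pieces and
    the same physical crossing can surface under several pair ids; then
    crossings are additionally merged by location alone.
    """
    if decluster_scope not in ("pair", "spatial"):
        raise ValueError("decluster_scope must be 'pair' or 'spatial'")
    n = len(f)
    radii = np.asarray(f.radius_um, dtype=float)
    if contact_dist_um is None and (n == 0 or np.any(np.isnan(radii))):
        raise ValueError(
            "fibers carry no radii; pass contact_dist_um explicitly"
        )
    locations, pairs = [], []
    for i in range(n):
        for j in range(i + 1, n):
            contact = (contact_dist_um if contact_dist_um is not None
                       else radii[i] + radii[j])
            if bbox_gap(f.fibers[i], f.fibers[j]) > contact:
                continue
            events = polyline_pair_events(f.fibers[i], f.fibers[j], contact,
                                          interior_margin=interior_margin_um)
            good = [
                (mid, ta, tb) for _, mid, ta, tb in events
                if angle_diff_deg(_inplane_angle(ta), _inplane_angle(tb))
                >= min_cross_angle_deg
            ]
            if not good:
                continue
            pts = np.asarray([g[0] for g in good])
            for center in _cluster_events(pts, decluster_factor * contact):
                locations.append(tuple(float(v) for v in center))
                pairs.append((i, j))
    if decluster_scope == "spatial" and locations:
        radius = decluster_factor * (contact_dist_um if contact_dist_um is not None
                                     else float(np.nanmean(radii)) * 2)
        centers = _cluster_events(np.asarray(locations), radius)
        locations = [tuple(float(v) for v in c) for c in centers]
        pairs = [(-1, -1)] * len(locations)
    if roi_volume_um3 is None:
        # whole-field volume from the fiber extent (informational only)
        roi_volume_um3 = float("nan")
    return CrossingResult(
        crossing_count=len(locations),
        roi_volume_um3=roi_volume_um3,
        crossing_locations=locations,
        pair_ids=pairs,
    )


def crossing_density(
    f: FiberSet,
    voxel_um: tuple[float, float, float] = (10.62, 1.21, 1.21),
    roi_px: tuple[int, int] = (200, 200),
    depth_um: float = 100.0,
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0),
    contact_dist_um: float | None = None,
    min_cross_angle_deg: float = 15.0,
) -> CrossingResult:
    """Crossing density inside one half-open ROI box.

    The box spans ``[origin, origin + extent)`` with in-plane extent
    ``roi_px × voxel`` and depth ``depth_um``; crossings are assigned to
    the box by containment of their location.  Volume =
    (roi_px_y · voxel_y) · (roi_px_x · voxel_x) · depth_um.
    """
    _, vy, vx = voxel_um
    ext_y = roi_px[0] * vy
    ext_x = roi_px[1] * vx
    volume = ext_y * ext_x * depth_um
    if volume <= 0:
        raise ValueError("degenerate ROI: zero volume")
    all_cross = detect_crossings(
        f, contact_dist_um=contact_dist_um, min_cross_angle_deg=min_cross_angle_deg
    )
    oz, oy, ox = origin_um
    lo = np.array([oz, oy, ox])
    hi = lo + np.array([depth_um, ext_y, ext_x])
    locations, pairs = [], []
    for loc, pid in zip(all_cross.crossing_locations, all_cross.pair_ids):
        p = np.asarray(loc)
        if np.all(p >= lo) and np.all(p < hi):
            locations.append(loc)
            pairs.append(pid)
    return CrossingResult(
        crossing_count=len(locations),
        roi_volume_um3=volume,
        crossing_locations=locations,
        pair_ids=pairs,
    )


@dataclass
class DensitySummary:
    """Mean ± sd of crossing density over several ROIs."""

    per_roi: list
    mean_density_per_um3: float
    sd_density_per_um3: float


def multi_roi_density(
    f: FiberSet,
    field_extent_um: tuple[float, float, float],
    n_rois: int = 4,
    voxel_um: tuple[float, float, float] = (10.62, 1.21, 1.21),
    roi_px: tuple[int, int] = (200, 200),
    depth_um: float = 100.0,
    seed: int = 0,
    contact_dist_um: float | None = None,
) -> DensitySummary:
    """Density over ``n_rois`` random ROI boxes inside the field, mean ± sd."""
    _, vy, vx = voxel_um
    ext = np.array([depth_um, roi_px[0] * vy, roi_px[1] * vx])
    hi = np.asarray(field_extent_um) - ext
    if np.any(hi < 0):
        raise ValueError("ROI box larger than the fiber field")
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_rois):
        origin = tuple(rng.uniform(0, h) if h > 0 else 0.0 for h in hi)
        results.append(
            crossing_density(
                f, voxel_um=voxel_um, roi_px=roi_px, depth_um=depth_um,
                origin_um=origin, contact_dist_um=contact_dist_um,
            )
        )
    dens = np.array([r.density_per_um3 for r in results])
    return DensitySummary(
        per_roi=results,
        mean_density_per_um3=float(dens.mean()),
        sd_density_per_um3=float(dens.std(ddof=1)) if len(dens) > 1 else 0.0,
    )
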