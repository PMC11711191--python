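"""Synthetic phantoms with exact ground truth.

Two families of phantoms are generated:

* **Layered sections** — labeled masks (background / stratum corneum /
  viable epidermis / dermis) with per-layer mean thickness and sinusoidal
  boundary undulation, emulating segmented H&E cross-sections.
* **Fibrous stacks** — 3-D intensity volumes in which collagen-like
  fibers are rendered as constant-radius tubes (10 μm thick by default)
  lying in section planes, with in-plane angles drawn from a three-mode
  mixture (perpendicular window / parallel window / diffuse), optional
  planted transversal crossings, an anisotropic generator PSF, and
  detector noise on a 12-bit range.

Every generator is deterministic given its seed and returns the exact
ground truth alongside the image, so every downstream measurement can be
scored against truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .core import (
    FiberSet,
    LAYER_LABELS,
    LayerImage,
    SampleMeta,
    ShgStack,
    TISSUE_LAYERS,
    angle_diff_deg,
)
from .geometry import polyline_min_distance, segment_segment_closest

BIT12_CEILING = 4095.0


class GenerationError(RuntimeError):
    """Raised when a phantom cannot be realized under the requested truth."""


class SizingError(ValueError):
    """Raised when requested layer thicknesses exceed the image height."""


@dataclass
class PhantomTruth:
    """Generator parameters and the exact ground truth they induce.

    The fields set before generation are the *requested* conditions; the
    generators return a copy with ``fiber_angles_deg`` and
    ``crossing_count`` filled in with what was actually realized.
    """

    layer_thickness_mm: dict = field(
        default_factory=lambda: {"SC": 0.39, "VE": 0.05, "D": 0.8}
    )
    boundary_undulation_mm: float = 0.0
    n_fibers: int = 100
    mixture_weights: tuple[float, float, float] = (0.25, 0.25, 0.5)
    fiber_radius_um: float = 5.0
    fiber_length_um: tuple[float, float] = (150.0, 400.0)
    planted_crossing_count: int = 0
    intensity_scale: float = 2000.0
    noise_sigma_frac: float = 0.05
    poisson: bool = False
    psf_sigma_um: tuple[float, float, float] = (0.0, 1.0, 1.0)
    out_of_plane_max_deg: float = 0.0
    angle_halfwidth_deg: float = 5.0
    seed: int = 0
    # filled in by the generators
    fiber_angles_deg: np.ndarray | None = None
    crossing_count: int | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.mixture_weights, dtype=float)
        if w.size != 3 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture_weights must be 3 non-negative fractions summing to 1")
        if self.planted_crossing_count < 0:
            raise ValueError("planted_crossing_count must be >= 0")
        for name, t in self.layer_thickness_mm.items():
            if t < 0:
                raise ValueError(f"layer thickness for {name!r} must be >= 0")
        if self.fiber_radius_um <= 0:
            raise ValueError("fiber_radius_um must be > 0")
        if self.fiber_angles_deg is not None:
            a = np.asarray(self.fiber_angles_deg, dtype=float)
            if a.size and (a.min() < 0 or a.max() >= 180):
                raise ValueError("fiber angles must lie in [0, 180)")
            self.fiber_angles_deg = a

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.fiber_angles_deg is not None:
            d["fiber_angles_deg"] = np.asarray(self.fiber_angles_deg).tolist()
        return d


# ---------------------------------------------------------------------------
# layered sections
# ---------------------------------------------------------------------------

def gen_layer_image(
    truth: PhantomTruth,
    width_px: int,
    pixel_size_mm: float,
    height_px: int | None = None,
    n_periods: int = 4,
    meta: SampleMeta | None = None,
):
    """Render a labeled layered section (SC over VE over D over background).

    Each layer's per-column thickness is its requested mean plus a
    sinusoid of amplitude ``boundary_undulation_mm`` with ``n_periods``
    full periods across the width and a seed-determined phase, so column
    means average back to the requested thickness.  Columns run along the
    outward normal (axis 0).
    """
    if width_px < 10:
        raise ValueError("width_px must be >= 10")
    if pixel_size_mm <= 0:
        raise ValueError("pixel_size_mm must be > 0")

    rng = np.random.default_rng(truth.seed)
    x = np.arange(width_px)
    amp = truth.boundary_undulation_mm
    counts = {}
    for layer in TISSUE_LAYERS:
        t_mm = truth.layer_thickness_mm.get(layer, 0.0)
        phase = rng.uniform(0, 2 * np.pi)
        if t_mm <= 0:
            counts[layer] = np.zeros(width_px, dtype=int)
            continue
        profile = t_mm + amp * np.sin(2 * np.pi * n_periods * x / width_px + phase)
        counts[layer] = np.maximum(0, np.round(profile / pixel_size_mm)).astype(int)

    top_margin = 5
    max_total = int(sum(c.max() for c in counts.values()))
    if height_px is None:
        height_px = max_total + 2 * top_margin
    labels = np.zeros((height_px, width_px), dtype=np.uint8)
    cum = np.full(width_px, top_margin, dtype=int)
    for layer in TISSUE_LAYERS:
        bottom = cum + counts[layer]
        if bottom.max() > height_px:
            raise SizingError(
                f"layer {layer!r} extends to row {int(bottom.max())} "
                f"but the image is only {height_px} rows tall"
            )
        lab = LAYER_LABELS[layer]
        for col in range(width_px):
            labels[cum[col]:bottom[col], col] = lab
        cum = bottom

    return LayerImage(
        labels=labels,
        pixel_size_mm=pixel_size_mm,
        meta=meta or SampleMeta(),
        normal_axis="y",
    )


# ---------------------------------------------------------------------------
# fibrous stacks
# ---------------------------------------------------------------------------

def sample_mixture_angles(rng: np.random.Generator, n: int,
                          weights, halfwidth_deg: float = 5.0) -> np.ndarray:
    """Draw in-plane angles from the (perpendicular, parallel, diffuse) mixture.

    Perpendicular mode: uniform over [0, hw] ∪ [180-hw, 180); parallel
    mode: uniform over [90-hw, 90+hw]; diffuse: uniform over the rest of
    [0, 180).  Angles are measured from the outward normal.
    """
    hw = halfwidth_deg
    comps = rng.choice(3, size=n, p=np.asarray(weights, dtype=float))
    u = rng.uniform(size=n)
    angles = np.empty(n)
    perp = comps == 0
    # the perpendicular window wraps around 0/180
    a = u[perp] * 2 * hw - hw
    angles[perp] = np.mod(a, 180.0)
    par = comps == 1
    angles[par] = 90.0 - hw + u[par] * 2 * hw
    dif = comps == 2
    # diffuse support: (hw, 90-hw) ∪ (90+hw, 180-hw), two equal intervals
    span = 90.0 - 2 * hw
    v = u[dif] * 2 * span
    angles[dif] = np.where(v < span, hw + v, 90.0 + hw + (v - span))
    return angles


def _direction(theta_deg: float) -> np.ndarray:
    """Unit in-plane direction (dy, dx) of orientation θ from the +y normal."""
    t = np.deg2rad(theta_deg)
    return np.array([np.cos(t), np.sin(t)])


def _make_fiber(center_yx, theta_deg, length_um, z_um, field_um, margin_um):
    """Straight 2-point polyline (z, y, x) clipped to the field interior."""
    d = _direction(theta_deg)
    lo = np.full(2, margin_um)
    hi = np.asarray(field_um) - margin_um
    # clip the parameter range so both endpoints stay inside the field
    t_min, t_max = -length_um / 2, length_um / 2
    for k in range(2):
        if abs(d[k]) > 1e-12:
            a = (lo[k] - center_yx[k]) / d[k]
            b = (hi[k] - center_yx[k]) / d[k]
            a, b = min(a, b), max(a, b)
            t_min, t_max = max(t_min, a), min(t_max, b)
    if t_max - t_min < 1e-6:
        return None
    p0 = np.array([z_um, *(center_yx + t_min * d)])
    p1 = np.array([z_um, *(center_yx + t_max * d)])
    return np.stack([p0, p1])


def _bulk_crossing_count(fibers, contact_um, min_angle_deg) -> int:
    """Exact transversal-contact count over all pairs of straight fibers.

    Straight 2-point fibers meet at most once, so the count is simply the
    number of pairs with minimum distance ≤ contact and in-plane tangent
    difference ≥ the transversality threshold.  Vectorized over all pairs.
    """
    n = len(fibers)
    if n < 2:
        return 0
    P0 = np.stack([f[0] for f in fibers])
    P1 = np.stack([f[1] for f in fibers])
    ii, jj = np.triu_indices(n, k=1)
    dist, _, _ = segment_segment_closest(P0[ii], P1[ii], P0[jj], P1[jj])
    theta = np.rad2deg(np.arctan2(P1[:, 2] - P0[:, 2], P1[:, 1] - P0[:, 1])) % 180
    dtheta = np.abs(theta[ii] - theta[jj]) % 180.0
    dtheta = np.minimum(dtheta, 180.0 - dtheta)
    return int(np.sum((dist <= contact_um) & (dtheta >= min_angle_deg)))


def render_fiber_support(fibers, radius_um, shape_px, voxel_um) -> np.ndarray:
    """Binary tube support of a set of centerline polylines.

    Each polyline is rasterized into its nearest z slice and dilated
    in-plane to the physical radius (union of physical-radius disks
    around centerline pixels), matching the section-plane geometry of
    the acquisition: the z spacing is much larger than the fiber radius,
    so a tube is confined to its section plane.
    """
    nz, ny, nx = shape_px
    vz, vy, vx = voxel_um
    center = np.zeros((nz, ny, nx), dtype=bool)
    step = 0.5 * min(vy, vx)
    for poly in fibers:
        poly = np.asarray(poly, float)
        for p0, p1 in zip(poly[:-1], poly[1:]):
            seg_len = np.linalg.norm(p1 - p0)
            npts = max(2, int(np.ceil(seg_len / step)) + 1)
            pts = p0 + np.linspace(0, 1, npts)[:, None] * (p1 - p0)
            zi = np.round(pts[:, 0] / vz).astype(int)
            yi = np.round(pts[:, 1] / vy).astype(int)
            xi = np.round(pts[:, 2] / vx).astype(int)
            ok = (zi >= 0) & (zi < nz) & (yi >= 0) & (yi < ny) & (xi >= 0) & (xi < nx)
            center[zi[ok], yi[ok], xi[ok]] = True
    ry = int(np.floor(radius_um / vy))
    rx = int(np.floor(radius_um / vx))
    yy, xx = np.mgrid[-ry:ry + 1, -rx:rx + 1]
    footprint = (yy * vy) ** 2 + (xx * vx) ** 2 <= radius_um ** 2
    support = np.zeros_like(center)
    for k in range(nz):
        if center[k].any():
            support[k] = ndi.binary_dilation(center[k], structure=footprint)
    return support


def gen_fiber_stack(
    truth: PhantomTruth,
    shape_px: tuple[int, int, int] = (12, 512, 512),
    voxel_um: tuple[float, float, float] = (10.62, 1.21, 1.21),
    meta: SampleMeta | None = None,
    min_cross_angle_deg: float = 15.0,
    separation_um: float | None = None,
    retry_budget: int = 200,
):
    """Render a fibrous SHG-like stack and return it with its exact truth.

    Fibers are straight tubes lying in section planes.  When
    ``planted_crossing_count`` > 0, fibers are added in coplanar pairs
    forced to intersect transversally (in-plane crossing angle ≥
    ``min_cross_angle_deg``); remaining fibers are rejection-sampled to
    keep a minimum separation from existing fibers, and any residual
    incidental crossings are counted into the emitted truth.

    Returns ``(stack, fiber_set, emitted_truth)`` where ``emitted_truth``
    carries the realized angle list and total crossing count.
    """
    nz, ny, nx = shape_px
    vz, vy, vx = voxel_um
    field_um = (ny * vy, nx * vx)
    r = truth.fiber_radius_um
    if min(field_um) < 4 * r or nz < 1:
        raise ValueError("stack too small to hold a fiber of the stated radius")
    contact = 2 * r
    sep = separation_um if separation_um is not None else 2.5 * contact
    enforce_sep = sep > 0

    rng = np.random.default_rng(truth.seed)
    n = truth.n_fibers
    n_pairs = truth.planted_crossing_count
    if 2 * n_pairs > n:
        raise GenerationError(
            f"{n_pairs} planted crossings need {2 * n_pairs} fibers but only {n} requested"
        )

    weights = np.asarray(truth.mixture_weights, dtype=float)
    hw = truth.angle_halfwidth_deg
    lmin, lmax = truth.fiber_length_um
    margin = r + 1.0

    fibers: list[np.ndarray] = []
    angles: list[float] = []

    def draw_angle() -> float:
        return float(sample_mixture_angles(rng, 1, weights, hw)[0])

    def draw_center():
        return np.array([
            rng.uniform(0.15 * field_um[0], 0.85 * field_um[0]),
            rng.uniform(0.15 * field_um[1], 0.85 * field_um[1]),
        ])

    def clear_of_existing(cand):
        if not enforce_sep:
            return True
        # fibers lie in section planes; only coplanar fibers can conflict
        # (the z step exceeds the contact distance)
        for f in fibers:
            if abs(f[0, 0] - cand[0, 0]) > contact:
                continue
            if polyline_min_distance(cand, f) < sep:
                return False
        return True

    # planted crossing pairs: coplanar, transversal, isolated from the rest
    for _ in range(n_pairs):
        placed = False
        for _ in range(retry_budget):
            t1 = draw_angle()
            t2 = draw_angle()
            if angle_diff_deg(t1, t2) < min_cross_angle_deg:
                continue
            point = draw_center()
            z = rng.integers(0, nz) * vz
            fa = _make_fiber(point, t1, rng.uniform(lmin, lmax), z, field_um, margin)
            fb = _make_fiber(point, t2, rng.uniform(lmin, lmax), z, field_um, margin)
            if fa is None or fb is None:
                continue
            if clear_of_existing(fa) and clear_of_existing(fb):
                fibers.extend([fa, fb])
                angles.extend([t1, t2])
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not plant {n_pairs} transversal crossings with the "
                f"requested angle mixture after {retry_budget} retries"
            )

    # remaining fibers: rejection-sampled to avoid incidental crossings
    for _ in range(n - 2 * n_pairs):
        best = None
        accepted = False
        for _ in range(retry_budget):
            theta = draw_angle()
            z = rng.integers(0, nz) * vz
            cand = _make_fiber(draw_center(), theta, rng.uniform(lmin, lmax),
                               z, field_um, margin)
            if cand is None:
                continue
            if clear_of_existing(cand):
                fibers.append(cand)
                angles.append(theta)
                accepted = True
                break
            if best is None:
                best = (cand, theta)
        if not accepted:
            if best is None:
                raise GenerationError("could not place a fiber inside the field")
            cand, theta = best
            fibers.append(cand)
            angles.append(theta)

    fiber_set = FiberSet(
        fibers=fibers,
        angles_deg=np.asarray(angles),
        radius_um=np.full(len(fibers), r),
        normal_axis="y",
        meta=meta or SampleMeta(),
    )
    emitted = replace(
        truth,
        fiber_angles_deg=np.asarray(angles),
        # exact truth: any residual incidental crossings count alongside
        # the planted ones
        crossing_count=_bulk_crossing_count(fibers, contact, min_cross_angle_deg),
    )

    stack = render_fiber_set(
        fiber_set, shape_px, voxel_um,
        intensity_scale=truth.intensity_scale,
        psf_sigma_um=truth.psf_sigma_um,
        noise_sigma=truth.noise_sigma_frac * truth.intensity_scale,
        poisson=truth.poisson,
        rng=rng,
        meta=meta,
    )
    return stack, fiber_set, emitted


def render_fiber_set(
    fiber_set: FiberSet,
    shape_px,
    voxel_um,
    intensity_scale: float,
    psf_sigma_um=(0.0, 1.0, 1.0),
    noise_sigma: float = 0.0,
    poisson: bool = False,
    rng: np.random.Generator | None = None,
    meta: SampleMeta | None = None,
) -> ShgStack:
    """Render a FiberSet into an intensity stack (tube support × scale,
    generator PSF blur, detector noise, 12-bit clip).

    With ``psf_sigma_um = 0`` and ``noise_sigma = 0`` the output is exactly
    ``intensity_scale`` on the tube support and 0 elsewhere, which is the
    ground-truth-consistency contract used by the tests.
    """
    vz, vy, vx = voxel_um
    radius = float(fiber_set.radius_um[0]) if len(fiber_set) else 0.0
    support = render_fiber_support(fiber_set.fibers, radius, shape_px, voxel_um)
    data = support.astype(np.float64) * intensity_scale
    sz, sy, sx = psf_sigma_um
    if max(psf_sigma_um) > 0:
        data = ndi.gaussian_filter(data, sigma=(sz / vz, sy / vy, sx / vx), mode="reflect")
    if poisson:
        if rng is None:
            rng = np.random.default_rng()
        data = rng.poisson(np.maximum(data, 0)).astype(np.float64)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        data = data + rng.normal(0.0, noise_sigma, size=data.shape)
    data = np.clip(data, 0.0, BIT12_CEILING)
    return ShgStack(
        data=data,
        voxel_um=tuple(voxel_um),
        normal_axis=fiber_set.normal_axis,
        meta=meta or fiber_set.meta,
        processing_log=[{"op": "synthesize", "intensity_scale": intensity_scale,
                         "noise_sigma": noise_sigma, "poisson": poisson}],
    )


def gen_paired_stacks(
    base_truth: PhantomTruth,
    intensity_ratio: float,
    shape_px: tuple[int, int, int] = (4, 1024, 1024),
    voxel_um: tuple[float, float, float] = (10.62, 1.21, 1.21),
):
    """A ventral/dorsal stack pair differing only in mean on-fiber intensity.

    Both stacks share one fiber geometry and one noise *distribution*
    (absolute sigma set by the base truth); the ventral on-fiber intensity
    is ``intensity_ratio`` × the dorsal one, exactly, before noise.
    Returns ``(ventral, dorsal)``.  If the scaled intensity exceeds the
    12-bit ceiling a ``clip_warning`` is recorded in the ventral stack's
    processing log.
    """
    if intensity_ratio <= 0:
        raise ValueError("intensity_ratio must be > 0")
    rng = np.random.default_rng(base_truth.seed)
    geom_truth = replace(base_truth, planted_crossing_count=0)
    # one geometry, rendered twice at different scales; dense fields are
    # fine here (no crossing bookkeeping), so separation is not enforced
    _, fiber_set, _ = gen_fiber_stack(
        replace(geom_truth, noise_sigma_frac=0.0, psf_sigma_um=(0, 0, 0)),
        shape_px=shape_px, voxel_um=voxel_um, separation_um=0.0,
    )
    noise_sigma = base_truth.noise_sigma_frac * base_truth.intensity_scale
    dorsal = render_fiber_set(
        fiber_set, shape_px, voxel_um,
        intensity_scale=base_truth.intensity_scale,
        psf_sigma_um=base_truth.psf_sigma_um,
        noise_sigma=noise_sigma, poisson=base_truth.poisson, rng=rng,
        meta=SampleMeta(surface="dorsal"),
    )
    ventral_scale = base_truth.intensity_scale * intensity_ratio
    ventral = render_fiber_set(
        fiber_set, shape_px, voxel_um,
        intensity_scale=ventral_scale,
        psf_sigma_um=base_truth.psf_sigma_um,
        noise_sigma=noise_sigma, poisson=base_truth.poisson, rng=rng,
        meta=SampleMeta(surface="ventral"),
    )
    if ventral_scale > BIT12_CEILING:
        ventral.processing_log.append(
            {"op": "synthesize_pair", "clip_warning": True,
             "requested_scale": ventral_scale, "ceiling": BIT12_CEILING}
        )
    return ventral, dorsal
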