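"""Mean SHG intensity over randomly placed regions of interest and
dorsal-vs-ventral intensity contrast.

ROIs are fixed physical sizes (200 μm × 250 μm by default), placed
uniformly at random in the admissible region — at least ``margin_px``
from every image boundary — and, by default, pairwise non-overlapping to
avoid pseudo-replication.  Means are taken on the maximum-intensity z
projection, the same view the summary images use; per-slice analysis is
available via ``plane``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SampleMeta, ShgStack


class PlacementError(RuntimeError):
    """Raised when the requested ROIs cannot be placed; reports how many fit."""

    def __init__(self, requested: int, placed: int, msg: str | None = None):
        self.requested = requested
        self.max_feasible = placed
        super().__init__(
            msg or f"could only place {placed} of {requested} requested ROIs"
        )


@dataclass(frozen=True)
class RoiSpec:
    """An axis-aligned in-plane ROI: origin and size in pixels (half-open box)."""

    origin_px: tuple[int, int]          # (y, x)
    size_px: tuple[int, int]            # (h, w)

    def slices(self) -> tuple[slice, slice]:
        (y, x), (h, w) = self.origin_px, self.size_px
        return slice(y, y + h), slice(x, x + w)

    def overlaps(self, other: "RoiSpec") -> bool:
        (ay, ax), (ah, aw) = self.origin_px, self.size_px
        (by, bx), (bh, bw) = other.origin_px, other.size_px
        return ay < by + bh and by < ay + ah and ax < bx + bw and bx < ax + aw


@dataclass
class IntensityResult:
    """Per-ROI mean intensities of one sample plus their grand mean ± sd."""

    per_roi_mean: np.ndarray
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self) -> None:
        self.per_roi_mean = np.asarray(self.per_roi_mean, dtype=float)

    @property
    def grand_mean(self) -> float:
        return float(np.mean(self.per_roi_mean)) if self.per_roi_mean.size else float("nan")

    @property
    def grand_sd(self) -> float:
        return float(np.std(self.per_roi_mean, ddof=1)) if self.per_roi_mean.size > 1 else 0.0


@dataclass
class ContrastResult:
    """Fold change of grand means between two samples plus the test outcome."""

    fold_change: float
    stat: "object"   # StatResult from stats_report
    a_meta: SampleMeta
    b_meta: SampleMeta


def sample_rois(
    s: ShgStack,
    n: int = 10,
    size_um: tuple[float, float] = (200.0, 250.0),
    margin_px: int = 150,
    seed: int = 0,
    non_overlap: bool = True,
    max_tries_per_roi: int = 2000,
) -> list[RoiSpec]:
    """Place ``n`` ROIs of physical size ``size_um`` uniformly at random.

    Origins are drawn uniformly over the admissible region (inside the
    margins, fully containing the ROI).  With ``non_overlap`` (default),
    candidates overlapping an already-placed ROI are redrawn; if an ROI
    cannot be placed within the retry budget a :class:`PlacementError`
    reports the number that did fit.  Deterministic given ``seed``.
    """
    if n == 0:
        return []
    _, ny, nx = s.shape
    _, vy, vx = s.voxel_um
    h = int(round(size_um[0] / vy))
    w = int(round(size_um[1] / vx))
    y_lo, y_hi = margin_px, ny - margin_px - h
    x_lo, x_hi = margin_px, nx - margin_px - w
    if y_hi < y_lo or x_hi < x_lo:
        raise PlacementError(n, 0, f"ROI of {h}×{w} px with margin {margin_px} "
                                   f"does not fit in a {ny}×{nx} image")
    rng = np.random.default_rng(seed)
    placed: list[RoiSpec] = []
    for _ in range(n):
        ok = False
        for _ in range(max_tries_per_roi):
            cand = RoiSpec(
                origin_px=(int(rng.integers(y_lo, y_hi + 1)),
                           int(rng.integers(x_lo, x_hi + 1))),
                size_px=(h, w),
            )
            if non_overlap and any(cand.overlaps(p) for p in placed):
                continue
            placed.append(cand)
            ok = True
            break
        if not ok:
            raise PlacementError(n, len(placed))
    return placed


def roi_mean_intensity(
    s: ShgStack,
    rois: list[RoiSpec],
    plane: str = "max_projection",
) -> IntensityResult:
    """Arithmetic mean intensity inside each ROI.

    ``plane`` is ``"max_projection"`` (default: ROIs evaluated on the
    maximum-intensity z projection) or an integer-valued string / int for
    a single slice.
    """
    if plane == "max_projection":
        img = s.max_projection()
    else:
        img = s.data[int(plane)]
    ny, nx = img.shape
    means = []
    for i, roi in enumerate(rois):
        ys, xs = roi.slices()
        if ys.stop > ny or xs.stop > nx or ys.start < 0 or xs.start < 0:
            raise IndexError(f"ROI {i} at {roi.origin_px} size {roi.size_px} "
                             f"lies outside the {ny}×{nx} image")
        means.append(float(img[ys, xs].mean()))
    return IntensityResult(per_roi_mean=np.array(means), meta=s.meta)


def intensity_contrast(a: IntensityResult, b: IntensityResult) -> ContrastResult:
    """Fold change a/b of the grand means plus a two-sample comparison."""
    from .stats_report import compare_groups

    if a.per_roi_mean.size == 0 or b.per_roi_mean.size == 0:
        raise ValueError("both intensity results must be non-empty")
    if b.grand_mean == 0:
        raise ZeroDivisionError("undefined ratio: denominator grand mean is 0")
    stat = compare_groups(a.per_roi_mean, b.per_roi_mean)
    return ContrastResult(
        fold_change=a.grand_mean / b.grand_mean,
        stat=stat,
        a_meta=a.meta,
        b_meta=b.meta,
    )
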