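"""Shared data containers for the skin-imaging pipeline.

Conventions used throughout the package:

* Image arrays are indexed ``(z, y, x)`` for stacks and ``(y, x)`` for
  sections, 0-based with half-open pixel boxes; physical coordinates sit
  at pixel centers.
* The outward normal of the skin surface is an in-plane axis stored on
  each container (``normal_axis``, ``"y"`` by default).  Fiber angles are
  measured from that normal: a fiber running along the normal has
  θ = 0° ("perpendicular" to the skin surface), a fiber running along
  the surface has θ = 90° ("parallel").  Orientations are undirected, so
  θ lives in [0, 180).
* Physical units: μm inside image-space code, mm in the thickness
  reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

LAYER_LABELS = {"background": 0, "SC": 1, "VE": 2, "D": 3}
LAYER_NAMES = {v: k for k, v in LAYER_LABELS.items()}
TISSUE_LAYERS = ("SC", "VE", "D")


@dataclass
class SampleMeta:
    """Identity of a skin sample: which surface, how far from the trunk tip."""

    surface: str = "dorsal"
    distance_from_tip_cm: float = 0.0
    specimen_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.surface not in ("dorsal", "ventral"):
            raise ValueError(f"surface must be 'dorsal' or 'ventral', got {self.surface!r}")
        if self.distance_from_tip_cm < 0:
            raise ValueError("distance_from_tip_cm must be >= 0")

    def to_dict(self) -> dict:
        return {
            "surface": self.surface,
            "distance_from_tip_cm": self.distance_from_tip_cm,
            "specimen_id": self.specimen_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SampleMeta":
        return cls(
            surface=d.get("surface", "dorsal"),
            distance_from_tip_cm=float(d.get("distance_from_tip_cm", 0.0)),
            specimen_id=str(d.get("specimen_id", "synthetic")),
        )


@dataclass
class LayerImage:
    """A segmented histology section: labeled layers plus physical scale.

    ``labels`` holds 0 = background, 1 = stratum corneum (SC),
    2 = viable epidermis (VE), 3 = dermis (D).  ``normal_axis`` names the
    image axis that runs along the outward skin normal ("y" means axis 0,
    i.e. columns are strips perpendicular to the surface).
    """

    labels: np.ndarray
    pixel_size_mm: float
    meta: SampleMeta = field(default_factory=SampleMeta)
    normal_axis: str = "y"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be > 0")
        bad = np.setdiff1d(np.unique(self.labels), list(LAYER_NAMES))
        if bad.size:
            raise ValueError(f"unknown label value(s) {bad.tolist()}; expected 0..3")
        if self.normal_axis not in ("y", "x"):
            raise ValueError("normal_axis must be 'y' or 'x'")

    def canonical(self) -> "LayerImage":
        """Rotate so that the outward normal runs along axis 0 (columns = strips)."""
        if self.normal_axis == "y":
            return self
        return LayerImage(
            labels=np.rot90(self.labels),
            pixel_size_mm=self.pixel_size_mm,
            meta=self.meta,
            normal_axis="y",
        )


@dataclass
class ShgStack:
    """A single-channel SHG intensity stack with physical voxel size.

    Intensities are kept in floating point while processing; quantization
    to integers happens only on export.  ``processing_log`` is an ordered
    audit trail of the operations applied so far.
    """

    data: np.ndarray
    voxel_um: tuple[float, float, float] = (10.62, 1.21, 1.21)
    normal_axis: str = "y"
    meta: SampleMeta = field(default_factory=SampleMeta)
    processing_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("stack data must be 2-D or 3-D")
        if np.any(self.data < 0):
            raise ValueError("stack intensities must be non-negative")
        vz, vy, vx = self.voxel_um
        if min(vz, vy, vx) <= 0:
            raise ValueError("voxel sizes must be > 0")
        if self.normal_axis not in ("y", "x"):
            raise ValueError("normal_axis must be 'y' or 'x'")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, log_entry: dict | None = None) -> "ShgStack":
        log = list(self.processing_log)
        if log_entry is not None:
            log.append(log_entry)
        return ShgStack(
            data=data,
            voxel_um=self.voxel_um,
            normal_axis=self.normal_axis,
            meta=self.meta,
            processing_log=log,
        )

    def max_projection(self) -> np.ndarray:
        """Maximum-intensity projection along z (the 'stacked image' view)."""
        return self.data.max(axis=0)


def polyline_angle_deg(points: np.ndarray, normal_axis: str = "y") -> float:
    """In-plane orientation of a polyline, in degrees from the outward normal.

    The angle is the direction of the total-least-squares line through the
    (y, x) vertices, mapped into [0, 180).  ``points`` is (n, 2) as (y, x)
    or (n, 3) as (z, y, x); only the in-plane coordinates enter.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("polyline needs at least 2 points")
    yx = pts[:, -2:]
    centered = yx - yx.mean(axis=0)
    # principal direction of the vertex cloud == TLS line direction
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    dy, dx = v[:, np.argmax(w)]
    if normal_axis == "x":
        dy, dx = dx, dy
    theta = math.degrees(math.atan2(dx, dy)) % 180.0
    return theta


def angle_diff_deg(a: float, b: float) -> float:
    """Smallest difference between two undirected orientations (degrees, ≤ 90)."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


@dataclass
class FiberSet:
    """Traced (or ground-truth) fibers: polylines with per-fiber attributes.

    ``fibers`` are (n_i, 3) arrays of (z, y, x) vertices in μm.  ``angles_deg``
    is the representative in-plane angle of each fiber measured from the
    outward normal; ``salience`` is the mean ridge response along the trace
    (1.0 for ground-truth fibers); ``radius_um`` the tube radius.
    """

    fibers: list = field(default_factory=list)
    angles_deg: np.ndarray = field(default_factory=lambda: np.empty(0))
    salience: np.ndarray = field(default_factory=lambda: np.empty(0))
    radius_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    normal_axis: str = "y"
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self) -> None:
        self.fibers = [np.atleast_2d(np.asarray(f, dtype=float)) for f in self.fibers]
        for f in self.fibers:
            if f.shape[0] < 2 or f.shape[1] != 3:
                raise ValueError("each fiber must be an (n>=2, 3) polyline of (z, y, x) μm")
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.salience = np.asarray(self.salience, dtype=float)
        self.radius_um = np.asarray(self.radius_um, dtype=float)
        n = len(self.fibers)
        if self.angles_deg.size == 0 and n:
            self.angles_deg = np.array(
                [polyline_angle_deg(f, self.normal_axis) for f in self.fibers]
            )
        if self.salience.size == 0 and n:
            self.salience = np.ones(n)
        if self.radius_um.size == 0 and n:
            self.radius_um = np.full(n, np.nan)
        for name, arr in (("angles_deg", self.angles_deg),
                          ("salience", self.salience),
                          ("radius_um", self.radius_um)):
            if arr.size != n:
                raise ValueError(f"{name} must have one entry per fiber")
        if n and (np.any(self.angles_deg < 0) or np.any(self.angles_deg >= 180)):
            raise ValueError("angles must lie in [0, 180)")
        if n and np.any(self.salience < 0):
            raise ValueError("salience must be >= 0")

    def __len__(self) -> int:
        return len(self.fibers)

    def subset(self, idx: Sequence[int]) -> "FiberSet":
        idx = np.asarray(idx, dtype=int)
        return FiberSet(
            fibers=[self.fibers[i] for i in idx],
            angles_deg=self.angles_deg[idx],
            salience=self.salience[idx],
            radius_um=self.radius_um[idx],
            normal_axis=self.normal_axis,
            meta=self.meta,
        )
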