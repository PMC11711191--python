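"""Reading and writing the pipeline's on-disk formats.

Stacks travel as multi-page TIFF with the in-plane pixel size in the
TIFF resolution tags and the z spacing in ImageJ-style metadata; masks
as single-page 8-bit label TIFFs.  Sample metadata and processing logs
ride in JSON sidecars (``<file>.json``).  Loading never applies any
processing: a 16-bit stack with values above the display clip loads
unclipped, because clipping is a pipeline stage, not an I/O side effect.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .core import FiberSet, LayerImage, SampleMeta, ShgStack


class FormatError(ValueError):
    """Raised for unreadable files or files with ambiguous physical units."""


def _sidecar(path) -> Path:
    return Path(str(path) + ".json")


def write_stack(s: ShgStack, path) -> None:
    """Write a stack as multi-page TIFF (uint16, rounded) + JSON sidecar."""
    path = Path(path)
    vz, vy, vx = s.voxel_um
    data = np.clip(np.round(s.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path, data, imagej=True,
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={"spacing": vz, "unit": "um", "axes": "ZYX"},
    )
    _sidecar(path).write_text(json.dumps({
        "voxel_um": [vz, vy, vx],
        "normal_axis": s.normal_axis,
        "meta": s.meta.to_dict(),
        "processing_log": s.processing_log,
    }, indent=2))


def read_stack(path, voxel_um=None) -> ShgStack:
    """Read a stack TIFF, honoring resolution metadata.

    Physical units are taken from the JSON sidecar when present, else
    from the TIFF tags; if neither yields a voxel size and none is passed
    explicitly, a :class:`FormatError` is raised rather than silently
    assuming one.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(np.float64)
        side = _sidecar(path)
        normal_axis, meta, log = "y", SampleMeta(), []
        if side.exists():
            sc = json.loads(side.read_text())
            voxel_um = voxel_um or tuple(sc["voxel_um"])
            normal_axis = sc.get("normal_axis", "y")
            meta = SampleMeta.from_dict(sc.get("meta", {}))
            log = sc.get("processing_log", [])
        elif voxel_um is None:
            try:
                page = tf.pages[0]
                xres = page.tags["XResolution"].value
                yres = page.tags["YResolution"].value
                vx = xres[1] / xres[0]
                vy = yres[1] / yres[0]
                vz = float(tf.imagej_metadata.get("spacing")) if tf.imagej_metadata else None
                if vz is None:
                    raise KeyError("spacing")
                voxel_um = (vz, vy, vx)
            except (KeyError, TypeError, ZeroDivisionError) as exc:
                raise FormatError(
                    f"{path}: no voxel size in metadata and none supplied"
                ) from exc
    if data.ndim == 2:
        data = data[None]
    return ShgStack(data=data, voxel_um=tuple(voxel_um),
                    normal_axis=normal_axis, meta=meta, processing_log=log)


def write_mask(img: LayerImage, path) -> None:
    """Write a label mask as single-page uint8 TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, img.labels.astype(np.uint8))
    _sidecar(path).write_text(json.dumps({
        "pixel_size_mm": img.pixel_size_mm,
        "normal_axis": img.normal_axis,
        "meta": img.meta.to_dict(),
    }, indent=2))


def read_mask(path, pixel_size_mm=None) -> LayerImage:
    """Read a label mask; labels outside {0, 1, 2, 3} are a format error."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    labels = tifffile.imread(path)
    side = _sidecar(path)
    normal_axis, meta = "y", SampleMeta()
    if side.exists():
        sc = json.loads(side.read_text())
        pixel_size_mm = pixel_size_mm or sc["pixel_size_mm"]
        normal_axis = sc.get("normal_axis", "y")
        meta = SampleMeta.from_dict(sc.get("meta", {}))
    if pixel_size_mm is None:
        raise FormatError(f"{path}: no pixel size in sidecar and none supplied")
    try:
        return LayerImage(labels=labels, pixel_size_mm=pixel_size_mm,
                          meta=meta, normal_axis=normal_axis)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_fiberset(f: FiberSet, path) -> None:
    Path(path).write_text(json.dumps({
        "fibers": [fb.tolist() for fb in f.fibers],
        "angles_deg": f.angles_deg.tolist(),
        "salience": f.salience.tolist(),
        "radius_um": [None if np.isnan(r) else r for r in f.radius_um],
        "normal_axis": f.normal_axis,
        "meta": f.meta.to_dict(),
    }))


def read_fiberset(path) -> FiberSet:
    d = json.loads(Path(path).read_text())
    return FiberSet(
        fibers=[np.asarray(fb) for fb in d["fibers"]],
        angles_deg=np.asarray(d["angles_deg"]),
        salience=np.asarray(d["salience"]),
        radius_um=np.asarray([np.nan if r is None else r for r in d["radius_um"]]),
        normal_axis=d.get("normal_axis", "y"),
        meta=SampleMeta.from_dict(d.get("meta", {})),
    )


def write_tables(report, out_dir) -> list[Path]:
    """Write a ReportSet as per-section CSVs, a comparisons JSON and a
    Markdown summary.  Deterministic: no timestamps, stable ordering."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in report.sections.items():
        fname = name.split("(")[0].strip().replace(" ", "_") + ".csv"
        p = out_dir / fname
        df.to_csv(p, index=False)
        written.append(p)
    if report.comparisons:
        comp = {
            name: {
                "test": r.test_name, "statistic": r.statistic,
                "p_value": r.p_value, "stars": r.stars,
                "n_per_group": list(r.n_per_group),
                "normality_ok": list(r.normality_ok),
                "variance_homogeneous": r.variance_homogeneous,
            }
            for name, r in report.comparisons.items()
        }
        p = out_dir / "comparisons.json"
        p.write_text(json.dumps(comp, indent=2, sort_keys=True))
        written.append(p)
    p = out_dir / "report.md"
    p.write_text(report.to_markdown())
    written.append(p)
    return written
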