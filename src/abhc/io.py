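"""Volume IO: DICOM reading, the package's array container, configs.

DICOM series are read-only input (rescale slope/intercept applied to
HU, frames ordered by acquisition time); the internal interchange
format is a compressed ``.npz`` archive with a JSON sidecar carrying
spacing, frame times and protocol metadata, which round-trips
losslessly and keeps the toolchain free of DICOM-writing edge cases.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .phantoms import DynamicSeries
from .simulator import CTImage, Geometry

__all__ = [
    "save_series",
    "load_series",
    "save_image",
    "load_image",
    "read_ct_volume",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_series(series: DynamicSeries, path: str | Path) -> Path:
    path = Path(path)
    np.savez_compressed(path, frames=series.frames, times_s=series.times_s)
    meta = {
        "kind": "dynamic_series",
        "protocol": series.protocol,
        "seed": series.seed,
        "geometry": _geometry_meta(series.geometry),
    }
    _sidecar(path.with_suffix(".npz")).write_text(json.dumps(meta, indent=2))
    return path.with_suffix(".npz")


def load_series(path: str | Path) -> DynamicSeries:
    path = Path(path)
    data = np.load(path)
    meta = json.loads(_sidecar(path).read_text())
    if meta.get("kind") != "dynamic_series":
        raise ValueError(f"{path} is not a dynamic-series container")
    return DynamicSeries(
        data["frames"], data["times_s"],
        geometry=_geometry_from_meta(meta["geometry"]),
        protocol=meta.get("protocol", ""),
        seed=meta.get("seed"),
    )


def save_image(image: CTImage, path: str | Path) -> Path:
    path = Path(path)
    np.savez_compressed(path, values=image.values)
    meta = {
        "kind": "ct_image",
        "reference_energy_kev": image.reference_energy_kev,
        "slice_thickness_mm": image.slice_thickness_mm,
        "geometry": _geometry_meta(image.geometry),
    }
    _sidecar(path.with_suffix(".npz")).write_text(json.dumps(meta, indent=2))
    return path.with_suffix(".npz")


def load_image(path: str | Path) -> CTImage:
    path = Path(path)
    data = np.load(path)
    meta = json.loads(_sidecar(path).read_text())
    if meta.get("kind") != "ct_image":
        raise ValueError(f"{path} is not a CT-image container")
    return CTImage(
        data["values"], _geometry_from_meta(meta["geometry"]),
        reference_energy_kev=meta.get("reference_energy_kev", 70.0),
        slice_thickness_mm=meta.get("slice_thickness_mm", 2.0),
    )


def _geometry_meta(geometry: Geometry | None) -> dict | None:
    if geometry is None:
        return None
    return {
        "n_pixels": geometry.n_pixels,
        "pixel_size_mm": geometry.pixel_size_mm,
        "n_angles": geometry.n_angles,
        "detector_oversample": geometry.detector_oversample,
    }


def _geometry_from_meta(meta: dict | None) -> Geometry | None:
    if meta is None:
        return None
    return Geometry(**meta)


def read_ct_volume(path: str | Path):
    """Read a DICOM directory (or array container) into HU.

    A directory is treated as a DICOM series: every readable file is
    loaded, rescale slope/intercept are applied, frames are ordered by
    acquisition/trigger time, and mixed pixel spacings are rejected.
    A ``.npz`` file is dispatched to the container loaders.
    """
    path = Path(path)
    if path.suffix == ".npz":
        meta = json.loads(_sidecar(path).read_text())
        if meta.get("kind") == "ct_image":
            return load_image(path)
        return load_series(path)
    import pydicom

    if not path.is_dir():
        raise ValueError(f"{path}: expected a DICOM directory or .npz container")
    frames = []
    for f in sorted(path.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if not hasattr(ds, "PixelData"):
            continue
        if not hasattr(ds, "RescaleSlope") or not hasattr(ds, "RescaleIntercept"):
            raise ValueError(f"{f.name}: missing rescale slope/intercept tags")
        hu = ds.pixel_array.astype(float) * float(ds.RescaleSlope) + float(
            ds.RescaleIntercept
        )
        t = _acquisition_seconds(ds)
        spacing = tuple(float(v) for v in getattr(ds, "PixelSpacing", (1.0, 1.0)))
        frames.append((t, spacing, hu))
    if not frames:
        raise ValueError(f"no DICOM images found under {path}")
    spacings = {fr[1] for fr in frames}
    if len(spacings) > 1:
        raise ValueError(f"mixed pixel spacings in series: {sorted(spacings)}")
    frames.sort(key=lambda fr: fr[0])
    spacing = frames[0][1]
    n = frames[0][2].shape[0]
    geometry = None
    if frames[0][2].shape[0] == frames[0][2].shape[1]:
        geometry = Geometry(n_pixels=n, pixel_size_mm=spacing[0], n_angles=max(n, 8))
    if len(frames) == 1:
        return CTImage(frames[0][2], geometry)
    times = np.array([fr[0] for fr in frames])
    if np.any(np.diff(times) <= 0):  # identical stamps: fall back to file order
        times = np.arange(len(frames), dtype=float)
    return DynamicSeries(
        np.stack([fr[2] for fr in frames]), times, geometry=geometry,
        protocol="dicom",
    )


def _acquisition_seconds(ds) -> float:
    for tag in ("AcquisitionTime", "ContentTime", "TriggerTime"):
        v = getattr(ds, tag, None)
        if v in (None, ""):
            continue
        if tag == "TriggerTime":
            return float(v) / 1000.0
        s = str(v)
        try:
            return int(s[0:2]) * 3600 + int(s[2:4]) * 60 + float(s[4:] or 0)
        except ValueError:
            continue
    return float(getattr(ds, "InstanceNumber", 0))
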