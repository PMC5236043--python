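"""Serialization: NIfTI volumes, YAML phantom specs, sinogram containers.

Volumes are written as NIfTI-1 with the grid spacing in the affine and the
frame timing in a JSON sidecar next to the image; phantoms round-trip
through YAML; sinograms are stored as compressed ``.npz`` arrays with a
JSON geometry sidecar.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .acquisition import ParallelGeometry, SinogramFrame
from .decay import Isotope
from .grid import ActivityImage, VoxelGrid
from .phantom import BackgroundSpec, BoxRegion, PhantomSpec, SphereSpec

__all__ = [
    "save_image",
    "load_image",
    "save_phantom",
    "load_phantom",
    "save_sinogram",
    "load_sinogram",
]


def save_image(img: ActivityImage, path) -> Path:
    path = Path(path)
    affine = np.diag([*img.grid.spacing, 1.0])
    affine[:3, 3] = img.grid.origin
    nib.save(nib.Nifti1Image(img.values, affine), str(path))
    meta = {
        "frame_start": img.frame_start,
        "frame_duration": img.frame_duration,
        "meta": {k: v for k, v in img.meta.items() if isinstance(v, (int, float, str))},
    }
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def load_image(path) -> ActivityImage:
    path = Path(path)
    nii = nib.load(str(path))
    affine = nii.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(o) for o in affine[:3, 3])
    values = np.asarray(nii.get_fdata())
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    grid = VoxelGrid(dims=values.shape, spacing=spacing, origin=origin)
    return ActivityImage(
        grid=grid,
        values=values,
        frame_start=meta.get("frame_start", 0.0),
        frame_duration=meta.get("frame_duration", 10.0),
        meta=meta.get("meta", {}),
    )


def _sphere_dict(s: SphereSpec) -> dict:
    return {
        "diameter": s.diameter,
        "center": list(s.center),
        "concentration0": s.concentration0,
        "isotope": {"name": s.isotope.name, "half_life": s.isotope.half_life},
    }


def _box_dict(b: BoxRegion) -> dict:
    return {"center": list(b.center), "size": list(b.size)}


def save_phantom(phantom: PhantomSpec, path) -> Path:
    path = Path(path)
    doc = {
        "spheres": [_sphere_dict(s) for s in phantom.spheres],
        "background": {
            "region": _box_dict(phantom.background.region),
            "concentration0": phantom.background.concentration0,
            "isotope": {
                "name": phantom.background.isotope.name,
                "half_life": phantom.background.isotope.half_life,
            },
        },
        "reference_source": _box_dict(phantom.reference_source),
        "reference_voi": _box_dict(phantom.reference_voi),
        "background_voi": _box_dict(phantom.background_voi),
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def load_phantom(path) -> PhantomSpec:
    doc = yaml.safe_load(Path(path).read_text())
    spheres = tuple(
        SphereSpec(
            diameter=s["diameter"],
            center=tuple(s["center"]),
            concentration0=s["concentration0"],
            isotope=Isotope(**s["isotope"]),
        )
        for s in doc["spheres"]
    )
    bg = doc["background"]
    return PhantomSpec(
        spheres=spheres,
        background=BackgroundSpec(
            region=BoxRegion(**bg["region"]),
            concentration0=bg["concentration0"],
            isotope=Isotope(**bg["isotope"]),
        ),
        reference_source=BoxRegion(**doc["reference_source"]),
        reference_voi=BoxRegion(**doc["reference_voi"]),
        background_voi=BoxRegion(**doc["background_voi"]),
    )


def save_sinogram(frame: SinogramFrame, path) -> Path:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    np.savez_compressed(path, counts=frame.counts)
    meta = {
        "mode": frame.mode,
        "frame_start": frame.frame_start,
        "frame_duration": frame.frame_duration,
        "scale": frame.scale,
        "grid": {
            "dims": list(frame.grid.dims),
            "spacing": list(frame.grid.spacing),
            "origin": list(frame.grid.origin),
        },
        "geometry": asdict(frame.geometry) if frame.geometry else None,
    }
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def load_sinogram(path) -> SinogramFrame:
    path = Path(path)
    if not path.suffix:
        path = path.with_suffix(".npz")
    counts = np.load(path)["counts"]
    meta = json.loads(Path(str(path) + ".json").read_text())
    g = meta["geometry"]
    geometry = None
    if g is not None:
        g["in_plane_dims"] = tuple(g["in_plane_dims"])
        g["in_plane_spacing"] = tuple(g["in_plane_spacing"])
        geometry = ParallelGeometry(**g)
    grid = VoxelGrid(
        dims=tuple(meta["grid"]["dims"]),
        spacing=tuple(meta["grid"]["spacing"]),
        origin=tuple(meta["grid"]["origin"]),
    )
    return SinogramFrame(
        counts=counts,
        geometry=geometry,
        grid=grid,
        frame_start=meta["frame_start"],
        frame_duration=meta["frame_duration"],
        mode=meta["mode"],
        scale=meta["scale"],
    )
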