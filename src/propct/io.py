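"""Standard-format I/O: projection stacks, phantoms and volumes.

Two on-disk representations are supported for projection stacks:

* a single HDF5 file (datasets ``frames``, ``angles``, optional ``flats`` /
  ``darks``; attrs ``pixel_um``, JSON-encoded ``geometry`` and ``meta``);
* a multi-page 32-bit float TIFF plus a JSON sidecar (``<name>.json``)
  holding angles, pixel size, geometry and metadata.

Data are stored float32, computed float64. Angle metadata is mandatory on
read — a stack without angles is not silently given defaults. HDF5 datasets
are written with ``track_times=False`` so identical data produce identical
files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .geometry import ConeBeamGeometry
from .phantom import VoxelPhantom
from .recon import ReconVolume
from .waveprop import ProjectionStack

__all__ = [
    "read_stack",
    "write_stack",
    "read_volume",
    "write_volume",
    "read_phantom",
    "write_phantom",
]

_H5_OPTS = dict(track_times=False)


def _geom_to_json(geom: ConeBeamGeometry | None) -> str:
    return json.dumps(dataclasses.asdict(geom)) if geom is not None else ""


def _geom_from_json(s: str) -> ConeBeamGeometry | None:
    if not s:
        return None
    return ConeBeamGeometry(**json.loads(s))


def write_stack(stack: ProjectionStack, path: str | Path) -> Path:
    """Write a projection stack as HDF5 (.h5/.hdf5) or TIFF+JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=stack.frames.astype(np.float32), **_H5_OPTS)
            f.create_dataset("angles", data=stack.angles_deg, **_H5_OPTS)
            if stack.flats is not None:
                f.create_dataset("flats", data=np.asarray(stack.flats, np.float32), **_H5_OPTS)
            if stack.darks is not None:
                f.create_dataset("darks", data=np.asarray(stack.darks, np.float32), **_H5_OPTS)
            f.attrs["pixel_um"] = stack.pixel_um
            f.attrs["geometry"] = _geom_to_json(stack.geometry)
            f.attrs["meta"] = json.dumps(stack.meta)
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, stack.frames.astype(np.float32))
        sidecar = {
            "angles_deg": stack.angles_deg.tolist(),
            "pixel_um": stack.pixel_um,
            "geometry": dataclasses.asdict(stack.geometry) if stack.geometry else None,
            "meta": stack.meta,
        }
        if stack.flats is not None:
            tifffile.imwrite(path.with_suffix(".flats.tif"),
                             np.asarray(stack.flats, np.float32))
        if stack.darks is not None:
            tifffile.imwrite(path.with_suffix(".darks.tif"),
                             np.asarray(stack.darks, np.float32))
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    else:
        raise ValueError(f"unsupported stack format {path.suffix!r} (use .h5 or .tif)")
    return path


def read_stack(path: str | Path) -> ProjectionStack:
    """Read a projection stack written by :func:`write_stack`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "angles" not in f:
                raise ValueError(f"{path}: missing angle metadata")
            return ProjectionStack(
                frames=f["frames"][()].astype(np.float64),
                angles_deg=f["angles"][()],
                pixel_um=float(f.attrs["pixel_um"]),
                flats=f["flats"][()].astype(np.float64) if "flats" in f else None,
                darks=f["darks"][()].astype(np.float64) if "darks" in f else None,
                geometry=_geom_from_json(f.attrs.get("geometry", "")),
                meta=json.loads(f.attrs.get("meta", "{}")),
            )
    if path.suffix.lower() in (".tif", ".tiff"):
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise ValueError(f"{path}: missing JSON sidecar with angle metadata")
        side = json.loads(sidecar_path.read_text())
        if "angles_deg" not in side:
            raise ValueError(f"{sidecar_path}: missing angle metadata")
        flats_p = path.with_suffix(".flats.tif")
        darks_p = path.with_suffix(".darks.tif")
        geom = side.get("geometry")
        return ProjectionStack(
            frames=tifffile.imread(path).astype(np.float64),
            angles_deg=np.asarray(side["angles_deg"], dtype=np.float64),
            pixel_um=float(side["pixel_um"]),
            flats=tifffile.imread(flats_p).astype(np.float64) if flats_p.exists() else None,
            darks=tifffile.imread(darks_p).astype(np.float64) if darks_p.exists() else None,
            geometry=ConeBeamGeometry(**geom) if geom else None,
            meta=side.get("meta", {}),
        )
    raise ValueError(f"unsupported stack format {path.suffix!r}")


def write_volume(vol: ReconVolume, path: str | Path) -> Path:
    """Write a reconstructed volume as HDF5 (dataset ``mu``, attrs provenance)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("mu", data=vol.mu_grid.astype(np.float32), **_H5_OPTS)
        f.attrs["voxel_um"] = vol.voxel_um
        f.attrs["provenance"] = json.dumps(vol.provenance, sort_keys=True)
    return path


def read_volume(path: str | Path) -> ReconVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        return ReconVolume(
            mu_grid=f["mu"][()].astype(np.float64),
            voxel_um=float(f.attrs["voxel_um"]),
            provenance=json.loads(f.attrs.get("provenance", "{}")),
        )


def write_phantom(phantom: VoxelPhantom, path: str | Path, params_json: str = "") -> Path:
    """Write a voxel phantom as HDF5 (datasets delta, beta, labels)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("delta", data=phantom.delta_grid.astype(np.float32), **_H5_OPTS)
        f.create_dataset("beta", data=phantom.beta_grid.astype(np.float32), **_H5_OPTS)
        f.create_dataset("labels", data=phantom.labels.astype(np.int8), **_H5_OPTS)
        f.attrs["voxel_um"] = phantom.voxel_um
        f.attrs["params"] = params_json
    return path


def read_phantom(path: str | Path) -> VoxelPhantom:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        return VoxelPhantom(
            delta_grid=f["delta"][()].astype(np.float64),
            beta_grid=f["beta"][()].astype(np.float64),
            labels=f["labels"][()],
            voxel_um=float(f.attrs["voxel_um"]),
        )
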