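"""Readers and writers: TIFF stacks, YAML acquisition schemes, HDF5 fields.

Formats: intensity volumes and maps travel as multi-page TIFF; SHFields, PSF
sets and Gaunt/Wigner caches as HDF5 with a channel table and a convention
tag; acquisition schemes as YAML lists of {view, pol_deg, tilt_deg}; profiles
as CSV.  Every artifact carries enough metadata to re-create it.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from . import __version__
from .field import SHField
from .gaunt import GauntTensor
from .psf import AcquisitionScheme, PolarizationState
from .sphere import EVEN_CHANNELS
from .wigner import WignerRotation

CONVENTION = "real-orthonormal-noCS-even4"


# ------------------------------------------------------------------- TIFF
def write_stack(volume: np.ndarray, path, voxel_size: float | None = None) -> None:
    """Write a 3D volume as a multi-page TIFF (lossless for uint16/float32)."""
    volume = np.asarray(volume)
    meta = {"axes": "ZYX"}
    if voxel_size is not None:
        meta["voxel_size_nm"] = voxel_size
    tifffile.imwrite(str(path), volume, metadata=meta)


def read_stack(path) -> tuple[np.ndarray, float | None]:
    """Read a multi-page TIFF volume; returns (volume, voxel_size_nm or None)."""
    with tifffile.TiffFile(str(path)) as tf:
        vol = tf.asarray()
        voxel = None
        try:
            desc = tf.pages[0].tags.get("ImageDescription")
            if desc is not None:
                meta = json.loads(desc.value)
                voxel = meta.get("voxel_size_nm")
        except Exception:
            pass
    if vol.ndim == 2:
        vol = vol[None]
    if vol.ndim != 3:
        raise ValueError(f"expected a 3D stack in {path}, got shape {vol.shape}")
    return vol, voxel


# ------------------------------------------------------------------ schemes
_SCHEME_KEYS = {"view", "pol_deg", "tilt_deg"}


def read_scheme(path) -> AcquisitionScheme:
    """Load a YAML/JSON acquisition scheme; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict):
        data = data.get("entries", data)
    if not isinstance(data, list) or len(data) == 0:
        raise ValueError(f"scheme file {path} must hold a non-empty entry list")
    entries = []
    for i, row in enumerate(data):
        unknown = set(row) - _SCHEME_KEYS
        if unknown:
            raise ValueError(f"scheme entry {i} has unknown keys {sorted(unknown)}")
        if "view" not in row or "pol_deg" not in row:
            raise ValueError(f"scheme entry {i} must define 'view' and 'pol_deg'")
        entries.append(
            PolarizationState(
                str(row["view"]), float(row["pol_deg"]), float(row.get("tilt_deg", 0.0))
            )
        )
    if len(set(entries)) < len(entries):
        warnings.warn("scheme contains duplicate entries", stacklevel=2)
    return AcquisitionScheme(tuple(entries))


def write_scheme(scheme: AcquisitionScheme, path) -> None:
    rows = [
        {"view": e.view, "pol_deg": e.pol_deg, "tilt_deg": e.tilt_deg}
        for e in scheme.entries
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(rows, fh, sort_keys=False)


# ------------------------------------------------------------------- HDF5
def write_field(field: SHField, path, extra: dict | None = None) -> None:
    """Write an SHField to HDF5 with the channel table and convention tag."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("coeffs", data=field.coeffs, compression="gzip")
        ds.attrs["voxel_size_nm"] = field.voxel_size
        ds.attrs["convention"] = CONVENTION
        ds.attrs["polodf_version"] = __version__
        f.create_dataset("channels", data=np.array(EVEN_CHANNELS, dtype=np.int8))
        for k, v in (extra or {}).items():
            ds.attrs[k] = v


def read_field(path) -> SHField:
    with h5py.File(path, "r") as f:
        ds = f["coeffs"]
        conv = ds.attrs.get("convention", CONVENTION)
        if conv != CONVENTION:
            raise ValueError(f"field in {path} uses convention {conv!r}")
        return SHField(ds[...], float(ds.attrs["voxel_size_nm"]))


def write_response(resp, path) -> None:
    """Serialize a SystemResponse (per-measurement SH-channel PSFs) to HDF5."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("psf", data=resp.psf, compression="gzip")
        ds.attrs["voxel_size_nm"] = resp.voxel_size
        ds.attrs["pad"] = resp.pad
        ds.attrs["shape"] = resp.shape
        ds.attrs["convention"] = CONVENTION
        ds.attrs["polodf_version"] = __version__
        rows = [(e.view, e.pol_deg, e.tilt_deg) for e in resp.entries]
        f.create_dataset(
            "entries",
            data=np.array(rows, dtype=[("view", "S1"), ("pol_deg", "f8"), ("tilt_deg", "f8")]),
        )


def read_response(path):
    """Load a SystemResponse written by :func:`write_response`."""
    from .psf import SystemResponse, psf_to_otf

    with h5py.File(path, "r") as f:
        ds = f["psf"]
        psf = ds[...]
        entries = tuple(
            PolarizationState(
                row["view"].decode(), float(row["pol_deg"]), float(row["tilt_deg"])
            )
            for row in f["entries"][...]
        )
        return SystemResponse(
            psf=psf,
            otf=psf_to_otf(psf),
            entries=entries,
            shape=tuple(int(s) for s in ds.attrs["shape"]),
            pad=int(ds.attrs["pad"]),
            voxel_size=float(ds.attrs["voxel_size_nm"]),
        )


def write_angular_cache(
    path, gaunt: GauntTensor | None = None, wigner: WignerRotation | None = None
) -> None:
    """Cache Gaunt/Wigner tables keyed by (convention, l_max)."""
    with h5py.File(path, "a") as f:
        if gaunt is not None:
            key = f"gaunt/{CONVENTION}/l{gaunt.l_max}"
            if key in f:
                del f[key]
            f.create_dataset(key, data=gaunt.values)
        if wigner is not None:
            for l, block in wigner.blocks.items():
                key = f"wigner_y90/{CONVENTION}/l{l}"
                if key in f:
                    del f[key]
                f.create_dataset(key, data=block)


def read_angular_cache(path, l_max: int = 4):
    """Load cached (GauntTensor, WignerRotation); missing parts return None."""
    gaunt = wigner = None
    with h5py.File(path, "r") as f:
        gkey = f"gaunt/{CONVENTION}/l{l_max}"
        if gkey in f:
            gaunt = GauntTensor(l_max=l_max, values=f[gkey][...])
        wkeys = {l: f"wigner_y90/{CONVENTION}/l{l}" for l in (0, 2, 4)}
        if all(k in f for k in wkeys.values()):
            wigner = WignerRotation({l: f[k][...] for l, k in wkeys.items()})
    return gaunt, wigner


def write_profile_csv(path, distances_nm: np.ndarray, values: np.ndarray, name="mean_op"):
    arr = np.column_stack([distances_nm, values])
    np.savetxt(path, arr, delimiter=",", header=f"distance_nm,{name}", comments="")


def scheme_path(name: str) -> Path:
    """Path of a bundled editable scheme preset (scheme18 / scheme8 / scheme6)."""
    p = Path(__file__).parent / "schemes" / f"{name}.yaml"
    if not p.exists():
        raise FileNotFoundError(f"no bundled scheme named {name!r}")
    return p
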