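"""NIfTI / JSON-sidecar / CSV plumbing.

Conventions: times are milliseconds everywhere on disk, image data are
float32 NIfTI, the 4-D stack is ordered (x, y, 1, contrast*echo), and the
sidecar lists per-volume (TS, T2p, TE) with ``"inf"`` allowed for TS.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import nibabel as nib
import numpy as np

from .fitting import ParameterMaps

SIDECAR_SCHEMA_VERSION = 1


class SidecarError(ValueError):
    """Malformed sidecar: missing or invalid per-volume coordinates."""


def _affine(pixel_size: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = pixel_size
    return aff


def save_stack(
    path, stack: np.ndarray, TS, T2p, TE, pixel_size: float = 2.0
) -> None:
    """Write a (ny, nx, n) stack as 4-D NIfTI plus a ``.json`` sidecar."""
    path = Path(path)
    stack = np.asarray(stack, np.float32)
    img = nib.Nifti1Image(stack[:, :, None, :], _affine(pixel_size))
    nib.save(img, str(path))
    sidecar = {
        "schema_version": SIDECAR_SCHEMA_VERSION,
        "units": "ms",
        "volumes": {
            str(i): {
                "TS": "inf" if math.isinf(ts) else float(ts),
                "T2p": float(t2p),
                "TE": float(te),
            }
            for i, (ts, t2p, te) in enumerate(zip(TS, T2p, TE))
        },
    }
    sidecar_path = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" \
        else path.with_suffix(".json")
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_stack(path) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Read a 4-D NIfTI + sidecar; returns (stack(ny,nx,n), TS, T2p, TE)."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, float)
    if data.ndim == 4:
        data = data[:, :, 0, :]
    sidecar_path = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" \
        else path.with_suffix(".json")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    vols = sidecar.get("volumes", {})
    n = data.shape[-1]
    TS = np.empty(n)
    T2p = np.empty(n)
    TE = np.empty(n)
    for i in range(n):
        entry = vols.get(str(i))
        if entry is None:
            raise SidecarError(f"sidecar is missing volume {i}")
        for key in ("TS", "T2p", "TE"):
            if key not in entry:
                raise SidecarError(f"volume {i} is missing {key!r}")
        ts = entry["TS"]
        TS[i] = math.inf if ts in ("inf", None) else float(ts)
        T2p[i] = float(entry["T2p"])
        TE[i] = float(entry["TE"])
    return data, TS, T2p, TE


def save_maps(outdir, maps: ParameterMaps, pixel_size: float = 2.0) -> dict[str, Path]:
    """One float32 NIfTI per parameter and SD map, plus the fitted-voxel mask."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, arr in maps.map_dict().items():
        p = outdir / f"{name}.nii"
        nib.save(nib.Nifti1Image(np.asarray(arr, np.float32), _affine(pixel_size)), str(p))
        written[name] = p
    p = outdir / "mask.nii"
    nib.save(nib.Nifti1Image(maps.mask.astype(np.uint8), _affine(pixel_size)), str(p))
    written["mask"] = p
    return written
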