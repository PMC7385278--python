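"""Volume I/O: NIfTI, MetaImage, multipage TIFF, raw uint16 + sidecar.

All formats round-trip the (z, y, x) grid and the isotropic spacing.
NIfTI and MetaImage carry spacing natively (converted to millimetres in
headers); TIFF stacks and raw files use a JSON sidecar ``<path>.json``
holding ``shape`` (raw only), ``spacing_um`` and the integer rescale
``slope``/``intercept`` mapping stored counts to HU. Integer label masks
are stored losslessly.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import tifffile

from .core import CTVolume

# HU = slope * stored + intercept for unsigned 16-bit containers
_U16_SLOPE = 1.0
_U16_INTERCEPT = -1024.0


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_volume(
    data: CTVolume | np.ndarray,
    path: str | Path,
    spacing_um: float | None = None,
) -> Path:
    """Write an HU volume or an integer mask; format from the suffix.

    Supported: ``.nii``/``.nii.gz``, ``.mha``/``.mhd``, ``.tif``/``.tiff``
    (uint16 with sidecar) and ``.raw`` (uint16 with sidecar). Masks
    (integer arrays) are stored as their integer values without rescale.
    """
    path = Path(path)
    if isinstance(data, CTVolume):
        array = data.values
        spacing = data.spacing_um
        is_mask = False
    else:
        array = np.asarray(data)
        if spacing_um is None:
            raise ValueError("spacing_um required when writing a bare array")
        spacing = float(spacing_um)
        is_mask = array.dtype.kind in "biu"
    suffix = "".join(path.suffixes[-2:]) if path.name.endswith(".nii.gz") else path.suffix

    if suffix in (".nii", ".nii.gz"):
        if is_mask:
            img_data = array.astype(np.int16)
        else:
            img_data = array.astype(np.float32)
        affine = np.diag([spacing / 1000.0] * 3 + [1.0])
        img = nib.Nifti1Image(img_data, affine)
        img.header.set_zooms((spacing / 1000.0,) * 3)
        nib.save(img, str(path))
    elif suffix in (".mha", ".mhd"):
        img = sitk.GetImageFromArray(
            array.astype(np.int16) if is_mask else array.astype(np.float32)
        )
        img.SetSpacing((spacing / 1000.0,) * 3)
        sitk.WriteImage(img, str(path))
    elif suffix in (".tif", ".tiff"):
        if is_mask:
            stored = array.astype(np.uint16)
            slope, intercept = 1.0, 0.0
        else:
            stored = np.round(array - _U16_INTERCEPT).astype(np.uint16)
            slope, intercept = _U16_SLOPE, _U16_INTERCEPT
        tifffile.imwrite(str(path), stored)
        _sidecar_path(path).write_text(
            json.dumps(
                {
                    "spacing_um": spacing,
                    "slope": slope,
                    "intercept": intercept,
                    "is_mask": is_mask,
                }
            )
        )
    elif suffix == ".raw":
        if is_mask:
            stored = array.astype(np.uint16)
            slope, intercept = 1.0, 0.0
        else:
            stored = np.round(array - _U16_INTERCEPT).astype(np.uint16)
            slope, intercept = _U16_SLOPE, _U16_INTERCEPT
        stored.tofile(str(path))
        _sidecar_path(path).write_text(
            json.dumps(
                {
                    "shape": list(array.shape),
                    "dtype": "uint16",
                    "spacing_um": spacing,
                    "slope": slope,
                    "intercept": intercept,
                    "is_mask": is_mask,
                }
            )
        )
    else:
        raise ValueError(f"unsupported volume format {suffix!r}")
    return path


def _load_sidecar(path: Path, required: tuple[str, ...]) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"missing sidecar metadata file {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    for key in required:
        if key not in meta:
            raise ValueError(f"sidecar {sidecar.name} lacks required field {key!r}")
    return meta


def read_volume(path: str | Path, **meta_kwargs) -> CTVolume | np.ndarray:
    """Read a volume; returns a CTVolume for HU data, ndarray for masks.

    Raw and TIFF containers require the JSON sidecar written by
    :func:`write_volume` (or an equivalent one); missing metadata raises
    an error naming the absent field.
    """
    path = Path(path)
    suffix = "".join(path.suffixes[-2:]) if path.name.endswith(".nii.gz") else path.suffix

    if suffix in (".nii", ".nii.gz"):
        img = nib.load(str(path))
        array = np.asarray(img.dataobj)
        spacing = float(img.header.get_zooms()[0]) * 1000.0
        if array.dtype.kind in "iu":
            return array
        return CTVolume(values=array.astype(np.float32), spacing_um=spacing, **meta_kwargs)
    if suffix in (".mha", ".mhd"):
        img = sitk.ReadImage(str(path))
        array = sitk.GetArrayFromImage(img)
        spacing = float(img.GetSpacing()[0]) * 1000.0
        if array.dtype.kind in "iu":
            return array
        return CTVolume(values=array.astype(np.float32), spacing_um=spacing, **meta_kwargs)
    if suffix in (".tif", ".tiff"):
        meta = _load_sidecar(path, ("spacing_um", "slope", "intercept"))
        stored = tifffile.imread(str(path))
        if meta.get("is_mask"):
            return stored.astype(np.int16)
        hu = stored.astype(np.float32) * meta["slope"] + meta["intercept"]
        return CTVolume(values=hu, spacing_um=float(meta["spacing_um"]), **meta_kwargs)
    if suffix == ".raw":
        meta = _load_sidecar(path, ("shape", "spacing_um", "slope", "intercept"))
        stored = np.fromfile(str(path), dtype=np.dtype(meta.get("dtype", "uint16")))
        expected = int(np.prod(meta["shape"]))
        if stored.size != expected:
            raise ValueError(
                f"truncated raw file: {stored.size} values, expected {expected}"
            )
        stored = stored.reshape(meta["shape"])
        if meta.get("is_mask"):
            return stored.astype(np.int16)
        hu = stored.astype(np.float32) * meta["slope"] + meta["intercept"]
        return CTVolume(values=hu, spacing_um=float(meta["spacing_um"]), **meta_kwargs)
    raise ValueError(f"unsupported volume format {suffix!r}")
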