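"""Readers and writers for CT slices, masks and manifests.

DICOM pixel data is converted to Hounsfield units via the rescale
slope/intercept, windowed to a fixed lung/soft-tissue window and normalized
to [0, 1]; 8/16-bit grayscale PNG/TIFF images are scaled by their bit depth.
Masks round-trip bit-exactly as 8-bit {0, 255} PNGs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from PIL import Image

#: Default HU display window: covers air (~-1000) through soft tissue (+400).
HU_WINDOW = (-1000.0, 400.0)


@dataclass(frozen=True)
class SliceMeta:
    source: str
    modality: str = "unknown"
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0
    pixel_spacing: Optional[Tuple[float, float]] = None
    bit_depth: Optional[int] = None


def _looks_like_dicom(path: Path) -> bool:
    if path.suffix.lower() in (".dcm", ".dicom"):
        return True
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def read_slice(path, window: Tuple[float, float] = HU_WINDOW):
    """Read one grayscale slice as a [0,1] float image plus its metadata."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if _looks_like_dicom(path):
        return _read_dicom(path, window)
    return _read_raster(path)


def _read_dicom(path, window):
    import pydicom

    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
    except Exception as exc:  # unreadable or unsupported transfer syntax
        raise IOError(f"cannot read DICOM file {path}: {exc}") from exc
    if arr.ndim != 2:
        raise IOError(f"multi-frame DICOM not supported (2-D slices only): {path}")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = arr.astype(np.float64) * slope + intercept
    lo, hi = window
    img = np.clip((hu - lo) / (hi - lo), 0.0, 1.0)
    spacing = getattr(ds, "PixelSpacing", None)
    meta = SliceMeta(
        source=str(path),
        modality=str(getattr(ds, "Modality", "CT")),
        rescale_slope=slope,
        rescale_intercept=intercept,
        pixel_spacing=tuple(float(v) for v in spacing) if spacing else None,
        bit_depth=int(getattr(ds, "BitsStored", 16)),
    )
    return img, meta


def _read_raster(path):
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    if arr.ndim != 2:
        raise IOError(f"expected single-channel grayscale image: {path}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise IOError(f"unsupported pixel type {arr.dtype}: {path}")
    img = arr.astype(np.float64) / (2**depth - 1)
    meta = SliceMeta(source=str(path), modality="raster", bit_depth=depth)
    return img, meta


def write_image(img, path):
    """Write a [0,1] grayscale image as 16-bit PNG."""
    arr = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    Image.fromarray((arr * 65535).round().astype(np.uint16)).save(path)


def write_mask(mask, path):
    """Write a binary mask as 8-bit {0, 255} PNG."""
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr).save(path)


def read_mask(path):
    """Read a {0, 255} PNG mask back to a {0, 1} uint8 array."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise IOError(f"expected single-channel mask: {path}")
    values = np.unique(arr)
    if not np.isin(values, (0, 255)).all():
        raise IOError(f"mask contains non-binary values {values[:5]}: {path}")
    return (arr == 255).astype(np.uint8)


def write_dicom(img, path, window: Tuple[float, float] = HU_WINDOW):
    """Export a [0,1] image as a minimal CT DICOM with standard rescale tags."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    lo, hi = window
    hu = np.asarray(img, dtype=np.float64) * (hi - lo) + lo
    intercept = -1024.0
    stored = np.clip(np.round(hu - intercept), 0, 65535).astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.Modality = "CT"
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Rows, ds.Columns = stored.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = intercept
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def write_manifest(manifest, path):
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_manifest(path):
    with open(path) as fh:
        return json.load(fh)


def save_dataset(records, manifest, out_dir):
    """Write a phantom dataset as image/mask PNG pairs plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, row in zip(records, manifest):
        stem = f"slice_{row['index']:05d}"
        img_path = out / f"{stem}.png"
        mask_path = out / f"{stem}_mask.png"
        write_image(rec.image, img_path)
        write_mask(rec.mask, mask_path)
        rows.append({**row, "image": img_path.name, "mask": mask_path.name})
    write_manifest(rows, out / "manifest.json")
    return out / "manifest.json"
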