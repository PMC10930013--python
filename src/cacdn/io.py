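"""Series readers/writers: DICOM (CT) and a plain array container.

The array backend stores pixels as ``pixels.npy`` plus a JSON sidecar
with grid, thickness, tube current and seed — a lossless float32 round
trip.  The DICOM backend writes a single-frame CT SOP instance with
Rescale Slope/Intercept chosen so stored values map to HU; pixels are
quantized to 16-bit integers with round-half-to-even.

Conventions used throughout the package: pixel (0, 0) is top-left,
x = column and y = row, pixel centres at half-pixel offsets, all
geometry in mm with the origin at the grid centre.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from cacdn.phantoms import CTImage, GridSpec

_CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"


def write_series(img: CTImage, path, backend: str = "array") -> Path:
    """Persist a CTImage; returns the written path.

    backend="array": directory with pixels.npy + meta.json (exact).
    backend="dicom": single .dcm file (HU quantized to integers).
    """
    path = Path(path)
    if backend == "array":
        path.mkdir(parents=True, exist_ok=True)
        np.save(path / "pixels.npy", img.pixels.astype(np.float32))
        meta = {
            "matrix": img.grid.matrix,
            "fov_mm": img.grid.fov,
            "pixel_spacing_mm": img.grid.pixel_spacing,
            "slice_thickness_mm": img.slice_thickness,
            "tube_current_mA": img.tube_current,
            "seed": img.seed,
            "provenance": img.provenance,
        }
        with open(path / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)
        return path
    if backend == "dicom":
        return _write_dicom(img, path)
    raise ValueError(f"unknown backend {backend!r}")


def read_series(path) -> CTImage:
    """Read a CTImage written by :func:`write_series` (either backend)."""
    path = Path(path)
    if path.is_dir() and (path / "meta.json").exists():
        with open(path / "meta.json") as fh:
            meta = json.load(fh)
        pixels = np.load(path / "pixels.npy")
        grid = GridSpec(matrix=meta["matrix"], fov=meta["fov_mm"])
        return CTImage(pixels=pixels, grid=grid,
                       slice_thickness=meta["slice_thickness_mm"],
                       tube_current=meta["tube_current_mA"],
                       seed=meta["seed"], provenance=meta["provenance"])
    if path.suffix == ".dcm" or path.is_file():
        return _read_dicom(path)
    raise FileNotFoundError(f"no recognizable series at {path}")


def _write_dicom(img: CTImage, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = _CT_SOP_CLASS
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = _CT_SOP_CLASS
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.Rows = ds.Columns = img.grid.matrix
    ds.PixelSpacing = [img.grid.pixel_spacing, img.grid.pixel_spacing]
    ds.SliceThickness = img.slice_thickness
    ds.XRayTubeCurrent = int(round(img.tube_current))
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = 0.0
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.ImageComments = img.provenance[:10240]
    # round-half-to-even quantization to stored integers
    stored = np.rint(img.pixels.astype(np.float64)).astype(np.int16)
    ds.PixelData = stored.tobytes()
    pydicom.dcmwrite(path, ds, enforce_file_format=True)
    return path


def _read_dicom(path: Path) -> CTImage:
    ds = pydicom.dcmread(path)
    if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
        raise ValueError(f"{path}: missing rescale slope/intercept tags")
    if "SliceThickness" not in ds or ds.SliceThickness is None:
        raise ValueError(f"{path}: missing slice thickness; refusing to guess")
    hu = ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope) \
        + float(ds.RescaleIntercept)
    spacing = float(ds.PixelSpacing[0])
    grid = GridSpec(matrix=int(ds.Rows), fov=spacing * int(ds.Rows))
    return CTImage(pixels=hu.astype(np.float32), grid=grid,
                   slice_thickness=float(ds.SliceThickness),
                   tube_current=float(getattr(ds, "XRayTubeCurrent", 0.0)),
                   provenance=str(getattr(ds, "ImageComments", "")))
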