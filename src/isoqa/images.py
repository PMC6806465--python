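"""Planar and volumetric image containers with the formats the tool reads/writes.

Planar images go to 16-bit TIFF (via :mod:`tifffile`) or single-frame
secondary-capture DICOM (via :mod:`pydicom`); volumes go to a raw float32
block plus a JSON header recording shape, spacing and origin.  Pixel values
are kept as floating-point relative transmission / attenuation units in
memory; the 16-bit scaling used on disk is recorded in the TIFF/DICOM
metadata so round trips are lossless to ~1.5e-5 of full scale.

Conventions
-----------
Planar pixel (row 0, col 0) is the array corner; coordinates refer to pixel
centers and are 0-based.  Column index increases with the imager +u axis,
row index increases with -v (so row 0 is the +v edge, as images display).
Volume voxel ``[i, j, k]`` lies at ``origin + (i, j, k) * spacing`` on the
room axes ``(LAT, LNG, VRT)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import BeamGeometry

__all__ = ["PlanarImage", "VolumeImage"]

_UINT16_MAX = 65535


@dataclass
class PlanarImage:
    """A 2D image with its imager geometry.

    ``pixels`` is ``(rows, cols)`` float; ``geom`` carries the beam and
    imager geometry the image was acquired with.
    """

    pixels: np.ndarray
    geom: BeamGeometry
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("planar pixels must be 2-D")

    # -- pixel <-> imager-mm conversions ---------------------------------
    def pixel_to_mm(self, row, col) -> np.ndarray:
        """Imager-plane (u, v) mm of fractional pixel indices."""
        rows, cols = self.pixels.shape
        pitch = self.geom.pixel_pitch_mm
        u = (np.asarray(col, dtype=float) - (cols - 1) / 2.0) * pitch
        v = ((rows - 1) / 2.0 - np.asarray(row, dtype=float)) * pitch
        u, v = np.broadcast_arrays(u, v)
        return np.stack([u, v], axis=-1)

    def mm_to_pixel(self, u, v) -> np.ndarray:
        rows, cols = self.pixels.shape
        pitch = self.geom.pixel_pitch_mm
        col = np.asarray(u, dtype=float) / pitch + (cols - 1) / 2.0
        row = (rows - 1) / 2.0 - np.asarray(v, dtype=float) / pitch
        return np.stack([row, col], axis=-1)

    def mm_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """(u, v) mm coordinate grids of all pixel centers."""
        rows, cols = self.pixels.shape
        uv = self.pixel_to_mm(np.arange(rows), 0.0)  # v along rows
        v = uv[:, 1][:, None] * np.ones((1, cols))
        uu = self.pixel_to_mm(0.0, np.arange(cols))
        u = uu[:, 0][None, :] * np.ones((rows, 1))
        return u, v

    # -- I/O --------------------------------------------------------------
    def write_tiff(self, path) -> None:
        import tifffile

        lo = float(self.pixels.min())
        hi = float(self.pixels.max())
        span = (hi - lo) or 1.0
        scaled = np.round((self.pixels - lo) / span * _UINT16_MAX).astype(np.uint16)
        desc = json.dumps({"scale_lo": lo, "scale_hi": hi,
                           "geom": self.geom.to_dict(), "meta": self.meta})
        tifffile.imwrite(str(path), scaled, description=desc)

    @classmethod
    def read_tiff(cls, path, geom: BeamGeometry | None = None) -> "PlanarImage":
        import tifffile

        with tifffile.TiffFile(str(path)) as tf:
            page = tf.pages[0]
            raw = page.asarray()
            desc = page.tags.get("ImageDescription")
            header = json.loads(desc.value) if desc is not None else {}
        lo = header.get("scale_lo", 0.0)
        hi = header.get("scale_hi", float(raw.max()) or 1.0)
        pixels = raw.astype(float) / _UINT16_MAX * (hi - lo) + lo
        if geom is None:
            geom = BeamGeometry(**header["geom"])
        return cls(pixels=pixels, geom=geom, meta=header.get("meta", {}))

    def write_dicom(self, path) -> None:
        """Write as a minimal single-frame secondary-capture DICOM."""
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

        lo = float(self.pixels.min())
        hi = float(self.pixels.max())
        span = (hi - lo) or 1.0
        arr = np.round((self.pixels - lo) / span * _UINT16_MAX).astype(np.uint16)

        fm = FileMetaDataset()
        fm.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        fm.MediaStorageSOPInstanceUID = generate_uid()
        fm.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = fm
        ds.SOPClassUID = SecondaryCaptureImageStorage
        ds.SOPInstanceUID = fm.MediaStorageSOPInstanceUID
        ds.Modality = self.meta.get("modality", "RTIMAGE")
        ds.Rows, ds.Columns = arr.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelSpacing = [str(self.geom.pixel_pitch_mm)] * 2
        ds.RescaleSlope = span / _UINT16_MAX
        ds.RescaleIntercept = lo
        ds.GantryAngle = str(self.geom.gantry_deg)
        ds.BeamLimitingDeviceAngle = str(self.geom.collimator_deg)
        ds.PatientSupportAngle = str(self.geom.couch_deg)
        ds.ImageComments = json.dumps({"geom": self.geom.to_dict(), "meta": self.meta})
        ds.PixelData = arr.tobytes()
        pydicom.dcmwrite(str(path), ds, enforce_file_format=True)

    @classmethod
    def read_dicom(cls, path, geom: BeamGeometry | None = None) -> "PlanarImage":
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        pixels = arr * slope + intercept
        meta = {}
        if geom is None:
            try:
                header = json.loads(str(getattr(ds, "ImageComments", "{}")))
                geom = BeamGeometry(**header["geom"])
                meta = header.get("meta", {})
            except (KeyError, ValueError):
                geom = BeamGeometry(
                    gantry_deg=float(getattr(ds, "GantryAngle", 0.0)),
                    pixel_pitch_mm=float(ds.PixelSpacing[0]),
                    imager_rows=int(ds.Rows), imager_cols=int(ds.Columns))
        return cls(pixels=pixels, geom=geom, meta=meta)


@dataclass
class VolumeImage:
    """A 3D voxel image with world coordinates on the room axes.

    ``voxels[i, j, k]`` sits at ``origin + (i, j, k) * spacing`` where axis
    0/1/2 run along LAT/LNG/VRT (x, y, z).
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("volume voxels must be 3-D")
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    def index_to_world(self, idx) -> np.ndarray:
        """World mm of fractional voxel indices (single triple or (N, 3))."""
        return np.asarray(idx, dtype=float) * self.spacing + self.origin

    def write_raw(self, path_stem) -> tuple[Path, Path]:
        """Write ``<stem>.raw`` (float32, C-order) + ``<stem>.json`` header."""
        stem = Path(path_stem)
        raw_path = stem.with_suffix(".raw")
        hdr_path = stem.with_suffix(".json")
        self.voxels.astype("<f4").tofile(raw_path)
        header = {
            "format": "isoqa-raw-volume", "version": 1,
            "dtype": "float32-le", "order": "C",
            "shape": list(self.voxels.shape),
            "spacing_mm": list(self.spacing),
            "origin_mm": list(self.origin),
            "axes": ["LAT", "LNG", "VRT"],
            "meta": self.meta,
        }
        hdr_path.write_text(json.dumps(header, indent=1))
        return raw_path, hdr_path

    @classmethod
    def read_raw(cls, path_stem) -> "VolumeImage":
        stem = Path(path_stem)
        header = json.loads(stem.with_suffix(".json").read_text())
        shape = tuple(header["shape"])
        vox = np.fromfile(stem.with_suffix(".raw"), dtype="<f4").reshape(shape)
        return cls(voxels=vox, spacing=header["spacing_mm"],
                   origin=header["origin_mm"], meta=header.get("meta", {}))
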