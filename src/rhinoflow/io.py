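"""File IO: NIfTI/DICOM volumes, CSV curve tables, JSON metadata."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List

import numpy as np
import pandas as pd

from .airspace import CANONICAL_AXES, HUVolume
from .curves import AARCurve, BinnedCurve

__all__ = [
    "save_nifti", "load_nifti", "save_mask_nifti",
    "load_dicom_series", "save_dicom_series",
    "save_curves", "load_curves", "save_binned", "save_json", "load_json",
]


def save_nifti(vol: HUVolume, path) -> None:
    """Write an HU volume as NIfTI with isotropic spacing in the affine."""
    import nibabel as nib

    affine = np.diag([vol.spacing, vol.spacing, vol.spacing, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32),
                             affine), str(path))


def load_nifti(path, axes=CANONICAL_AXES) -> HUVolume:
    """Read a NIfTI volume; voxels must be isotropic."""
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-3):
        raise ValueError(f"anisotropic voxels {zooms}; resample first")
    return HUVolume(np.asarray(img.dataobj, dtype=np.float32),
                    float(zooms[0]), tuple(axes))


def save_mask_nifti(mask: np.ndarray, spacing: float, path) -> None:
    import nibabel as nib

    affine = np.diag([spacing, spacing, spacing, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine),
             str(path))


def load_dicom_series(directory, axes=("SI", "AP", "LR")) -> HUVolume:
    """Read a single-frame DICOM series into an HU volume.

    Slices are sorted by ImagePositionPatient along the slice normal (or
    InstanceNumber as a fallback) and rescaled to Hounsfield units via
    RescaleSlope/Intercept.  ``axes`` labels the (slice, row, column)
    order; the default matches axial slices stacked head-to-foot.
    """
    import pydicom

    files = sorted(Path(directory).glob("*.dcm")) or sorted(
        p for p in Path(directory).iterdir() if p.is_file())
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    slices = [pydicom.dcmread(str(f)) for f in files]

    def sort_key(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return int(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=sort_key)
    arr = np.stack([s.pixel_array for s in slices]).astype(np.float32)
    s0 = slices[0]
    slope = float(getattr(s0, "RescaleSlope", 1.0))
    inter = float(getattr(s0, "RescaleIntercept", 0.0))
    arr = arr * slope + inter
    spacing = float(getattr(s0, "PixelSpacing", [1.0, 1.0])[0])
    return HUVolume(arr, spacing, tuple(axes)).to_canonical()


def save_dicom_series(vol: HUVolume, directory) -> None:
    """Write a volume as a minimal secondary-capture DICOM series."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vol = vol.to_canonical()
    # store as axial-style slices along SI for interoperability
    data = np.transpose(vol.values, (1, 0, 2))
    series_uid = generate_uid()
    study_uid = generate_uid()
    for i, sl in enumerate(data):
        ds = Dataset()
        ds.SOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, i * vol.spacing]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [vol.spacing, vol.spacing]
        ds.SliceThickness = vol.spacing
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.Rows, ds.Columns = sl.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = np.clip(sl + 1024.0, 0, 65535).astype(np.uint16).tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        fds = pydicom.dataset.FileDataset(
            str(directory / f"slice_{i:04d}.dcm"), ds, file_meta=meta,
            preamble=b"\0" * 128)
        fds.save_as(str(directory / f"slice_{i:04d}.dcm"),
                    enforce_file_format=True)


def save_curves(curves: Iterable[AARCurve], path) -> None:
    """Concatenate curves into one CSV (subject, side, state, flow, pressure)."""
    frames = [c.to_frame() for c in curves]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_curves(path) -> List[AARCurve]:
    df = pd.read_csv(path)
    need = {"subject", "side", "state", "flow_ml_s", "pressure_pa"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"curve CSV missing columns: {sorted(missing)}")
    out = []
    for (subj, side, state), g in df.groupby(["subject", "side", "state"]):
        out.append(AARCurve(g["flow_ml_s"].to_numpy(),
                            g["pressure_pa"].to_numpy(),
                            subject=str(subj), side=side, state=state))
    return out


def save_binned(binned: Iterable[BinnedCurve], path) -> None:
    """Binned curve tables with the fixed column layout."""
    rows = []
    for b in binned:
        t = b.table
        for _, r in t.iterrows():
            rows.append({
                "subject": b.subject, "side": b.side, "state": b.state,
                "phase": "inspiration" if r["bin_flow"] >= 0 else "expiration",
                "bin_flow_ml_s": r["bin_flow"],
                "mean_pressure_pa": r["mean_pressure"],
                "n": int(r["n"]), "sd": r["sd"],
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def save_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)


def load_json(path):
    with open(path) as fh:
        return json.load(fh)
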