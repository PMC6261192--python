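"""Reading DWI series from NIfTI-1 files or DICOM series directories."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import DwiSeries
from .volume import ImageVolume, read_volume


def read_dwi(paths, b_values=None) -> DwiSeries:
    """Read a DWI series from NIfTI-1 input.

    Parameters
    ----------
    paths : a single 4-D NIfTI path (volumes stacked on the 4th axis) or a
        list of 3-D NIfTI paths, one per b value.
    b_values : list of b values (s/mm^2), same order as the volumes.  For a
        4-D file, a sidecar ``<stem>.bval`` (whitespace-separated values, the
        FSL convention) is read when *b_values* is omitted.
    """
    if isinstance(paths, (str, Path)):
        path = Path(paths)
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"{path}: expected a 4-D NIfTI, got shape {data.shape}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        if b_values is None:
            sidecar = path.parent / (path.name.split(".")[0] + ".bval")
            if not sidecar.exists():
                raise ValueError(f"no b values given and sidecar {sidecar} not found")
            b_values = [float(t) for t in sidecar.read_text().split()]
        vols = [ImageVolume(data[..., i], spacing, origin) for i in range(data.shape[3])]
    else:
        if b_values is None:
            raise ValueError("b_values are required when reading one file per b value")
        vols = [read_volume(p) for p in paths]
    return DwiSeries(tuple(vols), tuple(float(b) for b in b_values))


def read_dwi_dicom(directory) -> DwiSeries:
    """Read a DWI series from a DICOM directory.

    Slices are grouped by the standard diffusion b-value tag (0018,9087),
    with the Siemens/GE shadow tags (0019,100C) and (0043,1039) as
    fallbacks, and stacked by Image Position (Patient).
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    groups: dict[float, list] = {}
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        b = _dicom_b_value(ds)
        if b is None:
            continue
        groups.setdefault(b, []).append(ds)
    if len(groups) < 2:
        raise ValueError(
            f"{directory}: found {len(groups)} distinct b values; at least 2 required"
        )
    vols = []
    bvals = sorted(groups)
    for b in bvals:
        slices = sorted(groups[b], key=lambda d: float(d.ImagePositionPatient[2]))
        data = np.stack([s.pixel_array.T.astype(float) for s in slices], axis=-1)
        ps = [float(v) for v in slices[0].PixelSpacing]
        dz = (
            float(slices[1].ImagePositionPatient[2]) - float(slices[0].ImagePositionPatient[2])
            if len(slices) > 1
            else float(getattr(slices[0], "SliceThickness", 1.0))
        )
        origin = tuple(float(v) for v in slices[0].ImagePositionPatient)
        vols.append(ImageVolume(data, (ps[1], ps[0], abs(dz)), origin))
    return DwiSeries(tuple(vols), tuple(bvals))


def _dicom_b_value(ds) -> float | None:
    for tag in ((0x0018, 0x9087), (0x0019, 0x100C), (0x0043, 0x1039)):
        if tag in ds:
            val = ds[tag].value
            try:
                if isinstance(val, (list, tuple, bytes)):
                    if isinstance(val, bytes):
                        val = val.split(b"\\")[0]
                    else:
                        val = val[0]
                return float(val)
            except (TypeError, ValueError):
                continue
    return None
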