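"""Volume I/O, dataset layout, and the shared domain types.

All images are NIfTI-1/2 read and written through nibabel.  A dataset
follows a BIDS-like layout::

    root/
      sub-01/func/sub-01_run-01_bold.nii[.gz]
      sub-01/func/sub-01_run-01_bold.json     (sidecar: FD, QC, labels)
      sub-01/anat/...

Masks and the ROI atlas must live on the template grid exactly; a grid
mismatch is an error, never an implicit resample.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Unreadable or structurally invalid image file."""


class ValidationError(ValueError):
    """Data violates a domain invariant (non-finite voxels, bad shapes...)."""


@dataclass
class Volume4D:
    """A 4D voxel array (x, y, z, t) with geometry and timing metadata.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Voxel values; a 3D array is promoted to t = 1.
    voxel_size_mm : array-like of 3 floats
        Voxel edge lengths in millimetres.
    tr_s : float
        Repetition time in seconds (time between consecutive frames).
    affine : ndarray (4, 4), optional
        Voxel-to-world map; defaults to a diagonal scaling by voxel size.
    """

    data: np.ndarray
    voxel_size_mm: np.ndarray
    tr_s: float
    affine: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise ValidationError(f"expected 3D or 4D data, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValidationError("all dimensions must be >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume contains non-finite voxels")
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float).reshape(3)
        if np.any(self.voxel_size_mm <= 0):
            raise ValidationError("voxel sizes must be positive")
        if not (np.isfinite(self.tr_s) and self.tr_s > 0):
            raise ValidationError("tr_s must be a positive real")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size_mm, 1.0])
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def frame(self, t: int) -> np.ndarray:
        return self.data[..., t]

    def with_data(self, data: np.ndarray) -> "Volume4D":
        """Copy of the volume carrying new voxel data on the same grid."""
        return Volume4D(data=data, voxel_size_mm=self.voxel_size_mm.copy(),
                        tr_s=self.tr_s, affine=self.affine.copy())


@dataclass
class MaskSet:
    """Brain / WM / CSF compartment masks plus a dilated brain mask.

    Invariants: WM and CSF are disjoint and both inside the brain;
    the dilated mask contains the brain.
    """

    brain: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    dilated_brain: np.ndarray

    def __post_init__(self):
        for name in ("brain", "wm", "csf", "dilated_brain"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        shapes = {m.shape for m in (self.brain, self.wm, self.csf, self.dilated_brain)}
        if len(shapes) != 1:
            raise ValidationError("all masks must share one grid")
        if np.any(self.wm & self.csf):
            raise ValidationError("WM and CSF masks overlap")
        if np.any((self.wm | self.csf) & ~self.brain):
            raise ValidationError("WM/CSF must lie inside the brain mask")
        if np.any(self.brain & ~self.dilated_brain):
            raise ValidationError("dilated mask must contain the brain mask")

    @property
    def gm(self) -> np.ndarray:
        """Grey matter: brain voxels that are neither WM nor CSF."""
        return self.brain & ~self.wm & ~self.csf


@dataclass
class ROIAtlas:
    """Integer parcellation (0 = background) with names, systems, centroids."""

    labels: np.ndarray
    names: dict
    systems: dict = field(default_factory=dict)
    centroids_mm: dict = field(default_factory=dict)
    voxel_size_mm: np.ndarray = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("atlas labels must be integer")
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValidationError(f"labels without names: {sorted(missing)}")
        if self.voxel_size_mm is None:
            self.voxel_size_mm = np.ones(3)
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float).reshape(3)
        if not self.centroids_mm:
            for lab in sorted(present):
                idx = np.argwhere(self.labels == lab)
                self.centroids_mm[lab] = idx.mean(axis=0) * self.voxel_size_mm

    @property
    def roi_ids(self):
        return sorted(set(int(v) for v in np.unique(self.labels)) - {0})

    def centroid_matrix(self, roi_ids=None) -> np.ndarray:
        ids = roi_ids if roi_ids is not None else self.roi_ids
        return np.array([self.centroids_mm[i] for i in ids], dtype=float)


@dataclass
class ScanRecord:
    """One functional scan of one subject, with paths and QC sidecar."""

    scan_id: str
    subject_id: str
    n_volumes: int
    image_path: Path
    sidecar_path: Path = None
    sidecar: dict = field(default_factory=dict)

    def validate(self):
        fd = self.sidecar.get("fd_mm")
        if fd is not None and len(fd) != self.n_volumes:
            raise ValidationError(
                f"scan {self.scan_id}: FD series length {len(fd)} != n_volumes {self.n_volumes}")


def read_volume(path, tr_s: float = None) -> Volume4D:
    """Read a NIfTI image into a :class:`Volume4D`.

    3D images are promoted to a single frame.  TR is taken from the
    header's time zoom unless overridden via ``tr_s``; a header TR of 0
    (common in masks) falls back to 1 s.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several distinct types
        raise FormatError(f"cannot read NIfTI image {path}: {exc}") from exc
    zooms = img.header.get_zooms()
    voxel = np.array(zooms[:3], dtype=float)
    if tr_s is None:
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    if not np.all(np.isfinite(data)):
        raise ValidationError(f"{path}: non-finite voxels")
    return Volume4D(data=np.asarray(data, dtype=np.float64), voxel_size_mm=voxel,
                    tr_s=tr_s, affine=np.array(img.affine))


def write_volume(vol: Volume4D, path) -> None:
    """Write a :class:`Volume4D` as NIfTI-1, preserving affine and TR."""
    path = Path(path)
    data = vol.data
    if data.shape[3] == 1:
        data = data[..., 0]
    img = nib.Nifti1Image(data, vol.affine)
    zooms = list(vol.voxel_size_mm)
    if data.ndim == 4:
        zooms.append(vol.tr_s)
    img.header.set_zooms(zooms)
    if data.ndim == 4:
        img.header.set_xyzt_units("mm", "sec")
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"failed writing {path}: {exc}") from exc


_BOLD_RE = re.compile(r"(?P<sub>sub-[A-Za-z0-9]+)_(?P<run>[A-Za-z0-9-]+)_bold\.nii(\.gz)?$")


def scan_dataset(root) -> list:
    """Discover functional scans under a BIDS-like tree.

    Returns one :class:`ScanRecord` per ``*_bold.nii[.gz]`` file found in
    ``sub-*/func/``, in deterministic lexicographic order, pairing each
    image with its JSON sidecar when present.  Sidecars with an FD series
    of the wrong length raise a :class:`ValidationError` naming the scan.
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    records = []
    for img_path in sorted(root.glob("sub-*/func/*_bold.nii*")):
        m = _BOLD_RE.search(img_path.name)
        if not m:
            logger.warning("skipping unrecognised functional image %s", img_path)
            continue
        try:
            img = nib.load(str(img_path))
            n_vol = img.shape[3] if len(img.shape) > 3 else 1
        except Exception:
            logger.warning("skipping unreadable scan %s", img_path)
            continue
        scan_id = img_path.name.split("_bold")[0]
        sidecar_path = img_path.parent / (scan_id + "_bold.json")
        sidecar = {}
        if sidecar_path.exists():
            with open(sidecar_path) as fh:
                sidecar = json.load(fh)
        rec = ScanRecord(scan_id=scan_id, subject_id=m.group("sub"), n_volumes=n_vol,
                         image_path=img_path,
                         sidecar_path=sidecar_path if sidecar_path.exists() else None,
                         sidecar=sidecar)
        rec.validate()
        records.append(rec)
    return records


def write_sidecar(record: ScanRecord, fd=None, qc: dict = None) -> None:
    """Write/update the scan's JSON sidecar with the FD series and QC metrics."""
    if fd is not None:
        fd = np.asarray(fd, dtype=float)
        if len(fd) != record.n_volumes:
            raise ValidationError(
                f"scan {record.scan_id}: FD length {len(fd)} != n_volumes {record.n_volumes}")
        record.sidecar["fd_mm"] = fd.tolist()
        record.sidecar["mean_fd_mm"] = float(fd.mean())
    if qc:
        for key, val in qc.items():
            record.sidecar[key] = _jsonable(val)
    if record.sidecar_path is None:
        record.sidecar_path = record.image_path.parent / (record.scan_id + "_bold.json")
    with open(record.sidecar_path, "w") as fh:
        json.dump(record.sidecar, fh, indent=1)


def _jsonable(val):
    if isinstance(val, np.ndarray):
        return val.tolist()
    if isinstance(val, (np.floating, np.integer)):
        return val.item()
    if isinstance(val, (np.bool_,)):
        return bool(val)
    if isinstance(val, dict):
        return {k: _jsonable(v) for k, v in val.items()}
    if isinstance(val, (list, tuple)):
        return [_jsonable(v) for v in val]
    if not isinstance(val, (str, int, float, bool, type(None))):
        raise ValidationError(f"value of type {type(val).__name__} is not JSON-serializable")
    return val
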