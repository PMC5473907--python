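"""Readers, writers and the run configuration.

Volumes travel as NIfTI-1 (4-D BOLD series, 3-D masks and parameter maps),
tables as UTF-8 CSV with '.' decimal separator, per-run metadata as JSON
sidecars, and configuration as YAML.  Time is stored in minutes everywhere
downstream of I/O; TE stays in seconds so that ΔR2* comes out in s⁻¹.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import DimensionError, SchemaError, ValidationError

ROI_ROLES = (
    "placenta_twinA",
    "placenta_twinB",
    "brain_twinA",
    "brain_twinB",
    "liver_twinA",
    "liver_twinB",
    "background",
)


@dataclass
class VolumeSeries:
    """A motion-corrected 4-D BOLD acquisition.

    Attributes
    ----------
    data : ndarray, shape (x, y, z, t)
        Signal intensities, arbitrary units, finite and non-negative.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    tr : float
        Repetition time in seconds per frame.
    te : float
        Echo time in seconds.
    t0 : float
        Acquisition start in minutes (default 0).
    frame_times : ndarray
        Frame midpoint times in minutes; strictly increasing.
    affine : ndarray, shape (4, 4)
        Voxel-to-world (mm) mapping.
    """

    data: np.ndarray
    voxel_size: tuple = (3.0, 3.0, 3.0)
    tr: float = 6.0
    te: float = 0.035
    t0: float = 0.0
    frame_times: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise DimensionError(f"expected 4-D data, got {self.data.ndim}-D")
        if self.tr <= 0 or self.te <= 0:
            raise ValidationError("tr and te must be > 0")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValidationError("intensities must be finite and >= 0")
        if self.frame_times is None:
            self.frame_times = self.t0 + np.arange(self.data.shape[3]) * self.tr / 60.0
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if len(self.frame_times) != self.data.shape[3]:
            raise ValidationError("frame_times length must equal number of frames")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValidationError("frame_times must be strictly increasing")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    def with_data(self, data: np.ndarray, frame_times: np.ndarray | None = None) -> "VolumeSeries":
        """Copy of this series with new data (and optionally a new time grid)."""
        return VolumeSeries(
            data=data,
            voxel_size=self.voxel_size,
            tr=self.tr,
            te=self.te,
            t0=self.t0,
            frame_times=self.frame_times if frame_times is None else frame_times,
            affine=self.affine,
        )


@dataclass
class ROISet:
    """Integer label volume plus a label -> anatomical-role dictionary."""

    labels: np.ndarray
    dictionary: Mapping[int, str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DimensionError("ROI labels must be a 3-D integer array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("ROI labels must be integers")
        self.dictionary = {int(k): str(v) for k, v in dict(self.dictionary).items()}
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.dictionary)
        if missing:
            raise ValidationError(f"labels without dictionary entry: {sorted(missing)}")
        bad = [r for r in self.dictionary.values() if r not in ROI_ROLES]
        if bad:
            raise ValidationError(f"unknown ROI roles: {bad}")

    def label_for_role(self, role: str) -> int:
        for lab, r in self.dictionary.items():
            if r == role:
                return lab
        raise ValidationError(f"role {role!r} not present in ROI set")

    def mask_for_role(self, role: str) -> np.ndarray:
        mask = self.labels == self.label_for_role(role)
        if not mask.any():
            raise ValidationError(f"ROI for role {role!r} is empty")
        return mask

    @property
    def roles(self) -> tuple:
        return tuple(sorted(set(self.dictionary.values())))


@dataclass
class RunConfig:
    """All tunable pipeline constants in one plain-text-serializable record."""

    # paradigm (minutes)
    baseline_dur: float = 10.0
    hyperoxia_dur: float = 10.0
    post_dur: float = 10.0
    # spatial smoothing
    smooth_kernel_width: int = 5
    smooth_sigma: float = 1.5
    # temporal smoothing
    temporal_window: int = 10
    resample_dt: float | None = None
    # outlier detection
    outlier_threshold: float = 3.0
    outlier_neighborhood: int = 2
    # fitting
    ttp_mode_convention: str = "as_printed"
    fit_alpha_max: float = 20.0
    fit_beta_max: float = 10.0
    fit_n_starts: int = 6
    # resampling statistics
    resampling_reps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if min(self.baseline_dur, self.hyperoxia_dur, self.post_dur) <= 0:
            raise ValidationError("paradigm durations must be > 0")
        if self.resampling_reps < 1:
            raise ValidationError("resampling_reps must be >= 1")
        if self.outlier_threshold <= 0:
            raise ValidationError("outlier_threshold must be > 0")
        if self.ttp_mode_convention not in ("as_printed", "standard_mode"):
            raise ValidationError("ttp_mode_convention must be as_printed|standard_mode")

    def paradigm(self):
        from .paradigm import OxygenParadigm

        return OxygenParadigm(self.baseline_dur, self.hyperoxia_dur, self.post_dur)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return p.with_name(name[: -len(ext)] + ".json")
    return p.with_suffix(".json")


def read_volume_series(path, tr: float | None = None, te: float | None = None, t0: float = 0.0) -> VolumeSeries:
    """Load a 4-D NIfTI-1 series; tr/te may come from a JSON sidecar.

    Explicit ``tr``/``te`` arguments override sidecar values.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise DimensionError(f"expected a 4-D NIfTI file, got {data.ndim}-D")
    meta = {}
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    tr = tr if tr is not None else meta.get("tr")
    te = te if te is not None else meta.get("te")
    t0 = meta.get("t0", t0)
    if tr is None or te is None:
        raise ValidationError("tr and te must be given or present in the JSON sidecar")
    if tr <= 0 or te <= 0:
        raise ValidationError("tr and te must be > 0")
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeSeries(data=data, voxel_size=vox, tr=float(tr), te=float(te), t0=float(t0), affine=img.affine)


def write_volume_series(series: VolumeSeries, path) -> None:
    """Write a 4-D NIfTI-1 file plus a JSON sidecar carrying tr/te/t0."""
    img = nib.Nifti1Image(series.data.astype(np.float64), series.affine)
    img.header.set_zooms(tuple(series.voxel_size) + (series.tr,))
    nib.save(img, str(path))
    _sidecar_path(path).write_text(
        json.dumps({"tr": series.tr, "te": series.te, "t0": series.t0}, sort_keys=True)
    )


def read_mask(path) -> tuple[np.ndarray, dict]:
    """Load a 3-D integer label volume; roles come from the JSON sidecar."""
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    if labels.ndim != 3:
        raise DimensionError(f"expected a 3-D mask, got {labels.ndim}-D")
    sc = _sidecar_path(path)
    dictionary = {}
    if sc.exists():
        raw = json.loads(sc.read_text())
        dictionary = {int(k): v for k, v in raw.get("roles", raw).items()}
    return labels, dictionary


def write_mask(rois: ROISet, path, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(rois.labels.astype(np.int32), np.eye(4) if affine is None else affine)
    nib.save(img, str(path))
    _sidecar_path(path).write_text(
        json.dumps({"roles": {str(k): v for k, v in rois.dictionary.items()}}, sort_keys=True)
    )


def write_map(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Write a 3-D scalar map (e.g. TTP in minutes) as NIfTI-1."""
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim != 3:
        raise DimensionError("expected a 3-D map")
    nib.save(nib.Nifti1Image(arr, np.eye(4) if affine is None else affine), str(path))


def read_map(path) -> np.ndarray:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=float)
    if arr.ndim != 3:
        raise DimensionError("expected a 3-D map")
    return arr


def write_table(records: Sequence[Mapping], path, columns: Sequence[str] | None = None) -> None:
    """Write keyed rows to CSV (header always present, deterministic column order)."""
    records = list(records)
    if records:
        keys = list(records[0].keys())
        for i, r in enumerate(records):
            if list(r.keys()) != keys:
                raise SchemaError(f"row {i} keys {list(r.keys())} differ from {keys}")
        df = pd.DataFrame.from_records(records, columns=keys)
    else:
        df = pd.DataFrame(columns=list(columns or []))
    df.to_csv(path, index=False, encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")
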