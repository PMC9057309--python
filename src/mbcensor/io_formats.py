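"""Readers and writers for every on-disk format the toolkit touches.

Motion parameters follow the HCP ``Movement_Regressors.txt`` dialect:
whitespace-delimited, at least 6 columns, of which the first three are
translations in mm and the next three rotations (degrees by default; a
units flag covers radian-emitting pipelines).  Columns beyond the sixth
(the derivative columns HCP appends) are ignored on read.

All coordinates crossing module boundaries are world-space millimetres;
voxel indices never leave this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


@dataclass
class MotionTrace:
    """Per-run rigid-body motion parameters.

    ``values`` is a T x 6 array: columns 0-2 are translations (mm),
    columns 3-5 rotations in ``units`` ('degrees' or 'radians').
    """

    values: np.ndarray
    tr: float
    units: str = "degrees"
    subject_id: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError(f"motion trace must be T x 6, got {self.values.shape}")
        if self.values.shape[0] < 2:
            raise ValueError("motion trace needs at least 2 frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("motion trace contains non-finite values")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.units not in ("degrees", "radians"):
            raise ValueError(f"unknown rotation units {self.units!r}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def rotations_in_radians(self) -> np.ndarray:
        """Return the three rotation columns converted to radians."""
        rot = self.values[:, 3:6]
        if self.units == "degrees":
            rot = np.deg2rad(rot)
        return rot


@dataclass
class ROISet:
    """Spherical ROI definitions: centers in mm, common radius (default
    5 mm, i.e. 10 mm diameter spheres)."""

    centers: np.ndarray
    radius: float = 5.0
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[1] != 3:
            raise ValueError("ROI centers must be n_roi x 3 (mm)")
        if self.centers.shape[0] < 2:
            raise ValueError("need at least 2 ROIs")
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")
        if not self.labels:
            self.labels = [f"roi{i:03d}" for i in range(self.centers.shape[0])]

    @property
    def n_roi(self) -> int:
        return self.centers.shape[0]

    def pair_distances(self) -> np.ndarray:
        """Euclidean distance (mm) for each ROI pair, upper-triangle order."""
        d = np.linalg.norm(self.centers[:, None, :] - self.centers[None, :, :], axis=-1)
        iu = np.triu_indices(self.n_roi, k=1)
        return d[iu]


@dataclass
class RunTimeseries:
    """ROI x time matrix for one run plus everything that travels with it:
    TR, nuisance series, the censor mask slot, and provenance flags.

    Provenance flags are monotone: once set they are never unset.
    """

    roi_data: np.ndarray
    tr: float
    nuisance: dict[str, np.ndarray] = field(default_factory=dict)
    keep: np.ndarray | None = None
    normalized: bool = False
    filtered: bool = False
    trimmed: bool = False
    subject_id: str = ""
    run_id: str = ""
    missing_rois: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.roi_data = np.asarray(self.roi_data, dtype=float)
        if self.roi_data.ndim != 2:
            raise ValueError("roi_data must be n_roi x T")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        T = self.roi_data.shape[1]
        if self.keep is None:
            self.keep = np.ones(T, dtype=bool)
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.shape != (T,):
            raise ValueError("censor mask length must equal T")
        for name, series in self.nuisance.items():
            series = np.asarray(series, dtype=float)
            if series.shape != (T,):
                raise ValueError(f"nuisance series {name!r} length {series.shape} != T={T}")
            self.nuisance[name] = series

    @property
    def n_roi(self) -> int:
        return self.roi_data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.roi_data.shape[1]


def read_motion_regressors(
    path: str | Path,
    units: str = "degrees",
    drop_leading: int = 0,
    tr: float = 0.72,
    subject_id: str = "",
    run_id: str = "",
) -> MotionTrace:
    """Read a whitespace-delimited motion-parameter file.

    Only the first six columns are used (translations mm, rotations per
    ``units``); the HCP derivative columns are ignored.  The first
    ``drop_leading`` rows (signal-equilibration frames) are removed.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            if len(toks) < 6:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 6 columns, got {len(toks)}"
                )
            try:
                rows.append([float(t) for t in toks[:6]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric token: {exc}") from None
    if not rows:
        raise FormatError(f"{path}: empty motion file")
    values = np.asarray(rows, dtype=float)[drop_leading:]
    if values.shape[0] < 2:
        raise FormatError(f"{path}: fewer than 2 frames after dropping {drop_leading}")
    return MotionTrace(values, tr=tr, units=units, subject_id=subject_id, run_id=run_id)


def write_motion_regressors(trace: MotionTrace, path: str | Path) -> None:
    """Write the 12-column dialect: 6 parameters plus their backward
    differences (first difference row zero)."""
    deriv = np.zeros_like(trace.values)
    deriv[1:] = np.diff(trace.values, axis=0)
    out = np.hstack([trace.values, deriv])
    np.savetxt(path, out, fmt="%.6f")


def extract_roi_timeseries(
    img,
    roiset: ROISet,
    brain_mask: np.ndarray | None = None,
    tr: float | None = None,
) -> RunTimeseries:
    """Average a 4D NIfTI image within each ROI sphere.

    Membership is voxel-center-in-sphere: a voxel belongs to an ROI when
    its world-space center lies within ``roiset.radius`` mm of the ROI
    center.  ROIs with no in-brain voxels yield an all-NaN row flagged in
    ``missing_rois``.
    """
    affine = getattr(img, "affine", None)
    if affine is None:
        raise FormatError("image has no affine; cannot map voxels to mm space")
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"expected 4D image, got shape {data.shape}")
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    nx, ny, nz, T = data.shape
    if brain_mask is None:
        brain_mask = np.ones((nx, ny, nz), dtype=bool)
    ii, jj, kk = np.nonzero(brain_mask)
    vox_ijk = np.column_stack([ii, jj, kk]).astype(float)
    vox_mm = vox_ijk @ affine[:3, :3].T + affine[:3, 3]
    flat = data[ii, jj, kk, :]  # n_vox x T

    n_roi = roiset.n_roi
    roi_data = np.full((n_roi, T), np.nan)
    missing = np.zeros(n_roi, dtype=bool)
    for r in range(n_roi):
        dist = np.linalg.norm(vox_mm - roiset.centers[r], axis=1)
        inside = dist <= roiset.radius
        if not inside.any():
            missing[r] = True
            continue
        roi_data[r] = flat[inside].mean(axis=0)
    if missing.all():
        raise FormatError("no ROI contains any in-brain voxel")
    return RunTimeseries(roi_data, tr=tr, missing_rois=missing)


def read_roi_centers(path: str | Path) -> ROISet:
    """Read a TSV of ROI sphere centers with x, y, z columns in mm."""
    df = pd.read_csv(path, sep="\t")
    for col in ("x", "y", "z"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    bad = df[["x", "y", "z"]].isna().any(axis=1)
    if bad.any():
        raise FormatError(f"{path}: malformed row index {int(np.nonzero(bad.values)[0][0])}")
    labels = list(df["label"].astype(str)) if "label" in df.columns else []
    radius = float(df["radius"].iloc[0]) if "radius" in df.columns else 5.0
    return ROISet(df[["x", "y", "z"]].to_numpy(float), radius=radius, labels=labels)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with 12 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


#: Configuration schema: key -> (default, required).  ``None`` default with
#: required=True means the key must be present.
CONFIG_SCHEMA: dict[str, tuple[object, bool]] = {
    "tr": (None, True),
    "lpf_cutoff_hz": (0.2, False),
    "notch_band_hz": ([0.31, 0.43], False),
    "bandpass_hz": ([0.009, 0.08], False),
    "filter_order": (2, False),
    "trim_volumes": (30, False),
    "min_volumes": (167, False),
    "drop_leading": (10, False),
    "n_random_vectors": (10, False),
    "bootstrap_samples": (10000, False),
    "search_range_pct": ([0.0, 80.0], False),
    "bisquare_c": (4.685, False),
    "gsr": (False, False),
}


def read_config(path: str | Path) -> dict:
    """Read a YAML config, validate against the schema, fill defaults."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    unknown = set(cfg) - set(CONFIG_SCHEMA)
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    out = {}
    for key, (default, required) in CONFIG_SCHEMA.items():
        if key in cfg:
            out[key] = cfg[key]
        elif required:
            raise FormatError(f"{path}: missing required config key {key!r}")
        else:
            out[key] = default
    return out
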