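"""Framewise motion and signal-change statistics.

FD (framewise displacement) is the sum of absolute backward differences
of the six rigid-body parameters, with rotations converted to arc length
on a 50 mm radius sphere.  DV (DVARS) is the root-mean-square over
voxels of the backward temporal difference of the (mode-1000 normalized)
signal.  The filtered variants (LPF, notch) apply a zero-phase
Butterworth filter to the motion parameters / voxel series *before*
differencing, which suppresses the respiratory pseudomotion that
contaminates these statistics at multiband sampling rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .io_formats import MotionTrace

#: Radius (mm) of the sphere used to convert rotations to displacements.
ROTATION_SPHERE_RADIUS_MM = 50.0


class FilterConfigError(ValueError):
    """Filter specification invalid for the given sampling rate."""


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth filter specification.

    kind is one of 'lowpass', 'bandpass', 'bandstop', 'none'; cutoffs are
    in Hz (one value for lowpass, two for band kinds).  Filtering is
    always applied forward-backward (zero phase), which squares the
    magnitude response: an order-2 design therefore has gain 0.5 at its
    cutoff frequency.
    """

    kind: str
    cutoffs: tuple[float, ...] = ()
    order: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "bandpass", "bandstop", "none"):
            raise FilterConfigError(f"unknown filter kind {self.kind!r}")
        object.__setattr__(self, "cutoffs", tuple(float(c) for c in self.cutoffs))
        n_expected = {"lowpass": 1, "bandpass": 2, "bandstop": 2, "none": 0}[self.kind]
        if len(self.cutoffs) != n_expected:
            raise FilterConfigError(
                f"{self.kind} filter needs {n_expected} cutoff(s), got {len(self.cutoffs)}"
            )
        if self.order < 1:
            raise FilterConfigError("filter order must be >= 1")
        if any(c <= 0 for c in self.cutoffs):
            raise FilterConfigError("cutoffs must be positive")
        if n_expected == 2 and not self.cutoffs[0] < self.cutoffs[1]:
            raise FilterConfigError("band filter requires low < high cutoff")

    def validate_for(self, fs: float) -> None:
        nyq = fs / 2.0
        if any(c >= nyq for c in self.cutoffs):
            raise FilterConfigError(
                f"cutoff(s) {self.cutoffs} must lie strictly below Nyquist {nyq:g} Hz"
            )


#: The 0.2 Hz low-pass used by the LPF-FD / LPF-DV statistics.
LOWPASS_02HZ = FilterSpec("lowpass", (0.2,))
#: Respiratory notch per Fair and colleagues.
NOTCH_031_043 = FilterSpec("bandstop", (0.31, 0.43))
#: Wider respiratory notch per Power and colleagues.
NOTCH_02_05 = FilterSpec("bandstop", (0.2, 0.5))
#: The RSFC band-pass.
BANDPASS_RSFC = FilterSpec("bandpass", (0.009, 0.08))

_VARIANT_DEFAULT_SPEC = {
    "standard": FilterSpec("none"),
    "lpf": LOWPASS_02HZ,
    "notch": NOTCH_031_043,
}


@dataclass
class FramewiseSeries:
    """A nonnegative framewise series (FD in mm, DV in signal units).

    Element 0 is 0 by convention: backward differences are undefined for
    the first frame, and frame 0 is never censorable by itself.
    """

    values: np.ndarray
    statistic: str  # 'FD' or 'DV'
    variant: str = "standard"  # 'standard', 'lpf', 'notch'
    filter: FilterSpec = field(default_factory=lambda: FilterSpec("none"))
    run_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("framewise series must be 1-D")
        if self.values[0] != 0:
            raise ValueError("framewise series must start at 0 by convention")
        if np.any(self.values < 0):
            raise ValueError("framewise series must be nonnegative")


def butterworth_zero_phase(series: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Forward-backward Butterworth filtering along the last axis.

    Edge handling: reflect ('even') padding of length 3*(order+1); edges
    are trimmed later in the pipeline anyway.  Pass-through for
    kind='none'.
    """
    series = np.asarray(series, dtype=float)
    if spec.kind == "none":
        return series.copy()
    spec.validate_for(fs)
    T = series.shape[-1]
    padlen = 3 * (spec.order + 1)
    if T <= 2 * padlen:
        raise FilterConfigError(f"series of length {T} too short for order-{spec.order} filter")
    nyq = fs / 2.0
    wn = [c / nyq for c in spec.cutoffs]
    b, a = signal.butter(spec.order, wn if len(wn) > 1 else wn[0], btype=spec.kind)
    return signal.filtfilt(b, a, series, axis=-1, padtype="even", padlen=padlen)


def zero_phase_gain(f: float, fs: float, spec: FilterSpec) -> float:
    """Closed-form amplitude gain of the forward-backward filter at f Hz.

    This is |H(e^{j 2 pi f / fs})|^2 of the digital (bilinear,
    prewarped-cutoff) Butterworth design — the independent check used by
    the tests.  Note the digital response differs from the analog
    prototype 1/(1+(f/fc)^{2n}) at frequencies approaching Nyquist.
    """
    spec.validate_for(fs)
    nyq = fs / 2.0
    wn = [c / nyq for c in spec.cutoffs]
    b, a = signal.butter(spec.order, wn if len(wn) > 1 else wn[0], btype=spec.kind)
    _, h = signal.freqz(b, a, worN=[2.0 * np.pi * f / fs])
    return float(np.abs(h[0]) ** 2)


def _resolve_spec(variant: str, spec: FilterSpec | None) -> FilterSpec:
    if variant not in _VARIANT_DEFAULT_SPEC:
        raise ValueError(f"unknown variant {variant!r}")
    if spec is None:
        return _VARIANT_DEFAULT_SPEC[variant]
    if variant == "standard" and spec.kind != "none":
        raise ValueError("standard variant does not filter; pass spec=None")
    return spec


def compute_fd(mp: MotionTrace, variant: str = "standard", spec: FilterSpec | None = None) -> FramewiseSeries:
    """Framewise displacement from a motion trace.

    Rotations are converted to arc length on a 50 mm sphere; for the
    'lpf'/'notch' variants the six parameter columns are filtered before
    backward differencing.  FD[0] = 0.
    """
    spec = _resolve_spec(variant, spec)
    fs = 1.0 / mp.tr
    trans = mp.values[:, :3]
    rot_mm = mp.rotations_in_radians() * ROTATION_SPHERE_RADIUS_MM
    params = np.hstack([trans, rot_mm])  # T x 6, all mm
    if spec.kind != "none":
        params = butterworth_zero_phase(params.T, fs, spec).T
    fd = np.zeros(params.shape[0])
    fd[1:] = np.abs(np.diff(params, axis=0)).sum(axis=1)
    return FramewiseSeries(fd, statistic="FD", variant=variant, filter=spec, run_id=mp.run_id)


def compute_dv(
    voxel_ts: np.ndarray,
    tr: float,
    variant: str = "standard",
    spec: FilterSpec | None = None,
    run_id: str = "",
) -> FramewiseSeries:
    """DVARS from a voxel-x-time (or ROI-x-time) matrix.

    The input is expected to be mode-1000 normalized already.  For the
    'lpf'/'notch' variants each series is filtered before differencing.
    Spatial smoothing, which applies to the standard variant on volume
    data only, is handled upstream (see :func:`smooth_volumes`).
    DV[0] = 0.
    """
    voxel_ts = np.asarray(voxel_ts, dtype=float)
    if voxel_ts.ndim != 2 or voxel_ts.shape[0] == 0:
        raise ValueError("voxel timeseries must be a non-empty 2-D matrix")
    spec = _resolve_spec(variant, spec)
    if spec.kind != "none":
        voxel_ts = butterworth_zero_phase(voxel_ts, 1.0 / tr, spec)
    dv = np.zeros(voxel_ts.shape[1])
    dv[1:] = np.sqrt(np.mean(np.diff(voxel_ts, axis=1) ** 2, axis=0))
    return FramewiseSeries(dv, statistic="DV", variant=variant, filter=spec, run_id=run_id)


def smooth_volumes(
    data: np.ndarray,
    voxel_sizes_mm: tuple[float, float, float],
    fwhm_mm: float = 4.0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian volume smoothing (separable, sigma = FWHM/2.3548 per axis,
    converted to voxels), restricted to the mask.  Used only for the
    standard-DV statistic."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected 4D data (x, y, z, t)")
    sigma_vox = [fwhm_mm / 2.3548 / vs for vs in voxel_sizes_mm]
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    mask = mask.astype(float)
    out = np.empty_like(data)
    norm = ndimage.gaussian_filter(mask, sigma_vox)
    for t in range(data.shape[3]):
        num = ndimage.gaussian_filter(data[..., t] * mask, sigma_vox)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[..., t] = np.where(mask > 0, num / norm, 0.0)
    return out
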