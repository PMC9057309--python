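"""Resting-state functional connectivity pipeline.

Order of operations per run: mode-1000 normalization, demean/detrend
(trend fitted on kept frames only, so censored values never leak into
the fit), linear interpolation across censored frames, 0.009-0.08 Hz
band-pass, 30-volume edge trims, censored-frame removal, then partial
correlation of every ROI pair against the nuisance design, Fisher
r-to-z immediately, and unweighted run averaging per subject.

Partial correlations (rather than sequential nuisance regression) keep
the removed nuisance space orthogonal to the correlations by
construction.  The nuisance design is: the band-pass-filtered motion
parameters, their squares, their backward-difference derivatives and
squared derivatives (24 columns), WM and CSF signals with derivatives
when available, optionally the global signal with derivative (GSR), and
an intercept — 29 columns without GSR, 31 with, when all compartment
signals are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .framewise import BANDPASS_RSFC, FilterSpec, butterworth_zero_phase
from .io_formats import MotionTrace, RunTimeseries

#: Volumes discarded from each run edge after band-pass filtering.
EDGE_TRIM_DEFAULT = 30
_Z_CLAMP = 1.0 - 1e-12


@dataclass
class NuisanceSet:
    """Global, white-matter and CSF signals with the erosion depth used."""

    gs: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    erosion_iterations: dict[str, int] = field(default_factory=dict)


def mode1000_normalize(
    values: np.ndarray, brain_values: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Scale a run so the modal in-brain intensity equals 1000.

    The mode is estimated as the midpoint of the tallest of 256
    histogram bins spanning the 1st-99th percentile of the pooled
    voxel-frame intensities.
    """
    values = np.asarray(values, dtype=float)
    pool = values if brain_values is None else np.asarray(brain_values, dtype=float)
    lo, hi = np.percentile(pool, [1, 99])
    if not hi > lo:
        mode = float(np.median(pool))
    else:
        counts, edges = np.histogram(pool.ravel(), bins=256, range=(lo, hi))
        b = int(np.argmax(counts))
        mode = float(0.5 * (edges[b] + edges[b + 1]))
    if mode <= 0:
        raise ValueError(f"non-positive modal intensity {mode:g}; cannot mode-1000 normalize")
    scale = 1000.0 / mode
    return values * scale, scale


def _erode_to_limit(mask: np.ndarray, max_iter: int = 4) -> tuple[np.ndarray, int]:
    """6-connected binary erosion, up to max_iter times, stopping before
    the mask would become empty."""
    struct = ndimage.generate_binary_structure(3, 1)
    used = 0
    current = mask.astype(bool)
    for _ in range(max_iter):
        nxt = ndimage.binary_erosion(current, structure=struct)
        if not nxt.any():
            break
        current = nxt
        used += 1
    return current, used


def compute_nuisance_signals(
    data4d: np.ndarray,
    brain_mask: np.ndarray,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
) -> NuisanceSet:
    """Mean in-brain signal (GS) plus WM/CSF compartment means after up
    to four iterations of 6-connected erosion (stopping while at least
    one voxel remains)."""
    data4d = np.asarray(data4d, dtype=float)
    out = {}
    iters = {}
    for name, mask in (("gs", brain_mask), ("wm", wm_mask), ("csf", csf_mask)):
        mask = np.asarray(mask).astype(bool)
        if not mask.any():
            raise ValueError(f"{name} mask is empty")
        if name == "gs":
            eroded, used = mask, 0
        else:
            eroded, used = _erode_to_limit(mask)
        out[name] = data4d[eroded].mean(axis=0)
        iters[name] = used
    return NuisanceSet(gs=out["gs"], wm=out["wm"], csf=out["csf"], erosion_iterations=iters)


def _backward_diff(x: np.ndarray, axis: int = -1) -> np.ndarray:
    d = np.zeros_like(x)
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(1, None)
    d[tuple(sl)] = np.diff(x, axis=axis)
    return d


def build_mp_regressors(mp: MotionTrace, band: FilterSpec = BANDPASS_RSFC) -> np.ndarray:
    """T x 24 motion block: band-passed MPs, their squares, their
    backward-difference derivatives, and the squared derivatives.
    Squares are taken after filtering; derivatives are of the filtered
    parameters, with element 0 set to 0."""
    fs = 1.0 / mp.tr
    mpf = butterworth_zero_phase(mp.values.T, fs, band).T  # T x 6
    dmp = _backward_diff(mpf, axis=0)
    return np.hstack([mpf, mpf**2, dmp, dmp**2])


def _fit_trend_on_kept(X: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Remove per-row mean and least-squares linear trend fitted on kept
    frames only, evaluated over all frames."""
    T = X.shape[-1]
    t = np.nonzero(keep)[0].astype(float)
    if t.size < 2:
        raise ValueError("fewer than 2 kept frames")
    tm = t.mean()
    xc = t - tm
    denom = float(xc @ xc)
    Xk = X[..., keep]
    slope = (Xk @ xc) / denom
    mean = Xk.mean(axis=-1)
    grid = np.arange(T) - tm
    return X - mean[..., None] - slope[..., None] * grid


def _interp_censored(X: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Linear interpolation across censored frames; edge runs of
    censored frames are held at the nearest kept value."""
    if keep.all():
        return X
    kept = np.nonzero(keep)[0]
    out = X.copy()
    cens = np.nonzero(~keep)[0]
    pos = np.interp(cens, kept, kept)  # fractional positions between kept neighbors
    left = np.searchsorted(kept, cens) - 1
    left = np.clip(left, 0, kept.size - 1)
    right = np.clip(left + 1, 0, kept.size - 1)
    lo, hi = kept[left], kept[right]
    with np.errstate(invalid="ignore"):
        w = np.where(hi > lo, (cens - lo) / np.where(hi > lo, hi - lo, 1), 0.0)
    w = np.clip(w, 0.0, 1.0)
    out[..., cens] = (1 - w) * X[..., lo] + w * X[..., hi]
    return out


def preprocess_run(
    run: RunTimeseries,
    keep: np.ndarray | None = None,
    band: FilterSpec = BANDPASS_RSFC,
    trim: int = EDGE_TRIM_DEFAULT,
) -> RunTimeseries:
    """Demean/detrend, interpolate over censored frames, band-pass, trim
    ``trim`` volumes per edge, and drop censored frames from the
    retained window.  ROI rows and nuisance series take the same path.
    """
    T = run.n_frames
    keep = run.keep if keep is None else np.asarray(keep, bool)
    if int(keep.sum()) < 2:
        raise ValueError("fewer than 2 kept frames")
    names = list(run.nuisance)
    stack = np.vstack([run.roi_data] + [run.nuisance[n][None, :] for n in names])
    stack = _fit_trend_on_kept(stack, keep)
    stack = _interp_censored(stack, keep)
    stack = butterworth_zero_phase(stack, 1.0 / run.tr, band)
    window = slice(trim, T - trim) if trim > 0 else slice(None)
    stack = stack[:, window]
    retained = keep[window]
    stack = stack[:, retained]
    n_roi = run.n_roi
    return RunTimeseries(
        stack[:n_roi],
        tr=run.tr,
        nuisance={n: stack[n_roi + i] for i, n in enumerate(names)},
        normalized=run.normalized,
        filtered=True,
        trimmed=True,
        subject_id=run.subject_id,
        run_id=run.run_id,
    )


def partial_corr_matrix(data: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Fisher-z partial correlations of every row pair of ``data``
    (n_series x t) after least-squares residualization against
    ``design`` (t x p).  Raises on rank-deficient designs, naming the
    offending columns."""
    data = np.asarray(data, float)
    design = np.asarray(design, float)
    t = data.shape[1]
    if design.shape[0] != t:
        raise ValueError("design and data frame counts differ")
    p = design.shape[1]
    if t < p + 2:
        raise ValueError(f"need at least p+2={p + 2} frames, got {t}")
    # scale columns for a meaningful rank tolerance; guard zero columns
    norms = np.linalg.norm(design, axis=0)
    if np.any(norms == 0):
        bad = list(np.nonzero(norms == 0)[0])
        raise ValueError(f"design columns {bad} are identically zero")
    q, r = np.linalg.qr(design / norms)
    small = np.abs(np.diag(r)) < 1e-10
    if small.any():
        raise ValueError(f"design is rank deficient; collinear columns {list(np.nonzero(small)[0])}")
    resid = data.T - q @ (q.T @ data.T)  # t x n
    resid = resid - resid.mean(axis=0)  # Pearson demeaning (no-op when the design has an intercept)
    # a series lying in the design span has a ~zero residual; its partial
    # correlation with anything is 0 by convention
    sd = resid.std(axis=0)
    ref = np.maximum(data.std(axis=1), 1.0)
    annihilated = sd <= 1e-12 * ref
    safe = np.where(annihilated, 1.0, sd)
    rn = resid / safe
    corr = (rn.T @ rn) / resid.shape[0]
    corr[annihilated, :] = 0.0
    corr[:, annihilated] = 0.0
    iu = np.triu_indices(data.shape[0], k=1)
    return np.arctanh(np.clip(corr[iu], -_Z_CLAMP, _Z_CLAMP))


def subject_rsfc(run_z: list[np.ndarray]) -> np.ndarray:
    """Unweighted mean of run-level Fisher-z vectors."""
    if not run_z:
        raise ValueError("no included runs")
    return np.mean(np.asarray(run_z, dtype=float), axis=0)


# ---------------------------------------------------------------------------
# batch engine: one run, many censor masks (used by MAC-RSFC and the sweeps)


@dataclass
class RunContext:
    """Mask-independent precomputation for one run."""

    roi: np.ndarray  # n_roi x T raw
    aux: np.ndarray  # n_aux x T raw nuisance series (order: wm, csf, gs as present)
    mp_block: np.ndarray  # T x 24
    tr: float
    trim: int = EDGE_TRIM_DEFAULT
    band: FilterSpec = BANDPASS_RSFC


def make_run_context(
    run: RunTimeseries,
    mp: MotionTrace,
    gsr: bool = False,
    band: FilterSpec = BANDPASS_RSFC,
    trim: int = EDGE_TRIM_DEFAULT,
) -> RunContext:
    aux_rows = []
    for name in ("WM", "CSF"):
        if name in run.nuisance:
            aux_rows.append(run.nuisance[name])
    if gsr:
        if "GS" not in run.nuisance:
            raise ValueError("GSR requested but run has no GS nuisance series")
        aux_rows.append(run.nuisance["GS"])
    aux = np.vstack(aux_rows) if aux_rows else np.empty((0, run.n_frames))
    return RunContext(
        roi=run.roi_data,
        aux=aux,
        mp_block=build_mp_regressors(mp, band),
        tr=run.tr,
        trim=trim,
        band=band,
    )


def censored_z_multi(ctx: RunContext, masks: list[np.ndarray]) -> np.ndarray:
    """Fisher-z partial-correlation vectors for one run under several
    censor masks.  Filtering is batched across masks for speed; the
    result is identical to running the pipeline per mask."""
    T = ctx.roi.shape[1]
    n_roi, n_aux = ctx.roi.shape[0], ctx.aux.shape[0]
    rows = n_roi + n_aux
    prepped = []
    for keep in masks:
        keep = np.asarray(keep, bool)
        stack = np.vstack([ctx.roi, ctx.aux]) if n_aux else ctx.roi
        stack = _fit_trend_on_kept(stack, keep)
        stack = _interp_censored(stack, keep)
        prepped.append(stack)
    big = np.vstack(prepped)
    big = butterworth_zero_phase(big, 1.0 / ctx.tr, ctx.band)
    window = slice(ctx.trim, T - ctx.trim) if ctx.trim > 0 else slice(None)
    mp_win = ctx.mp_block[window]
    out = []
    for m, keep in enumerate(masks):
        keep = np.asarray(keep, bool)
        stack = big[m * rows : (m + 1) * rows]
        aux_f = stack[n_roi:]
        d_aux = _backward_diff(aux_f, axis=-1)
        stack_w = stack[:, window]
        aux_w = stack_w[n_roi:]
        d_aux_w = d_aux[:, window]
        retained = keep[window]
        roi_r = stack_w[:n_roi][:, retained]
        design = np.hstack(
            [mp_win[retained]]
            + ([aux_w[:, retained].T, d_aux_w[:, retained].T] if n_aux else [])
            + [np.ones((int(retained.sum()), 1))]
        )
        out.append(partial_corr_matrix(roi_r, design))
    return np.asarray(out)


def censored_z(ctx: RunContext, keep: np.ndarray) -> np.ndarray:
    """Single-mask convenience wrapper around :func:`censored_z_multi`."""
    return censored_z_multi(ctx, [keep])[0]


def dataset_rsfc(
    runs: dict,
    plan=None,
    gsr: bool = False,
    band: FilterSpec = BANDPASS_RSFC,
    trim: int = EDGE_TRIM_DEFAULT,
) -> tuple[list, np.ndarray]:
    """Subject-level Fisher-z table for a whole dataset.

    ``runs`` maps (subject, run) to an object with ``motion`` and ``ts``
    attributes; ``plan`` is a CensorPlan (None = no censoring).  Returns
    (retained subjects, subjects x pairs array), averaging run-level z
    over each subject's included runs.
    """
    if plan is None:
        subjects = sorted({s for (s, _) in runs})
        included = {k: True for k in runs}
        masks = {k: np.ones(runs[k].ts.n_frames, bool) for k in runs}
    else:
        subjects = sorted({s for (s, _) in runs if plan.retained.get(s, False)})
        included = plan.included
        masks = plan.masks
    out = []
    for s in subjects:
        zs = []
        for key in sorted(k for k in runs if k[0] == s and included.get(k, False)):
            sim = runs[key]
            ctx = make_run_context(sim.ts, sim.motion, gsr=gsr, band=band, trim=trim)
            zs.append(censored_z(ctx, masks[key]))
        out.append(subject_rsfc(zs))
    return subjects, np.asarray(out)
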