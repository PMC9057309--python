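"""Censoring-parameter optimization by bias-variance decomposition.

The objective, evaluated per ROI pair and averaged, is the change due
to censoring in (between-subject variance + squared motion-induced
bias) / N_subjects: censoring removes artifact-driven bias but costs
frames, runs and eventually subjects, and the minimum of the resulting
curve over the 0-80% frames-removed range defines the optimal censoring
parameter.

The bias terms are built from the measured change in mean connectivity
under targeted vs count-matched random censoring (the MAC-RSFC DeltaZ
machinery): the change in bias at a grid point is the additive inverse
of |mean_i DeltaZ_{i,k}|, and the total removable bias of uncensored
data is extrapolated to 100% frames removed from a zero-intercept
robust (bisquare) regression of that quantity on percent removed, after
resampling every curve to a 0.01% grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .censoring import apply_exclusion, fit_gev, gev_dv_threshold, mask_from_threshold
from .framewise import BANDPASS_RSFC, FilterSpec, compute_dv, compute_fd
from .mac_rsfc import N_RAND_DEFAULT, delta_z
from .rsfc import EDGE_TRIM_DEFAULT, make_run_context

logger = logging.getLogger(__name__)

#: Bisquare tuning constant for the bias-extrapolation robust fit.
BISQUARE_C = 4.685
#: Resampling resolution (percent frames removed) for all curves.
RESAMPLE_STEP_PCT = 0.01
#: Search range (percent removed) for the optimum.
SEARCH_RANGE_PCT = (0.0, 80.0)
#: Fixed Phi_F / d_G ratios (mm) transferred from large-sample combined
#: optimization: keyed by GSR state.
COMBINED_RATIO_DEFAULT = {False: 0.02438, True: 11.0277}


@dataclass
class SweepResult:
    """Per-grid-point censoring outcomes along one parameter axis."""

    method: str
    grid_params: np.ndarray  # Phi_F, d_G, or the combined multiplier
    percents: np.ndarray  # realized % frames removed
    delta_bias: np.ndarray  # G x K, Eq-style change in bias (<= 0)
    var_c: np.ndarray  # G x K between-subject variance after censoring
    n_s: np.ndarray  # G, subjects retained
    n_su: int
    var_u: np.ndarray  # K, uncensored between-subject variance
    mean_u: np.ndarray  # K, uncensored mean z (diagnostic)


@dataclass
class ResampledSweep:
    percents: np.ndarray  # 0.01%-grid
    delta_bias: np.ndarray  # P x K
    var_c: np.ndarray  # P x K
    n_s: np.ndarray  # P
    n_su: int
    var_u: np.ndarray
    grid_percents: np.ndarray
    grid_params: np.ndarray
    method: str


@dataclass
class BiasEstimate:
    """Extrapolated total removable bias of uncensored data, per pair."""

    bias_u: np.ndarray  # slope * 100, z units, >= 0
    slope: np.ndarray
    ols_fallback: int = 0


@dataclass
class OptimResult:
    method: str
    percent_opt: float
    param_opt: float
    delta_mse_opt: float
    search_range: tuple
    percents: np.ndarray = field(repr=False, default=None)
    curve: np.ndarray = field(repr=False, default=None)
    negative_bias_sq: int = 0
    extra: dict = field(default_factory=dict)


def _pooled_quantile_thresholds(values: list[np.ndarray], targets: np.ndarray) -> np.ndarray:
    """Thresholds realizing the target removal percents, as pooled
    upper quantiles (target 0 maps to +inf)."""
    pooled = np.concatenate([v[1:] for v in values])  # frame 0 is convention, not data
    out = np.empty(targets.size)
    for i, p in enumerate(targets):
        out[i] = np.inf if p <= 0 else float(np.quantile(pooled, 1.0 - p / 100.0))
    return out


def sweep_censoring(
    dataset,
    method: str = "lpf-fd",
    percent_targets: np.ndarray | None = None,
    ratio: float | None = None,
    n_rand: int = N_RAND_DEFAULT,
    seed: int = 0,
    gsr: bool = False,
    band: FilterSpec = BANDPASS_RSFC,
    trim: int = EDGE_TRIM_DEFAULT,
    min_vol: int = 167,
    dv_variant: str = "lpf",
) -> SweepResult:
    """Sweep a censoring parameter so realized removal spans ~0-80%.

    method 'lpf-fd' thresholds LPF-FD at pooled quantiles; 'gev-dv'
    sweeps the run-adaptive d_G; 'combined-ratio' sweeps Phi_F with d_G
    locked to Phi_F / ratio and masks combined by union.  The DV source
    is the run's ROI matrix.
    """
    if percent_targets is None:
        percent_targets = np.arange(0.0, 85.0, 5.0)
    percent_targets = np.asarray(percent_targets, float)
    if 0.0 not in percent_targets:
        percent_targets = np.concatenate([[0.0], percent_targets])
    percent_targets = np.unique(percent_targets)

    runs = dataset.runs
    keys = sorted(runs)
    contexts = {
        k: make_run_context(runs[k].ts, runs[k].motion, gsr=gsr, band=band, trim=trim)
        for k in keys
    }
    need_fd = method in ("lpf-fd", "combined-ratio")
    need_dv = method in ("gev-dv", "combined-ratio")
    fd = {k: compute_fd(runs[k].motion, "lpf").values for k in keys} if need_fd else {}
    dv, gev = {}, {}
    if need_dv:
        for k in keys:
            dv[k] = compute_dv(runs[k].ts.roi_data, runs[k].ts.tr, dv_variant).values
            gev[k] = fit_gev(dv[k])

    if method == "lpf-fd":
        grid = _pooled_quantile_thresholds(list(fd.values()), percent_targets)
    elif method == "gev-dv":
        mean_num = float(np.mean([max(g.shape + 0.3, 0.0) for g in gev.values()]))
        mean_num = max(mean_num, 1e-6)
        grid = np.array(
            [np.inf if p <= 0 else mean_num / (p / 100.0) for p in percent_targets]
        )
    elif method == "combined-ratio":
        if ratio is None:
            ratio = COMBINED_RATIO_DEFAULT[gsr]
        grid = _pooled_quantile_thresholds(list(fd.values()), percent_targets)
    else:
        raise ValueError(f"unknown method {method!r}")

    rows = []
    for gi, param in enumerate(grid):
        masks = {}
        for k in keys:
            keep = np.ones(runs[k].ts.n_frames, bool)
            if need_fd and np.isfinite(param):
                keep &= mask_from_threshold(fd[k], param)
            if method == "gev-dv":
                if np.isfinite(param):
                    thr = gev_dv_threshold(gev[k], param, values=dv[k][1:])
                    if np.isfinite(thr):
                        keep &= dv[k] <= thr
                    elif thr == -np.inf:
                        keep[1:] = False
            elif method == "combined-ratio" and np.isfinite(param):
                d_g = param / ratio
                thr = gev_dv_threshold(gev[k], d_g, values=dv[k][1:])
                if np.isfinite(thr):
                    keep &= dv[k] <= thr
                elif thr == -np.inf:
                    keep[1:] = False
            masks[k] = keep
        plan = apply_exclusion(masks, min_vol=min_vol)
        if plan.n_subjects_retained < 3:
            logger.info("grid point %d removes too many subjects; truncating sweep", gi)
            break
        table = delta_z(
            runs, plan, n_rand=n_rand, seed=seed, gsr=gsr, band=band, trim=trim,
            contexts=contexts,
        )
        rows.append(
            dict(
                param=param,
                percent=plan.percent_removed,
                dbias=-np.abs(table.delta_z.mean(axis=0)),
                var_c=table.targeted_z.var(axis=0, ddof=1),
                n_s=plan.n_subjects_retained,
                mean_c=table.targeted_z.mean(axis=0),
            )
        )
    if not rows or rows[0]["percent"] > 0:
        raise ValueError("sweep grid does not include the no-censoring anchor")
    base = rows[0]
    return SweepResult(
        method=method,
        grid_params=np.array([r["param"] for r in rows]),
        percents=np.array([r["percent"] for r in rows]),
        delta_bias=np.vstack([r["dbias"] for r in rows]),
        var_c=np.vstack([r["var_c"] for r in rows]),
        n_s=np.array([r["n_s"] for r in rows]),
        n_su=int(base["n_s"]),
        var_u=base["var_c"],
        mean_u=base["mean_c"],
    )


def resample_sweep(
    sweep: SweepResult,
    step: float = RESAMPLE_STEP_PCT,
    max_pct: float | None = None,
) -> ResampledSweep:
    """Re-parameterize by percent removed and linearly resample every
    curve to the fine grid."""
    order = np.argsort(sweep.percents)
    x = sweep.percents[order]
    x, uniq = np.unique(x, return_index=True)
    idx = order[uniq]
    if max_pct is None:
        max_pct = min(SEARCH_RANGE_PCT[1], float(x.max()))
    grid = np.arange(0.0, max_pct + step / 2, step)
    db = np.column_stack(
        [np.interp(grid, x, sweep.delta_bias[idx, k]) for k in range(sweep.delta_bias.shape[1])]
    )
    vc = np.column_stack(
        [np.interp(grid, x, sweep.var_c[idx, k]) for k in range(sweep.var_c.shape[1])]
    )
    ns = np.interp(grid, x, sweep.n_s[idx].astype(float))
    return ResampledSweep(
        percents=grid,
        delta_bias=db,
        var_c=vc,
        n_s=ns,
        n_su=sweep.n_su,
        var_u=sweep.var_u,
        grid_percents=x,
        grid_params=sweep.grid_params[idx],
        method=sweep.method,
    )


def estimate_uncensored_bias(
    resampled: ResampledSweep,
    c: float = BISQUARE_C,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> BiasEstimate:
    """Per pair, fit -DeltaBias vs percent removed through the origin by
    IRLS with bisquare weights (tuning constant ``c``), OLS start, and
    extrapolate to 100% removed: bias_u = slope * 100."""
    x = resampled.percents
    Y = -resampled.delta_bias.T  # K x P
    sxx = float(x @ x)
    if sxx == 0:
        return BiasEstimate(bias_u=np.zeros(Y.shape[0]), slope=np.zeros(Y.shape[0]))
    slope = Y @ x / sxx
    ols_slope = slope.copy()
    fallback = np.zeros(Y.shape[0], bool)
    for _ in range(max_iter):
        resid = Y - slope[:, None] * x
        med = np.median(resid, axis=1, keepdims=True)
        scale = 1.4826 * np.median(np.abs(resid - med), axis=1)
        active = scale > 0
        if not active.any():
            break
        u = np.zeros_like(resid)
        u[active] = resid[active] / (c * scale[active, None])
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        wxx = w @ (x**2)
        wxy = (w * Y) @ x
        new = slope.copy()
        good = active & (wxx > 0)
        new[good] = wxy[good] / wxx[good]
        bad = active & (wxx <= 0)
        if bad.any():
            new[bad] = ols_slope[bad]
            fallback |= bad
        delta = np.max(np.abs(new - slope) / np.maximum(1.0, np.abs(slope)))
        slope = new
        if delta < tol:
            break
    else:
        logger.warning("bias extrapolation IRLS hit iteration cap; using last iterate")
    return BiasEstimate(bias_u=slope * 100.0, slope=slope, ols_fallback=int(fallback.sum()))


def delta_mse(resampled: ResampledSweep, bias: BiasEstimate) -> tuple[np.ndarray, int]:
    """DeltaMSE-RSFC curve on the resampled grid, plus the count of
    negative post-censoring squared-bias values (tracked, not clamped).

    Per pair: Bias_c^2 = Bias_u^2 + [(Bias_u + DeltaBias)^2 - Bias_u^2];
    DeltaMSE_k = (var_c + Bias_c^2)/N_S - (var_u + Bias_u^2)/N_SU; the
    curve is the mean over pairs.
    """
    bu = bias.bias_u[None, :]
    db = resampled.delta_bias
    delta_bias_sq = (bu + db) ** 2 - bu**2
    bias_c_sq = bu**2 + delta_bias_sq
    neg = int((bias_c_sq < -1e-15).sum())
    if neg:
        logger.warning("%d grid cells produced negative squared bias", neg)
    mse_c = (resampled.var_c + bias_c_sq) / resampled.n_s[:, None]
    mse_u = (resampled.var_u + bias.bias_u**2) / resampled.n_su
    curve = (mse_c - mse_u[None, :]).mean(axis=1)
    return curve, neg


def optimize_single(
    percents: np.ndarray,
    curve: np.ndarray,
    search_range: tuple = SEARCH_RANGE_PCT,
    percent_to_param: tuple[np.ndarray, np.ndarray] | None = None,
) -> OptimResult:
    """Global minimum of the DeltaMSE-RSFC curve within the search range.

    The censoring parameter at the optimum is recovered by inverse
    interpolation of the percent <-> parameter map."""
    lo, hi = search_range
    sel = (percents >= lo) & (percents <= hi)
    if not sel.any():
        raise ValueError("search range contains no grid points")
    if not np.all(np.isfinite(curve[sel])):
        bad = percents[sel][~np.isfinite(curve[sel])]
        raise ValueError(f"non-finite objective at percent(s) {bad[:5]}")
    i = int(np.argmin(np.where(sel, curve, np.inf)))
    pct = float(percents[i])
    param = np.nan
    if percent_to_param is not None:
        xs, ps = percent_to_param
        finite = np.isfinite(ps)
        if finite.any():
            param = float(np.interp(pct, xs[finite], ps[finite]))
    return OptimResult(
        method="",
        percent_opt=pct,
        param_opt=param,
        delta_mse_opt=float(curve[i]),
        search_range=search_range,
        percents=percents,
        curve=curve,
    )


def optimize_censoring(
    dataset,
    method: str = "lpf-fd",
    search_range: tuple = SEARCH_RANGE_PCT,
    **sweep_kw,
) -> OptimResult:
    """End-to-end single-method optimization: sweep, resample, bias
    extrapolation, DeltaMSE curve, 1-D minimum."""
    sweep = sweep_censoring(dataset, method=method, **sweep_kw)
    res = resample_sweep(sweep)
    bias = estimate_uncensored_bias(res)
    curve, neg = delta_mse(res, bias)
    out = optimize_single(
        res.percents, curve, search_range, (res.grid_percents, res.grid_params)
    )
    out.method = method
    out.negative_bias_sq = neg
    out.extra = {"sweep": sweep, "resampled": res, "bias": bias}
    return out


def optimize_combined_fixed_ratio(
    dataset,
    ratio: float | None = None,
    gsr: bool = False,
    search_range: tuple = SEARCH_RANGE_PCT,
    **sweep_kw,
) -> OptimResult:
    """1-D optimization of combined LPF-FD + GEV-DV censoring with
    Phi_F / d_G locked to ``ratio`` (defaults transferred from
    large-sample joint optimization) and masks combined by union."""
    if ratio is None:
        ratio = COMBINED_RATIO_DEFAULT[gsr]
    out = optimize_censoring(
        dataset, method="combined-ratio", ratio=ratio, gsr=gsr,
        search_range=search_range, **sweep_kw,
    )
    out.extra["ratio"] = ratio
    out.extra["d_g_opt"] = out.param_opt / ratio if np.isfinite(out.param_opt) else np.nan
    return out


def optimize_2d_grid(
    dataset,
    phi_grid: np.ndarray,
    dg_grid: np.ndarray,
    search_range: tuple = SEARCH_RANGE_PCT,
    n_rand: int = N_RAND_DEFAULT,
    seed: int = 0,
    gsr: bool = False,
    band: FilterSpec = BANDPASS_RSFC,
    trim: int = EDGE_TRIM_DEFAULT,
    min_vol: int = 167,
) -> OptimResult:
    """Exhaustive coarse 2-D grid over (Phi_F, d_G).

    The per-pair uncensored bias is extrapolated from a 1-D LPF-FD
    sweep, then Eq-style DeltaMSE is evaluated at every (Phi_F, d_G)
    cell whose realized removal lies in the search range.  Cost grows
    with the grid product; log a warning for large grids.
    """
    phi_grid = np.asarray(phi_grid, float)
    dg_grid = np.asarray(dg_grid, float)
    if phi_grid.size * dg_grid.size > 400:
        logger.warning("2-D grid of %d cells will be slow", phi_grid.size * dg_grid.size)
    base = optimize_censoring(
        dataset, method="lpf-fd", search_range=search_range,
        n_rand=n_rand, seed=seed, gsr=gsr, band=band, trim=trim, min_vol=min_vol,
    )
    bias = base.extra["bias"]
    runs = dataset.runs
    keys = sorted(runs)
    contexts = {
        k: make_run_context(runs[k].ts, runs[k].motion, gsr=gsr, band=band, trim=trim)
        for k in keys
    }
    fd = {k: compute_fd(runs[k].motion, "lpf").values for k in keys}
    dv = {k: compute_dv(runs[k].ts.roi_data, runs[k].ts.tr, "lpf").values for k in keys}
    gev = {k: fit_gev(dv[k]) for k in keys}
    sweep0 = base.extra["sweep"]
    best = None
    neg_total = 0
    for phi in phi_grid:
        for dg in dg_grid:
            masks = {}
            for k in keys:
                keep = mask_from_threshold(fd[k], phi) if np.isfinite(phi) else np.ones(
                    fd[k].size, bool
                )
                thr = gev_dv_threshold(gev[k], dg, values=dv[k][1:])
                if np.isfinite(thr):
                    keep = keep & (dv[k] <= thr)
                elif thr == -np.inf:
                    keep = keep.copy()
                    keep[1:] = False
                masks[k] = keep
            plan = apply_exclusion(masks, min_vol=min_vol)
            pct = plan.percent_removed
            if not (search_range[0] <= pct <= search_range[1]):
                continue
            if plan.n_subjects_retained < 3:
                continue
            table = delta_z(
                runs, plan, n_rand=n_rand, seed=seed, gsr=gsr, band=band, trim=trim,
                contexts=contexts,
            )
            dbias = -np.abs(table.delta_z.mean(axis=0))
            var_c = table.targeted_z.var(axis=0, ddof=1)
            bu = bias.bias_u
            bias_c_sq = (bu + dbias) ** 2
            neg_total += int((bias_c_sq < -1e-15).sum())
            val = float(
                np.mean(
                    (var_c + bias_c_sq) / plan.n_subjects_retained
                    - (sweep0.var_u + bu**2) / sweep0.n_su
                )
            )
            if best is None or val < best[0]:
                best = (val, phi, dg, pct)
    if best is None:
        raise ValueError("no 2-D grid cell falls inside the search range")
    val, phi, dg, pct = best
    return OptimResult(
        method="2d-grid",
        percent_opt=pct,
        param_opt=phi,
        delta_mse_opt=val,
        search_range=search_range,
        negative_bias_sq=neg_total,
        extra={"phi_opt": phi, "d_g_opt": dg, "bias": bias},
    )


def group_mse_to_truth(Z: np.ndarray, truth: np.ndarray) -> float:
    """Truth-referenced MSE of the group-mean estimate: mean over pairs
    of (mean_i z - theta)^2 + var_i(z)/N.  Used to validate optima on
    synthetic data where theta is known."""
    Z = np.asarray(Z, float)
    n = Z.shape[0]
    return float(np.mean((Z.mean(axis=0) - truth) ** 2 + Z.var(axis=0, ddof=1) / n))
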