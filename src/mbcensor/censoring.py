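"""Censor-mask construction and run/subject exclusion accounting.

Fixed-threshold censoring flags frames whose framewise statistic exceeds
a threshold.  Run-adaptive GEV-DV censoring instead fits a generalized
extreme value distribution to each run's (low-pass-filtered) DV values
and censors the right tail whose mass is (k_G + 0.3) / d_G, where k_G is
the fitted shape and d_G a dataset-wide aggressiveness parameter: runs
with heavier DV tails (larger k_G) lose proportionally more frames.

Shape-parameter sign convention: k_G > 0 means a heavy right tail
(Frechet domain), matching the convention of common statistics packages;
this is the negative of scipy's ``genextreme`` shape ``c``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .framewise import FramewiseSeries

logger = logging.getLogger(__name__)

#: Minimum uncensored volumes for a run to stay in the analysis
#: (2 minutes at the reference multiband TR of 0.72 s).
MIN_VOLUMES_DEFAULT = 167


@dataclass
class CensorParams:
    """Censoring thresholds: phi_f (mm, LPF-FD), phi_d (signal units,
    fixed LPF-DV), d_g (dimensionless, GEV-DV).  Any may be None."""

    phi_f: float | None = None
    phi_d: float | None = None
    d_g: float | None = None
    fd_variant: str = "lpf"
    dv_variant: str = "lpf"

    def __post_init__(self) -> None:
        for name in ("phi_f", "phi_d", "d_g"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass
class GEVFit:
    """Maximum-likelihood GEV parameters for one run's DV values."""

    shape: float  # k_G, heavy-right-tail-positive convention
    scale: float
    loc: float
    n: int
    converged: bool

    def tail_quantile(self, q: float) -> float:
        """Value with right-tail mass q under the fitted distribution."""
        return float(stats.genextreme.ppf(1.0 - q, -self.shape, loc=self.loc, scale=self.scale))


def mask_from_threshold(series: FramewiseSeries | np.ndarray, phi: float) -> np.ndarray:
    """Boolean keep vector: keep[t] iff values[t] <= phi (ties kept)."""
    if phi <= 0:
        raise ValueError("threshold must be positive")
    values = series.values if isinstance(series, FramewiseSeries) else np.asarray(series, float)
    return values <= phi


def _pwm_start(x: np.ndarray) -> tuple[float, float, float]:
    """Probability-weighted-moments starting point (Hosking) for GEV MLE.

    Returns (shape k, scale, loc) in the heavy-tail-positive convention.
    """
    x = np.sort(x)
    n = x.size
    j = np.arange(n)
    b0 = x.mean()
    b1 = np.sum(j / (n - 1.0) * x) / n
    b2 = np.sum(j * (j - 1.0) / ((n - 1.0) * (n - 2.0)) * x) / n
    c = (2 * b1 - b0) / (3 * b2 - b0) - np.log(2) / np.log(3)
    kappa = 7.8590 * c + 2.9554 * c**2  # Hosking's k: >0 means bounded tail
    from scipy.special import gamma as gamma_fn

    if abs(kappa) < 1e-9:
        kappa = 1e-9
    g = gamma_fn(1 + kappa)
    sigma = (2 * b1 - b0) * kappa / (g * (1 - 2.0**-kappa))
    mu = b0 + sigma * (g - 1) / kappa
    if not (np.isfinite(sigma) and sigma > 0 and np.isfinite(mu)):
        sigma = max(x.std(), 1e-12)
        mu = x.mean()
        kappa = 0.1
    return -kappa, sigma, mu  # convert Hosking k to heavy-tail-positive shape


def fit_gev(dv: FramewiseSeries | np.ndarray) -> GEVFit:
    """Fit a GEV distribution by maximum likelihood.

    Frame 0 (whose 0 value is a convention, not data) is excluded.  The
    data are standardized before optimization and the parameters mapped
    back, which makes the fit exactly location/scale equivariant.  A
    probability-weighted-moments start feeds a Nelder-Mead refinement of
    the negative log-likelihood (tolerance 1e-8).
    """
    values = dv.values[1:] if isinstance(dv, FramewiseSeries) else np.asarray(dv, float)
    values = values[np.isfinite(values)]
    if values.size < 50:
        raise ValueError(f"need >= 50 finite values to fit a GEV, got {values.size}")
    m, s = float(values.mean()), float(values.std())
    if s <= 0:
        return GEVFit(shape=0.0, scale=1e-12, loc=m, n=values.size, converged=False)
    y = (values - m) / s

    k0, sig0, mu0 = _pwm_start(y)

    def nll(params: np.ndarray) -> float:
        k, log_sig, mu = params
        with np.errstate(all="ignore"):
            ll = stats.genextreme.logpdf(y, -k, loc=mu, scale=np.exp(log_sig))
        if not np.all(np.isfinite(ll)):
            return 1e12
        return -float(ll.sum())

    converged = False
    res = optimize.minimize(
        nll,
        x0=np.array([k0, np.log(sig0), mu0]),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000},
    )
    if not (res.success and np.isfinite(res.fun) and res.fun < 1e11):
        # fallback initialization: Gumbel-ish moment start
        res2 = optimize.minimize(
            nll,
            x0=np.array([0.05, np.log(max(y.std(), 1e-6) * 0.78), float(np.median(y))]),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000},
        )
        if res2.fun < res.fun:
            res = res2
        converged = bool(res.success and np.isfinite(res.fun) and res.fun < 1e11)
    else:
        converged = True
    k, log_sig, mu = res.x
    return GEVFit(
        shape=float(k),
        scale=float(np.exp(log_sig) * s),
        loc=float(mu * s + m),
        n=values.size,
        converged=converged,
    )


def gev_dv_threshold(
    fit: GEVFit,
    d_g: float,
    values: np.ndarray | None = None,
) -> float:
    """Run-adaptive DV threshold: right-tail mass (k_G + 0.3) / d_G.

    The numerator is floored at 0 (k_G <= -0.3 censors nothing) and the
    mass capped at 1 (censor everything).  If the fit did not converge,
    falls back to the empirical quantile of ``values`` with k_G treated
    as 0, with a logged warning.
    """
    if d_g <= 0:
        raise ValueError("d_g must be positive")
    if fit.converged:
        q = float(np.clip((fit.shape + 0.3) / d_g, 0.0, 1.0))
        if q <= 0:
            return np.inf
        if q >= 1:
            return -np.inf
        return fit.tail_quantile(q)
    if values is None:
        raise ValueError("unconverged GEV fit and no values for empirical fallback")
    logger.warning("GEV fit did not converge; using empirical quantile fallback")
    warnings.warn("GEV fit did not converge; empirical quantile fallback used", RuntimeWarning)
    q = float(np.clip(0.3 / d_g, 0.0, 1.0))
    if q <= 0:
        return np.inf
    if q >= 1:
        return -np.inf
    return float(np.quantile(values, 1.0 - q))


def combine_masks(*masks: np.ndarray) -> np.ndarray:
    """Elementwise AND of keep vectors (union of the censored sets)."""
    if not masks:
        raise ValueError("need at least one mask")
    length = len(masks[0])
    out = np.ones(length, dtype=bool)
    for m in masks:
        m = np.asarray(m, dtype=bool)
        if m.shape != (length,):
            raise ValueError(f"mask length mismatch: {m.shape} vs ({length},)")
        out &= m
    return out


def random_mask_like(keep: np.ndarray, seed) -> np.ndarray:
    """A keep vector censoring a uniformly random subset of the same run,
    matched in count to the targeted mask.  Deterministic given seed."""
    keep = np.asarray(keep, dtype=bool)
    k = int((~keep).sum())
    out = np.ones(keep.size, dtype=bool)
    if k == 0:
        return out
    rng = np.random.default_rng(seed)
    out[rng.choice(keep.size, size=k, replace=False)] = False
    return out


@dataclass
class CensorPlan:
    """Dataset-wide censoring outcome.

    ``masks`` maps (subject, run) -> keep vector.  Runs with fewer than
    ``min_vol`` kept frames are excluded; a subject is retained iff at
    least one run remains.  ``percent_removed`` uses the pre-exclusion
    denominator: every frame entering censoring consideration counts,
    including frames of runs that are later excluded.
    """

    masks: dict = field(default_factory=dict)
    included: dict = field(default_factory=dict)
    retained: dict = field(default_factory=dict)
    min_vol: int = MIN_VOLUMES_DEFAULT
    frames_flagged: int = 0
    frames_total: int = 0

    @property
    def percent_removed(self) -> float:
        if self.frames_total == 0:
            return 0.0
        return 100.0 * self.frames_flagged / self.frames_total

    @property
    def n_subjects_retained(self) -> int:
        return sum(bool(v) for v in self.retained.values())

    def subject_runs(self, subject) -> list:
        """Keys of this subject's included runs."""
        return [key for key, inc in self.included.items() if key[0] == subject and inc]


def apply_exclusion(masks: dict, min_vol: int = MIN_VOLUMES_DEFAULT) -> CensorPlan:
    """Build a CensorPlan from per-run keep vectors.

    A run stays included iff it retains at least ``min_vol`` frames; a
    subject is retained iff it has >= 1 included run.
    """
    plan = CensorPlan(masks={k: np.asarray(v, bool) for k, v in masks.items()}, min_vol=min_vol)
    for (subject, run), keep in plan.masks.items():
        kept = int(keep.sum())
        plan.frames_total += keep.size
        plan.frames_flagged += keep.size - kept
        plan.included[(subject, run)] = kept >= min_vol
        plan.retained.setdefault(subject, False)
        if plan.included[(subject, run)]:
            plan.retained[subject] = True
    return plan
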