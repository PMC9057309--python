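"""Synthetic multiband resting-state fMRI generator.

Produces multi-subject, multi-run fixtures with the statistical
structure the censoring methods assume: motion traces mixing slow AR(1)
drift, respiration-locked pseudomotion at ~0.3 Hz (the hallmark of
multiband acquisitions, concentrated on the phase-encode translation
axis), and sparse large spikes; and ROI timeseries drawn from a known
network covariance with an optional motion-coupled, distance-dependent
artifact added.  The ground-truth Fisher-z connectivity of the clean
signal is returned with the data, so estimator bias and truth-referenced
mean squared error are measurable.

Seed discipline: one master seed in the config; every stochastic
component draws from ``numpy.random.default_rng([master, tag, subject,
run])`` streams, so any run is reproducible in isolation and the whole
dataset is bit-identical across calls.

The respiratory waveform is ``exp(sin)``-shaped rather than a pure
sinusoid: real respiratory traces are asymmetric, and the asymmetry
matters here because FD rectifies parameter increments (a symmetric
sinusoid would alias its FD signature to twice the respiratory rate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .framewise import compute_fd
from .io_formats import MotionTrace, ROISet, RunTimeseries

__all__ = [
    "SynthConfig",
    "SimRun",
    "SyntheticDataset",
    "default_roi_centers",
    "default_network_covariance",
    "simulate_motion_trace",
    "simulate_dataset",
    "simulate_confounded_cohort",
]

#: Decay constant (s) of the exponential kernel coupling FD to BOLD artifact.
ARTIFACT_KERNEL_TAU_S = 6.0
#: Motion-severity multiplier carried by trait-positive subjects in the
#: confounded-cohort generator.  Chosen large enough that the trait is the
#: dominant source of between-subject motion differences, which is the
#: regime where SQM-based quality metrics are maximally misled.
TRAIT_SEVERITY_FACTOR = 3.0


class InvalidConfigError(ValueError):
    pass


def default_roi_centers(n_roi: int, seed: int = 0) -> np.ndarray:
    """Deterministic pseudo-random ROI centers inside a 70 mm radius sphere."""
    rng = np.random.default_rng([seed, 104729])
    pts = []
    while len(pts) < n_roi:
        p = rng.uniform(-70, 70, size=3)
        if np.linalg.norm(p) <= 70:
            pts.append(p)
    return np.asarray(pts)


def default_network_covariance(
    n_roi: int, within: float = 0.35, between: float = 0.08
) -> np.ndarray:
    """Two-block network covariance with unit variances."""
    half = n_roi // 2
    cov = np.full((n_roi, n_roi), between)
    cov[:half, :half] = within
    cov[half:, half:] = within
    np.fill_diagonal(cov, 1.0)
    return cov


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a desk-scale multiband resting-state study: 40
    subjects with 4 runs of 300 frames at TR = 0.72 s, 10 ROIs, 0.3 Hz
    respiratory pseudomotion, sparse ~0.8 mm spikes, and a
    motion-coupled artifact gain of 3 (signal units per mm of
    kernel-smoothed FD).
    """

    n_subjects: int = 40
    runs_per_subject: int = 4
    T: int = 300
    tr: float = 0.72
    n_roi: int = 10
    roi_centers: np.ndarray | None = None
    motion_level: float = 1.0
    resp_freq: float = 0.3
    resp_amp: float = 0.2
    spike_rate: float = 0.02
    spike_amp: float = 0.8
    artifact_coupling: float = 3.0
    network_covariance: np.ndarray | None = None
    noise_sd: float = 0.5
    drift_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 240:
            raise InvalidConfigError("T must be >= 240 (30-frame edge trims need room)")
        nyquist = 1.0 / (2.0 * self.tr)
        if not 0 < self.resp_freq < nyquist:
            raise InvalidConfigError(
                f"resp_freq must lie in (0, Nyquist={nyquist:g} Hz), got {self.resp_freq}"
            )
        if not 0 <= self.spike_rate <= 1:
            raise InvalidConfigError("spike_rate must be in [0, 1]")
        if self.roi_centers is None:
            self.roi_centers = default_roi_centers(self.n_roi, self.seed)
        self.roi_centers = np.asarray(self.roi_centers, float)
        if self.roi_centers.shape != (self.n_roi, 3):
            raise InvalidConfigError("roi_centers must be n_roi x 3")
        if self.network_covariance is None:
            self.network_covariance = default_network_covariance(self.n_roi)
        self.network_covariance = np.asarray(self.network_covariance, float)
        cov = self.network_covariance
        if cov.shape != (self.n_roi, self.n_roi):
            raise InvalidConfigError("network_covariance must be n_roi x n_roi")
        if not np.allclose(cov, cov.T):
            raise InvalidConfigError("network_covariance must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise InvalidConfigError("network_covariance must be positive semi-definite")


@dataclass
class SimRun:
    motion: MotionTrace
    ts: RunTimeseries


@dataclass
class SyntheticDataset:
    cfg: SynthConfig
    subjects: list[str]
    runs: dict  # (subject_id, run_id) -> SimRun
    ground_truth_z: np.ndarray
    severities: np.ndarray
    roi_set: ROISet
    trait: np.ndarray | None = None
    ground_truth_z_by_trait: dict | None = None

    def subject_runs(self, subject: str) -> list[SimRun]:
        return [sr for (s, _), sr in self.runs.items() if s == subject]

    def pair_distances(self) -> np.ndarray:
        return self.roi_set.pair_distances()


def _resp_waveform(t_s: np.ndarray, freq: float, phase: float) -> np.ndarray:
    """Quasi-respiratory waveform with alternating breath depth,
    zero-mean, unit peak-to-peak.

    w(theta) = 3 sin(theta/2) + (1/3) sin(3 theta/2), theta = 2 pi f t.
    Its derivative is cos(theta/2) (1 + cos theta), so the *magnitude*
    of the frame-to-frame increments rises and falls once per
    respiratory cycle: the FD signature of this pseudomotion peaks at
    the respiratory rate itself.  A pure sinusoid would not do this —
    FD rectifies increments, which would alias the whole signature to
    twice the respiratory frequency."""
    theta = 2 * np.pi * freq * t_s + phase
    w = 3 * np.sin(theta / 2) + np.sin(3 * theta / 2) / 3
    w = w - w.mean()
    return w / np.ptp(w)


def simulate_motion_trace(cfg: SynthConfig, subject_severity: float, seed) -> MotionTrace:
    """One run of rigid-body parameters: AR(1) drift on all six axes,
    respiratory pseudomotion (amplitude resp_amp * severity) on the
    phase-encode translation axis with a weaker copy on pitch, and
    sparse single-frame spikes (rate spike_rate, amplitude spike_amp *
    severity).  Rotations are emitted in degrees.
    """
    rng = np.random.default_rng(seed)
    T = cfg.T
    vals = np.zeros((T, 6))
    # slow drift: AR(1), phi=0.98, innovation sd drift_sd (mm / degrees)
    if cfg.drift_sd > 0:
        innov = rng.normal(0.0, cfg.drift_sd, size=(T, 6))
        drift = np.empty((T, 6))
        drift[0] = innov[0]
        for t in range(1, T):
            drift[t] = 0.98 * drift[t - 1] + innov[t]
        vals += drift
    else:
        rng.normal(0.0, 1.0, size=(T, 6))  # keep stream alignment
    # respiratory pseudomotion, phase-encode (y) translation + pitch
    amp = cfg.resp_amp * subject_severity
    phase = rng.uniform(0, 2 * np.pi)
    if amp > 0:
        w = _resp_waveform(np.arange(T) * cfg.tr, cfg.resp_freq, phase)
        vals[:, 1] += amp * w
        vals[:, 4] += 0.3 * amp * w  # degrees; ~0.26 mm arc per degree-equivalent
    # sparse spikes: single-frame offsets on a random translation axis
    spike_here = rng.random(T) < cfg.spike_rate
    axes = rng.integers(0, 3, size=T)
    signs = rng.choice([-1.0, 1.0], size=T)
    sizes = rng.uniform(0.5, 1.5, size=T)
    s_amp = cfg.spike_amp * subject_severity
    if s_amp > 0:
        for t in np.nonzero(spike_here)[0]:
            vals[t, axes[t]] += s_amp * signs[t] * sizes[t]
    return MotionTrace(vals, tr=cfg.tr, units="degrees")


def _exp_kernel(tr: float, tau_s: float = ARTIFACT_KERNEL_TAU_S) -> np.ndarray:
    """Causal single-exponential kernel, unit sum, truncated at 5 tau."""
    n = max(int(np.ceil(5 * tau_s / tr)), 1)
    k = np.exp(-np.arange(n) * tr / tau_s)
    return k / k.sum()


def _artifact_loadings(centers: np.ndarray, seed: int) -> np.ndarray:
    """Spatially smooth positive artifact loadings (GP with a 60 mm RBF
    kernel around 1), so injected artifact covariance decays with
    inter-ROI distance."""
    rng = np.random.default_rng([seed, 7907])
    d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    K = 0.16 * np.exp(-d2 / (2 * 60.0**2)) + 1e-8 * np.eye(len(centers))
    ell = 1.0 + np.linalg.cholesky(K) @ rng.standard_normal(len(centers))
    return np.clip(ell, 0.1, None)


def _truth_z(cov_signal: np.ndarray, noise_sd: float) -> np.ndarray:
    total = cov_signal + noise_sd**2 * np.eye(cov_signal.shape[0])
    sd = np.sqrt(np.diag(total))
    corr = total / np.outer(sd, sd)
    iu = np.triu_indices(cov_signal.shape[0], k=1)
    return np.arctanh(corr[iu])


def _nearest_psd_corr(corr: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped nearest correlation matrix (diag renormalized)."""
    w, v = np.linalg.eigh(corr)
    fixed = (v * np.maximum(w, floor)) @ v.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def _simulate(cfg: SynthConfig, cov_by_subject: Iterable[np.ndarray], severities: np.ndarray) -> dict:
    kernel = _exp_kernel(cfg.tr)
    loadings = _artifact_loadings(cfg.roi_centers, cfg.seed)
    runs: dict = {}
    for i, cov in enumerate(cov_by_subject):
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(cfg.n_roi))
        sub = f"sub{i:03d}"
        for j in range(cfg.runs_per_subject):
            run = f"run{j}"
            motion = simulate_motion_trace(
                cfg, severities[i], seed=[cfg.seed, 15013, i, j]
            )
            rng = np.random.default_rng([cfg.seed, 22447, i, j])
            signal = chol @ rng.standard_normal((cfg.n_roi, cfg.T))
            noise = cfg.noise_sd * rng.standard_normal((cfg.n_roi, cfg.T))
            data = signal + noise
            if cfg.artifact_coupling != 0:
                fd = compute_fd(motion, "standard").values
                a = np.convolve(fd, kernel)[: cfg.T]
                a = a - np.median(a)
                data = data + cfg.artifact_coupling * np.outer(loadings, a)
            ts = RunTimeseries(
                data,
                tr=cfg.tr,
                nuisance={"GS": data.mean(axis=0)},
                subject_id=sub,
                run_id=run,
            )
            runs[(sub, run)] = SimRun(motion=motion, ts=ts)
    return runs


def _draw_severities(cfg: SynthConfig) -> np.ndarray:
    # gamma with mean 1 and CV 0.5: a broad but unimodal between-subject
    # motion spread, right-skewed like empirical mean-FD distributions
    rng = np.random.default_rng([cfg.seed, 31337])
    return cfg.motion_level * rng.gamma(shape=4.0, scale=0.25, size=cfg.n_subjects)


def simulate_dataset(cfg: SynthConfig) -> SyntheticDataset:
    """Full synthetic cohort.

    Per run, ROI series are multivariate Gaussian draws with covariance
    ``network_covariance`` plus white noise, with the motion-coupled
    artifact (FD convolved with a 6 s exponential kernel, scaled by
    spatially smooth per-ROI loadings) added when artifact_coupling != 0.
    ``ground_truth_z`` is the Fisher z of the artifact-free population
    correlation (network signal + noise floor).
    """
    severities = _draw_severities(cfg)
    cov = cfg.network_covariance + 0.0
    runs = _simulate(cfg, (cov for _ in range(cfg.n_subjects)), severities)
    return SyntheticDataset(
        cfg=cfg,
        subjects=[f"sub{i:03d}" for i in range(cfg.n_subjects)],
        runs=runs,
        ground_truth_z=_truth_z(cov, cfg.noise_sd),
        severities=severities,
        roi_set=ROISet(cfg.roi_centers),
    )


def simulate_confounded_cohort(
    cfg: SynthConfig,
    trait_effect: float,
    severity_factor: float = TRAIT_SEVERITY_FACTOR,
) -> SyntheticDataset:
    """Cohort with a latent binary 'third variable' confound.

    Half of subjects carry a trait that (a) multiplies their motion
    severity by ``severity_factor`` and (b) adds ``trait_effect`` to the
    true Fisher-z connectivity of every pair within the first half of
    the ROIs.  With artifact_coupling = 0 this produces motion-RSFC
    correlations across subjects with no motion artifact at all — the
    failure mode of SQM-based quality metrics.
    """
    if trait_effect < 0:
        raise InvalidConfigError("trait_effect must be >= 0")
    severities = _draw_severities(cfg)
    trait = np.arange(cfg.n_subjects) % 2 == 0
    severities = np.where(trait, severities * severity_factor, severities)

    # the trait shifts the *measurable* ground-truth z (i.e. including the
    # white-noise floor), so the induced group difference equals trait_effect
    base_cov = cfg.network_covariance + 0.0
    noise_var = cfg.noise_sd**2
    total = base_cov + noise_var * np.eye(cfg.n_roi)
    sd = np.sqrt(np.diag(total))
    total_corr = total / np.outer(sd, sd)
    n_affected = max(2, int(round(0.7 * cfg.n_roi)))
    z = np.arctanh(np.clip(total_corr, -1 + 1e-12, 1 - 1e-12))
    block = np.zeros_like(z, dtype=bool)
    block[:n_affected, :n_affected] = True
    np.fill_diagonal(block, False)
    z_carrier = np.where(block, z + trait_effect, z)
    carrier_total_corr = np.tanh(z_carrier)
    np.fill_diagonal(carrier_total_corr, 1.0)
    carrier_total_corr = _nearest_psd_corr(carrier_total_corr)
    carrier_cov = carrier_total_corr * np.outer(sd, sd) - noise_var * np.eye(cfg.n_roi)
    # keep the carrier signal covariance PSD after removing the noise floor
    w, v = np.linalg.eigh(carrier_cov)
    carrier_cov = (v * np.maximum(w, 1e-8)) @ v.T

    covs = [carrier_cov if trait[i] else base_cov for i in range(cfg.n_subjects)]
    runs = _simulate(cfg, covs, severities)
    truth_carrier = _truth_z(carrier_cov, cfg.noise_sd)
    truth_base = _truth_z(base_cov, cfg.noise_sd)
    n_carrier = int(trait.sum())
    truth_mean = (n_carrier * truth_carrier + (cfg.n_subjects - n_carrier) * truth_base) / cfg.n_subjects
    return SyntheticDataset(
        cfg=cfg,
        subjects=[f"sub{i:03d}" for i in range(cfg.n_subjects)],
        runs=runs,
        ground_truth_z=truth_mean,
        severities=severities,
        roi_set=ROISet(cfg.roi_centers),
        trait=trait,
        ground_truth_z_by_trait={True: truth_carrier, False: truth_base},
    )
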