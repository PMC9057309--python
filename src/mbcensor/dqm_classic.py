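"""Traditional dataset-quality metrics built on subject-level motion.

These are the QC-FC family and relatives: across-subject correlations
between a subject quality metric (mean or median FD) and each ROI
pair's connectivity, summarized as medians, FDR rejection rates,
distance correlations, two-step GLM coefficients, tercile contrasts,
and between-subject variance change.  They are provided for comparison:
all of them inherit any third-variable confound that couples motion to
true connectivity across subjects, which the confounded-cohort
generator reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .framewise import compute_fd


@dataclass
class SubjectQC:
    """Per-subject FD summaries over all analyzed volumes of all runs."""

    subjects: list
    mean_fd: np.ndarray
    median_fd: np.ndarray
    variant: str = "lpf"


def subject_fd_summary(runs: dict, variant: str = "lpf") -> SubjectQC:
    """Mean and median FD per subject, pooling frames 1..T-1 of every
    run (frame 0 carries the conventional 0, not a measurement)."""
    per_subject: dict = {}
    for (subject, _), sim in runs.items():
        fd = compute_fd(sim.motion, variant).values[1:]
        per_subject.setdefault(subject, []).append(fd)
    subjects = sorted(per_subject)
    pooled = [np.concatenate(per_subject[s]) for s in subjects]
    return SubjectQC(
        subjects=subjects,
        mean_fd=np.array([p.mean() for p in pooled]),
        median_fd=np.array([np.median(p) for p in pooled]),
        variant=variant,
    )


def qcfc(Z: np.ndarray, sqm: np.ndarray) -> np.ndarray:
    """Pearson correlation, across subjects, between each ROI pair's
    Fisher-z connectivity (rows of Z = subjects) and the subject quality
    metric."""
    Z = np.asarray(Z, float)
    sqm = np.asarray(sqm, float)
    if Z.shape[0] != sqm.size:
        raise ValueError("subject counts differ between Z and SQM")
    if Z.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if np.isclose(sqm.std(), 0):
        raise ValueError("SQM has zero variance")
    zc = Z - Z.mean(axis=0)
    qc = sqm - sqm.mean()
    denom = np.sqrt((zc**2).sum(axis=0) * (qc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, zc.T @ qc / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def qcfc_summaries(
    qcfc_r: np.ndarray,
    pair_distances: np.ndarray,
    n_subjects: int,
    alpha: float = 0.05,
) -> dict:
    """Median |QC-FC|, Benjamini-Hochberg null rejection rate at
    ``alpha``, and the Spearman correlation between QC-FC and ROI-pair
    distance (0 with a flag when QC-FC is degenerate)."""
    qcfc_r = np.asarray(qcfc_r, float)
    df = n_subjects - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = qcfc_r * np.sqrt(df / np.clip(1 - qcfc_r**2, 1e-300, None))
    pvals = 2 * stats.t.sf(np.abs(tstat), df)
    reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    degenerate = np.isclose(np.std(qcfc_r), 0)
    if degenerate:
        dist_corr = 0.0
    else:
        dist_corr = float(stats.spearmanr(qcfc_r, pair_distances).statistic)
    return {
        "median_abs_qcfc": float(np.median(np.abs(qcfc_r))),
        "null_rejection_rate": float(reject.mean()),
        "distance_corr": dist_corr,
        "distance_corr_degenerate": bool(degenerate),
    }


def highlow_rejection(
    Z: np.ndarray, median_fd: np.ndarray, alphas: np.ndarray | float = 0.05
) -> np.ndarray:
    """Fraction of ROI pairs whose connectivity differs (Welch's t,
    uncorrected p < alpha) between the upper and lower tercile of
    subject median FD; evaluated over an alpha grid."""
    Z = np.asarray(Z, float)
    median_fd = np.asarray(median_fd, float)
    n = median_fd.size
    if n < 6:
        raise ValueError("need at least 6 subjects for a tercile split")
    k = n // 3
    order = np.argsort(median_fd)
    low, high = order[:k], order[-k:]
    if k < 2:
        raise ValueError("tercile size < 2")
    res = stats.ttest_ind(Z[high], Z[low], axis=0, equal_var=False)
    pvals = np.nan_to_num(res.pvalue, nan=1.0)
    alphas_arr = np.atleast_1d(np.asarray(alphas, float))
    rates = np.array([(pvals < a).mean() for a in alphas_arr])
    return rates if np.ndim(alphas) else float(rates[0])


def glm_metrics(Z: np.ndarray, sqm: np.ndarray, pair_distances: np.ndarray) -> dict:
    """Two-step GLM summaries.

    Step 1 regresses each pair's z on the centered SQM (intercept = pair
    mean RSFC, slope = pair QC-FC effect); step 2 regresses the step-1
    intercepts and slopes on pair distance.
    """
    Z = np.asarray(Z, float)
    sqm = np.asarray(sqm, float)
    d = np.asarray(pair_distances, float)
    if np.isclose(sqm.std(), 0):
        raise ValueError("SQM has zero variance")
    x = sqm - sqm.mean()
    sxx = float(x @ x)
    slopes = Z.T @ x / sxx
    intercepts = Z.mean(axis=0)  # centered regressor: intercept is the pair mean
    rs_slope, rs_int = np.polyfit(d, intercepts, 1)
    qc_slope, qc_int = np.polyfit(d, slopes, 1)
    return {
        "mean_rsfc": float(rs_int),
        "rsfc_distance_slope": float(rs_slope),
        "mean_qcfc": float(qc_int),
        "qcfc_distance_slope": float(qc_slope),
    }


def variance_change(Z_censored: np.ndarray, Z_uncensored: np.ndarray) -> float:
    """Mean over pairs of the change in across-subject variance of z due
    to censoring.  Both tables must cover the same subjects."""
    Z_censored = np.asarray(Z_censored, float)
    Z_uncensored = np.asarray(Z_uncensored, float)
    if Z_censored.shape != Z_uncensored.shape:
        raise ValueError("subject sets under the two conditions must match")
    return float(
        np.mean(Z_censored.var(axis=0, ddof=1) - Z_uncensored.var(axis=0, ddof=1))
    )
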