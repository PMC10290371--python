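"""Reliability and method-comparison statistics.

Observer agreement is quantified with the intraclass correlation
coefficient.  The default model is ICC(2,1) — two-way random effects,
absolute agreement, single measures — the standard choice when each
subject is rated by the same set of observers who are themselves regarded
as a random sample of possible observers:

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

with MSR, MSC, MSE the subject, rater and residual mean squares of the
two-way ANOVA, n subjects and k raters.  ICC(3,1) (raters fixed) and the
average-measures form ICC(2,k) are available for sensitivity analysis.
Method comparison uses paired t-tests; no multiple-testing correction is
applied, and each parameter is reported with its own p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alignment import ANGLE_PARAMS, DISTANCE_PARAMS, AlignmentMeasurement

__all__ = ["ICCResult", "PairedTResult", "icc", "paired_t", "summarize_observers"]

_MODEL_LABELS = {
    "ICC2": "two-way random, absolute agreement, single measures",
    "ICC3": "two-way mixed, consistency, single measures",
    "ICC2k": "two-way random, absolute agreement, average measures",
}


@dataclass(frozen=True)
class ICCResult:
    icc: float
    model_label: str
    F: float
    p: float
    n_subjects: int
    n_raters: int

    def __post_init__(self) -> None:
        if self.icc > 1.0 + 1e-12:
            raise ValueError("ICC cannot exceed 1")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.n_subjects < 2 or self.n_raters < 2:
            raise ValueError("need at least 2 subjects and 2 raters")


def icc(ratings: np.ndarray, model: str = "ICC2") -> ICCResult:
    """Intraclass correlation of a complete subjects-by-raters matrix.

    Computed from the two-way ANOVA mean squares; the F test compares
    subject variance against residual variance.  A matrix with no variance
    at all leaves the ICC undefined and raises ``ValueError``; perfect
    agreement between raters (zero residual, non-zero subject variance)
    returns exactly 1.
    """
    if model not in _MODEL_LABELS:
        raise ValueError(f"model must be one of {sorted(_MODEL_LABELS)}")
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters matrix")
    if np.isnan(X).any():
        raise ValueError("ratings matrix must be complete (no missing cells)")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    grand = X.mean()
    if np.allclose(X, grand):
        raise ValueError("ratings have zero total variance; ICC undefined")

    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((X - grand) ** 2)
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    if model == "ICC2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif model == "ICC3":
        denom = msr + (k - 1) * mse
    else:  # ICC2k
        denom = msr + (msc - mse) / n
    if denom <= 0:
        raise ValueError("degenerate ratings matrix; ICC undefined")
    value = (msr - mse) / denom
    if mse == 0.0:  # perfect within-subject agreement (up to rater offsets)
        F = np.inf
        p = 0.0
    else:
        F = msr / mse
        p = float(sps.f.sf(F, n - 1, (n - 1) * (k - 1)))
    return ICCResult(
        icc=float(value),
        model_label=_MODEL_LABELS[model],
        F=float(F),
        p=float(p),
        n_subjects=n,
        n_raters=k,
    )


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    mean_difference: float
    degenerate: bool = False


def paired_t(a, b) -> PairedTResult:
    """Two-sided paired t-test of ``a`` against ``b``.

    Identical vectors return t = 0, p = 1 (no evidence of a difference,
    not an error).  A constant non-zero shift has zero difference variance
    and an unbounded statistic; it is returned as infinite t with
    ``degenerate=True`` rather than raising.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired_t requires two equal-length 1D arrays, n >= 2")
    d = a - b
    md = float(d.mean())
    if np.allclose(d, 0.0):
        return PairedTResult(t=0.0, p=1.0, mean_difference=0.0)
    if np.allclose(d, md):
        return PairedTResult(
            t=float(np.sign(md)) * np.inf, p=0.0, mean_difference=md, degenerate=True
        )
    t, p = sps.ttest_rel(a, b)
    return PairedTResult(t=float(t), p=float(p), mean_difference=md)


def summarize_observers(
    measurements: list[AlignmentMeasurement],
    parameters: tuple[str, ...] = ANGLE_PARAMS + DISTANCE_PARAMS,
    icc_model: str = "ICC2",
) -> pd.DataFrame:
    """Per-parameter observer agreement table.

    Groups measurements by ``observer_id`` (each observer must have rated
    the same patients), and reports per-observer mean and SD, the absolute
    difference of the observer means (Delta), and the inter-observer ICC
    with its p-value.  Shaped like a per-parameter reliability table.
    """
    by_obs: dict[str, dict] = {}
    for m in measurements:
        by_obs.setdefault(m.observer_id, {})[m.patient_id] = m
    observers = sorted(by_obs)
    if len(observers) < 2:
        raise ValueError("need measurements from at least two observers")
    subject_sets = [set(d) for d in by_obs.values()]
    if any(s != subject_sets[0] for s in subject_sets[1:]):
        raise ValueError("all observers must have measured the same patients")
    subjects = sorted(subject_sets[0])

    rows = []
    for param in parameters:
        mat = np.array(
            [[getattr(by_obs[o][s], param) for o in observers] for s in subjects]
        )
        means = mat.mean(axis=0)
        sds = mat.std(axis=0, ddof=1)
        row = {"parameter": param}
        for j, o in enumerate(observers):
            row[f"mean_{o}"] = means[j]
            row[f"sd_{o}"] = sds[j]
        row["delta"] = float(abs(means[0] - means[1]))
        try:
            r = icc(mat, model=icc_model)
            row["icc"], row["icc_p"] = r.icc, r.p
        except ValueError:  # zero-variance parameter
            row["icc"], row["icc_p"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")
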