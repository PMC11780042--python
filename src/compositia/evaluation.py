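"""Evaluation protocol: localization error summaries, Dice aggregation,
percentage relative error, linear regression (Pearson r, r²),
Bland–Altman limits of agreement, and the subject-level k-fold harness.

Conventions: standard deviations are population (divide by N); the
limits of agreement are bias ± 1.96 × sd of the paired differences;
the under-10-mm percentage uses a strict inequality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold

LOA_MULTIPLIER = 1.96
UNDER_MM_THRESHOLD = 10.0


@dataclass
class AgreementSummary:
    r: float
    p_value: float
    r2: float
    bias: float
    upper_loa: float
    lower_loa: float
    pre_mean: float
    pre_sd: float

    def __post_init__(self):
        if not -1.0 - 1e-9 <= self.r <= 1.0 + 1e-9:
            raise ValueError("r outside [-1, 1]")
        if not self.lower_loa - 1e-9 <= self.bias <= self.upper_loa + 1e-9:
            raise ValueError("bias outside the limits of agreement")
        if self.pre_mean < 0:
            raise ValueError("pre_mean must be non-negative")


def pre(pred: float, truth: float) -> float:
    """Percentage relative error |pred - truth| / |truth| × 100."""
    if truth == 0:
        raise ZeroDivisionError("PRE undefined for a zero ground-truth value")
    return abs(pred - truth) / abs(truth) * 100.0


def bland_altman(pred, truth) -> tuple[float, float, float]:
    """(bias, upper LOA, lower LOA) of pred - truth."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("series length mismatch")
    if pred.size < 2:
        raise ValueError("need at least two paired observations")
    diff = pred - truth
    bias = float(diff.mean())
    sd = float(diff.std(ddof=0))
    return bias, bias + LOA_MULTIPLIER * sd, bias - LOA_MULTIPLIER * sd


def regression_summary(pred, truth) -> AgreementSummary:
    """OLS of pred on truth with Pearson r/p, r², bias, LOA and PRE ± sd."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("series length mismatch")
    if pred.size < 3:
        raise ValueError("need at least three paired observations")
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        raise ValueError("regression undefined for a constant series")
    res = stats.linregress(truth, pred)
    bias, upper, lower = bland_altman(pred, truth)
    if np.any(truth == 0):
        raise ZeroDivisionError("PRE undefined for zero ground-truth values")
    pres = np.abs(pred - truth) / np.abs(truth) * 100.0
    return AgreementSummary(
        r=float(res.rvalue), p_value=float(res.pvalue), r2=float(res.rvalue ** 2),
        bias=bias, upper_loa=upper, lower_loa=lower,
        pre_mean=float(pres.mean()), pre_sd=float(pres.std(ddof=0)),
    )


def localization_summary(errors_mm) -> tuple[float, float, float]:
    """(MAE, sd, % of cases with error strictly under 10 mm)."""
    e = np.abs(np.asarray(errors_mm, dtype=float))
    if e.size == 0:
        raise ValueError("empty error series")
    pct = float((e < UNDER_MM_THRESHOLD).mean() * 100.0)
    return float(e.mean()), float(e.std(ddof=0)), pct


def kfold_split(subjects, k: int = 5, seed: int = 0):
    """Deterministic subject-level partition: list of (train_ids, test_ids)."""
    subjects = list(subjects)
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds the {len(subjects)} subjects")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    out = []
    for tr, te in kf.split(subjects):
        out.append(([subjects[i] for i in tr], [subjects[i] for i in te]))
    return out


def aggregate_folds(fold_values) -> tuple[float, float]:
    """mean ± population sd over per-fold metric values."""
    v = np.asarray(fold_values, dtype=float)
    return float(v.mean()), float(v.std(ddof=0))


def kfold_harness(subjects, evaluate_fold, k: int = 5, seed: int = 0):
    """Run `evaluate_fold(train_ids, test_ids)` on every fold.

    `evaluate_fold` returns a dict of metric name -> value; the harness
    returns ``(per_fold: list of dict, aggregate: dict of name -> (mean, sd))``.
    """
    per_fold = []
    for train_ids, test_ids in kfold_split(subjects, k=k, seed=seed):
        per_fold.append(dict(evaluate_fold(train_ids, test_ids)))
    keys = per_fold[0].keys()
    aggregate = {key: aggregate_folds([f[key] for f in per_fold]) for key in keys}
    return per_fold, aggregate
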