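"""Diagnostic accuracy, regression and group statistics.

The dextran assay is treated as the gold standard for death
(dextran-positive = dead, dextran-negative = viable) and RyR positivity
as a diagnostic *test for viability* (positive test = viable).  Hence

    TP = RyR+ and Dx-,  FN = RyR- and Dx-,
    TN = RyR- and Dx+,  FP = RyR+ and Dx+.

Also here: the ROC sweep over the RyR-fraction threshold, ordinary
least-squares regression of contraction force on living-cell fraction
(with the F-test against the intercept-only model), normal-approximation
summaries, and Welch / paired t-tests with Holm–Bonferroni correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .classify import CellRecord


@dataclass
class AccuracyReport:
    """Confusion counts and derived rates of the RyR viability test.

    Rates are ``None`` when their denominator is zero.
    """

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @staticmethod
    def _rate(num: int, den: int) -> Optional[float]:
        return num / den if den else None

    @property
    def sensitivity(self) -> Optional[float]:
        return self._rate(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return self._rate(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> Optional[float]:
        return self._rate(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Optional[float]:
        return self._rate(self.tn, self.tn + self.fn)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "n": self.n,
        }


@dataclass
class RegressionResult:
    """OLS fit of force (µN) on living fraction."""

    slope: Optional[float]
    intercept: Optional[float]
    r_squared: Optional[float]
    f_pvalue: Optional[float]
    n: int
    slope_se: Optional[float] = None
    slope_ci: Optional[Tuple[float, float]] = None
    degenerate: bool = False


@dataclass
class DistributionSummary:
    """Median, mean and normal-approximation 95% CI of one statistic."""

    median: float
    mean: float
    ci_low: float
    ci_high: float
    n: int
    small_sample: bool = False
    degenerate: bool = False


def accuracy_from_records(records: Sequence[CellRecord]) -> AccuracyReport:
    """Confusion matrix of RyR positivity against dextran truth."""
    tp = fn = tn = fp = 0
    for r in records:
        if r.dextran_positive:
            if r.ryr_positive:
                fp += 1
            else:
                tn += 1
        else:
            if r.ryr_positive:
                tp += 1
            else:
                fn += 1
    return AccuracyReport(tp=tp, fn=fn, tn=tn, fp=fp)


def roc_from_scores(
    f_ryr: np.ndarray, dextran_positive: np.ndarray, thetas: Iterable[float]
) -> pd.DataFrame:
    """ROC of the RyR-fraction threshold against fixed dextran truth.

    For each theta a cell tests positive (viable) when ``f_ryr >= theta``;
    TPR is the positive rate among dextran-negative (truly viable) cells,
    FPR among dextran-positive (dead) ones.
    """
    f = np.asarray(f_ryr, dtype=float)
    dead = np.asarray(dextran_positive, dtype=bool)
    thetas = np.asarray(list(thetas), dtype=float)
    if thetas.size == 0:
        raise ValueError("theta grid must be nonempty")
    n_pos = int((~dead).sum())
    n_neg = int(dead.sum())
    rows = []
    for th in thetas:
        test_pos = f >= th
        tpr = (test_pos & ~dead).sum() / n_pos if n_pos else np.nan
        fpr = (test_pos & dead).sum() / n_neg if n_neg else np.nan
        rows.append({"theta": th, "fpr": fpr, "tpr": tpr})
    return pd.DataFrame(rows)


def roc_sweep(
    labels,
    ryr_mask: np.ndarray,
    dextran_positive: np.ndarray,
    thetas: Iterable[float],
    r_ryr_px: int = 4,
) -> pd.DataFrame:
    """ROC computed from the label map and binary RyR image.

    ``dextran_positive`` gives, per cell id (index 0 unused or a length
    n_cells vector), the fixed dextran truth.  RyR fractions are
    recomputed from the dilated mask exactly as in classification.
    """
    from .classify import dilate_mask

    lab = labels.labels
    n = labels.n_cells
    dil = dilate_mask(ryr_mask, r_ryr_px)
    areas = np.bincount(lab.ravel(), minlength=n + 1).astype(float)
    counts = np.bincount(lab.ravel(), weights=dil.ravel().astype(float),
                         minlength=n + 1)
    with np.errstate(invalid="ignore"):
        f = counts[1:] / areas[1:]
    dead = np.asarray(dextran_positive, dtype=bool)
    if dead.size == n + 1:
        dead = dead[1:]
    return roc_from_scores(f, dead, thetas)


def roc_auc(roc: pd.DataFrame) -> float:
    """Area under a swept ROC curve (trapezoid over sorted FPR)."""
    pts = roc[["fpr", "tpr"]].dropna().to_numpy()
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    pts = np.vstack([[0.0, 0.0], pts, [1.0, 1.0]])
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def force_regression(
    living_fraction: Sequence[float], force_un: Sequence[float]
) -> RegressionResult:
    """OLS of contraction force on the fraction of living myocytes.

    Reports slope, intercept, R² and the F-test p-value against the
    intercept-only model.  Zero variance in the fractions leaves the
    slope undefined (``degenerate=True``).
    """
    x = np.asarray(living_fraction, dtype=float)
    y = np.asarray(force_un, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("living_fraction and force must be 1D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("living fractions must lie in [0, 1]")
    if np.ptp(x) == 0:
        return RegressionResult(None, None, None, None, n, degenerate=True)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        f_pvalue=float(res.f_pvalue),
        n=n,
        slope_se=float(res.bse[1]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
    )


def distribution_summary(values: Sequence[float]) -> DistributionSummary:
    """Median, mean and 95% CI (mean ± 1.96·SE, normal approximation).

    n = 1 yields a degenerate CI equal to the mean; n < 5 is flagged as a
    small sample.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    mean = float(v.mean())
    median = float(np.median(v))
    if v.size == 1:
        return DistributionSummary(median, mean, mean, mean, 1,
                                   small_sample=True, degenerate=True)
    se = float(v.std(ddof=1) / math.sqrt(v.size))
    return DistributionSummary(
        median, mean, mean - 1.96 * se, mean + 1.96 * se, int(v.size),
        small_sample=v.size < 5,
    )


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def group_tests(
    comparisons: Sequence[Tuple[str, Sequence[float], Sequence[float]]],
    paired: bool = False,
) -> pd.DataFrame:
    """t-tests for a family of two-group comparisons with Holm correction.

    Each comparison is ``(name, group_a, group_b)``.  Unpaired groups are
    compared with Welch's two-tailed t-test; ``paired=True`` uses the
    paired t-test (equal lengths required).  A paired comparison with
    identically zero differences has an undefined t statistic and is
    reported with ``p_raw = NaN`` (excluded from the Holm family).
    """
    rows = []
    for name, a, b in comparisons:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"comparison {name!r}: need n >= 2 per group")
        if paired:
            if a.size != b.size:
                raise ValueError(f"comparison {name!r}: paired groups differ in length")
            diff = a - b
            if np.all(diff == 0):
                stat, p = np.nan, np.nan
            else:
                stat, p = sps.ttest_rel(a, b)
        else:
            stat, p = sps.ttest_ind(a, b, equal_var=False)
        rows.append({"comparison": name, "t": float(stat) if stat == stat else np.nan,
                     "p_raw": float(p) if p == p else np.nan})
    frame = pd.DataFrame(rows)
    adjusted = np.full(len(frame), np.nan)
    defined = frame["p_raw"].notna().to_numpy()
    if defined.any():
        adjusted[defined] = holm_bonferroni(frame.loc[defined, "p_raw"].to_numpy())
    frame["p_adjusted"] = adjusted
    return frame
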