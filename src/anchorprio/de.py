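"""Standardization against the control mean and shrinkage-t differential
expression for the case/control study.

The variance-shrinkage t statistic follows the median-target form: each
gene's pooled empirical variance v_g is shrunk toward the median gene
variance v_median with an analytically estimated intensity

    lambda* = min(1, sum_g Var^(v_g) / sum_g (v_g - v_median)^2)
    v*_g    = lambda* v_median + (1 - lambda*) v_g
    t*_g    = mean_diff_g / sqrt(v*_g (1/n_case + 1/n_ctrl))

where Var^(v_g) is the standard unbiased variance-of-variance estimate
built from centered squared deviations.  Two-sided p-values use the
Student t reference with n_case + n_ctrl - 2 degrees of freedom
(one-sided available via ``alternative``).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import CASE, CONTROL, ExpressionStudy

logger = logging.getLogger(__name__)

DE_COLUMNS = ["gene", "mean_diff", "v_g", "v_star", "t_star", "p"]


@dataclass
class LogRatioMatrix:
    """Per-sample log2 ratios versus the per-gene control mean."""

    values: pd.DataFrame              # genes x samples
    sample_groups: Dict[str, str]

    @property
    def controls(self):
        return [s for s in self.values.columns if self.sample_groups[s] == CONTROL]

    @property
    def cases(self):
        return [s for s in self.values.columns if self.sample_groups[s] == CASE]


def standardize(study: ExpressionStudy) -> LogRatioMatrix:
    """Subtract each gene's overall control mean from every sample.

    Control samples therefore average exactly zero per gene when their
    values are complete.  Genes missing in all controls have no
    reference and are dropped with a warning.
    """
    controls = study.controls
    if len(controls) < 2:
        raise ValueError("standardization needs at least 2 control samples")
    ctrl_mean = study.values[controls].mean(axis=1, skipna=True)
    no_ref = ctrl_mean.isna()
    if no_ref.any():
        logger.warning("standardize: dropping %d gene(s) missing in all controls",
                       int(no_ref.sum()))
    values = study.values.loc[~no_ref].sub(ctrl_mean[~no_ref], axis=0)
    return LogRatioMatrix(values, dict(study.sample_groups))


def _unbiased_var_of_var(x: np.ndarray) -> np.ndarray:
    """Unbiased estimate of Var(s^2) per row from centered squared
    deviations: n/(n-1)^3 * sum_k (w_k - w_bar)^2 with w_k = (x_k - x_bar)^2."""
    n = x.shape[1]
    w = (x - x.mean(axis=1, keepdims=True)) ** 2
    wc = w - w.mean(axis=1, keepdims=True)
    return n / (n - 1) ** 3 * (wc ** 2).sum(axis=1)


class ShrinkageTTest(BaseEstimator):
    """Scikit-learn style estimator for the shrinkage t-test.

    Parameters
    ----------
    alternative : {"two-sided", "less", "greater"}
        Sidedness of the p-value (two-sided by default).

    Attributes (after :meth:`fit`)
    ------------------------------
    genes_ : ndarray of feature names
    mean_diff_, v_, v_star_, t_star_, p_value_ : per-gene arrays
    lambda_star_ : float in [0, 1], estimated shrinkage intensity
    v_median_ : float, the shrinkage target
    results_ : DataFrame with columns gene, mean_diff, v_g, v_star, t_star, p
    """

    def __init__(self, alternative: str = "two-sided"):
        self.alternative = alternative

    def fit(self, X, y):
        """Fit on ``X`` of shape (n_samples, n_genes) and binary labels
        ``y`` (1/"case" = case, 0/"control" = control)."""
        if isinstance(X, pd.DataFrame):
            genes = np.asarray(X.columns)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            genes = np.arange(values.shape[1])
        y = np.asarray([1 if lab in (1, CASE, True) else 0 for lab in y])
        if values.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the number of samples")
        case, ctrl = values[y == 1], values[y == 0]
        n1, n0 = case.shape[0], ctrl.shape[0]
        if n1 < 2 or n0 < 2:
            raise ValueError("both groups need at least 2 samples")
        df = n1 + n0 - 2

        v_case = case.var(axis=0, ddof=1)
        v_ctrl = ctrl.var(axis=0, ddof=1)
        v_g = ((n1 - 1) * v_case + (n0 - 1) * v_ctrl) / df
        c1, c0 = (n1 - 1) / df, (n0 - 1) / df
        var_of_v = (c1 ** 2 * _unbiased_var_of_var(case.T)
                    + c0 ** 2 * _unbiased_var_of_var(ctrl.T))

        v_median = float(np.median(v_g))
        denom = float(((v_g - v_median) ** 2).sum())
        lam = 1.0 if denom == 0.0 else min(1.0, float(var_of_v.sum()) / denom)
        v_star = lam * v_median + (1.0 - lam) * v_g

        mean_diff = case.mean(axis=0) - ctrl.mean(axis=0)
        scale = np.sqrt(v_star * (1.0 / n1 + 1.0 / n0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_star = np.where(scale > 0, mean_diff / scale, 0.0)
        if self.alternative == "two-sided":
            p = 2.0 * stats.t.sf(np.abs(t_star), df)
        elif self.alternative == "greater":
            p = stats.t.sf(t_star, df)
        elif self.alternative == "less":
            p = stats.t.cdf(t_star, df)
        else:
            raise ValueError(f"unknown alternative {self.alternative!r}")
        p = np.minimum(p, 1.0)

        self.genes_ = genes
        self.mean_diff_ = mean_diff
        self.v_ = v_g
        self.v_star_ = v_star
        self.t_star_ = t_star
        self.p_value_ = p
        self.lambda_star_ = lam
        self.v_median_ = v_median
        self.df_ = df
        self.results_ = pd.DataFrame({
            "gene": genes, "mean_diff": mean_diff, "v_g": v_g,
            "v_star": v_star, "t_star": t_star, "p": p,
        })
        return self


def shrinkage_t(ratios: LogRatioMatrix, alternative: str = "two-sided"
                ) -> ShrinkageTTest:
    """Run the shrinkage t-test on a standardized log-ratio matrix."""
    X = ratios.values.T
    y = [ratios.sample_groups[s] for s in ratios.values.columns]
    return ShrinkageTTest(alternative=alternative).fit(X, y)


def select_heart_candidates(result: ShrinkageTTest, alpha: float = 0.1) -> set:
    """Genes with p strictly below ``alpha``."""
    return set(np.asarray(result.genes_)[result.p_value_ < alpha])
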