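"""Conjugate normal-normal posterior per gene and the Typified Bayes
Value (TBV) decision rule.

For a gene with prior θ ~ N(θ0, σ0²) and case log2-ratio data summarized
by (x̄, σ, n) with known-variance normal likelihood, the posterior is
N(θ1, σ1²) in precision form:

    1/σ1² = 1/σ0² + n/σ²
    θ1    = σ1² (θ0/σ0² + n x̄/σ²)

The prioritization statistic is TBV = θ1/σ1; a gene is called
significant when |TBV| > 2.58, the two-sided 99% standard-normal
critical value as conventionally rounded (the exact quantile 2.5758 is
available and the genes that flip between the two cuts are surfaced in
the run report).  No multiplicity adjustment is applied — the fixed cut
is the procedure.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .de import LogRatioMatrix

TBV_THRESHOLD = 2.58
POSTERIOR_COLUMNS = ["gene", "theta0", "sigma0", "xbar", "sigma", "n",
                     "theta1", "sigma1", "tbv", "significant"]


def case_likelihoods(ratios: LogRatioMatrix, include_controls: bool = False
                     ) -> pd.DataFrame:
    """Per-gene likelihood summaries (x̄, σ, n) from the log-ratio matrix.

    By default only case samples contribute (each case compared against
    the control mean); ``include_controls`` widens the summary to all
    samples.  Genes with zero spread or fewer than two contributing
    samples are dropped.
    """
    cols = ratios.values.columns if include_controls else ratios.cases
    sub = ratios.values[list(cols)]
    n = sub.notna().sum(axis=1)
    xbar = sub.mean(axis=1)
    sigma = sub.std(axis=1, ddof=1)
    out = pd.DataFrame({"gene": sub.index, "xbar": xbar.values,
                        "sigma": sigma.values, "n": n.values})
    return out[(out["n"] >= 2) & (out["sigma"] > 0)].reset_index(drop=True)


def posterior_update(priors: pd.DataFrame, likelihoods: pd.DataFrame,
                     threshold: float = TBV_THRESHOLD
                     ) -> Tuple[pd.DataFrame, Set[str], Set[str]]:
    """Closed-form conjugate update for every gene present in both inputs.

    Returns (posterior table, genes with data but no prior, genes with a
    prior but no data).  Genes in only one input receive no TBV call.
    """
    merged = priors.merge(likelihoods, on="gene", how="inner")
    no_prior = set(likelihoods["gene"]) - set(priors["gene"])
    no_data = set(priors["gene"]) - set(likelihoods["gene"])
    if (merged["sigma0"] <= 0).any():
        raise ValueError("non-positive prior sigma0")
    if (merged["sigma"] <= 0).any():
        raise ValueError("non-positive likelihood sigma")

    prior_prec = 1.0 / merged["sigma0"] ** 2
    data_prec = merged["n"] / merged["sigma"] ** 2
    sigma1 = np.sqrt(1.0 / (prior_prec + data_prec))
    theta1 = sigma1 ** 2 * (merged["theta0"] * prior_prec
                            + merged["n"] * merged["xbar"] / merged["sigma"] ** 2)
    tbv = theta1 / sigma1
    out = pd.DataFrame({
        "gene": merged["gene"], "theta0": merged["theta0"],
        "sigma0": merged["sigma0"], "xbar": merged["xbar"],
        "sigma": merged["sigma"], "n": merged["n"],
        "theta1": theta1, "sigma1": sigma1, "tbv": tbv,
        "significant": np.abs(tbv) > threshold,
    })
    return (out.sort_values("gene", kind="mergesort").reset_index(drop=True),
            no_prior, no_data)


@dataclass
class TbvDecision:
    all_significant: Set[str]
    non_hsa21: Set[str]
    hsa21: Set[str]


def tbv_decision(posteriors: pd.DataFrame, chromosomes: Mapping[str, str],
                 threshold: float = TBV_THRESHOLD,
                 hsa21_label: str = "HSA21") -> TbvDecision:
    """Split the strictly-|TBV|-above-threshold genes by chromosome."""
    sig = set(posteriors.loc[np.abs(posteriors["tbv"]) > threshold, "gene"])
    on21 = {g for g in sig if chromosomes.get(g) == hsa21_label}
    return TbvDecision(sig, sig - on21, on21)


def threshold_sensitivity(posteriors: pd.DataFrame,
                          rounded: float = TBV_THRESHOLD,
                          exact: Optional[float] = None) -> Dict[str, object]:
    """Report how many calls flip between the rounded 2.58 cut and the
    exact 99% two-sided normal quantile."""
    from scipy import stats
    if exact is None:
        exact = float(stats.norm.ppf(0.995))
    abs_tbv = np.abs(posteriors["tbv"])
    n_rounded = int((abs_tbv > rounded).sum())
    n_exact = int((abs_tbv > exact).sum())
    flipped = posteriors.loc[(abs_tbv > exact) & (abs_tbv <= rounded), "gene"]
    return {"threshold_rounded": rounded, "threshold_exact": exact,
            "n_significant_rounded": n_rounded, "n_significant_exact": n_exact,
            "n_flipped": n_exact - n_rounded, "flipped_genes": sorted(flipped)}


class TbvPrioritizer(BaseEstimator):
    """Estimator facade over the conjugate update.

    ``fit(priors, likelihoods)`` stores ``posterior_``, ``no_prior_``
    and ``no_data_``; ``predict(genes)`` returns the significance calls.
    """

    def __init__(self, threshold: float = TBV_THRESHOLD):
        self.threshold = threshold

    def fit(self, priors: pd.DataFrame, likelihoods: pd.DataFrame):
        post, no_prior, no_data = posterior_update(priors, likelihoods,
                                                   self.threshold)
        self.posterior_ = post
        self.no_prior_ = no_prior
        self.no_data_ = no_data
        return self

    def predict(self, genes) -> np.ndarray:
        calls = dict(zip(self.posterior_["gene"], self.posterior_["significant"]))
        return np.asarray([bool(calls.get(g, False)) for g in genes])
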