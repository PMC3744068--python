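"""Per-gene normal priors and meta-analysis candidate scores.

The prior for a gene's true log2 effect θ is N(θ0, σ0²) where θ0 is the
mean of its per-study log2-ratio means and σ0 the sample standard
deviation of those means, using only studies in which the transcript's
presence p-value clears the detection filter (< 0.1 by default).

The meta-analysis candidate score is a documented surrogate — a Stouffer
combination |Σ_s z_s| / sqrt(S) with z_s = log2fc_mean / se over the
qualifying studies — since the original scoring scheme belongs to an
earlier study and is out of scope; precomputed scores may be supplied
instead, and the cutoff (3.4 by default, inclusive) is configurable.
"""
from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .io import StudyEffectTable

logger = logging.getLogger(__name__)

PRIOR_COLUMNS = ["gene", "theta0", "sigma0", "n_studies_used"]
SCORE_COLUMNS = ["gene", "score", "n_studies_used", "is_candidate"]


def build_priors(table: StudyEffectTable, presence_alpha: float = 0.1
                 ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate (θ0, σ0) per gene from the study-level effect table.

    Only studies with ``presence_p < presence_alpha`` contribute.  Genes
    with fewer than two qualifying studies, or with zero variance across
    them (infinite prior precision), are excluded and itemized in the
    second returned frame with a reason.

    Returns
    -------
    priors : DataFrame with columns gene, theta0, sigma0, n_studies_used
    excluded : DataFrame with columns gene, reason, n_studies_used
    """
    df = table.data
    qual = df[df["presence_p"] < presence_alpha]
    grouped = qual.groupby("gene")["log2fc_mean"]
    stats = grouped.agg(theta0="mean", sigma0=lambda x: x.std(ddof=1), n="count")

    all_genes = pd.Index(table.genes, name="gene")
    stats = stats.reindex(all_genes)
    stats["n"] = stats["n"].fillna(0).astype(int)

    too_few = stats["n"] < 2
    degenerate = (~too_few) & (stats["sigma0"] == 0.0)
    excluded = pd.concat([
        pd.DataFrame({"gene": stats.index[too_few],
                      "reason": "fewer_than_two_studies",
                      "n_studies_used": stats.loc[too_few, "n"].values}),
        pd.DataFrame({"gene": stats.index[degenerate],
                      "reason": "zero_variance_across_studies",
                      "n_studies_used": stats.loc[degenerate, "n"].values}),
    ], ignore_index=True).sort_values("gene", kind="mergesort").reset_index(drop=True)

    keep = ~(too_few | degenerate)
    priors = pd.DataFrame({
        "gene": stats.index[keep],
        "theta0": stats.loc[keep, "theta0"].values,
        "sigma0": stats.loc[keep, "sigma0"].values,
        "n_studies_used": stats.loc[keep, "n"].values,
    }).reset_index(drop=True)
    if len(excluded):
        logger.info("build_priors: excluded %d gene(s) (%d with <2 studies, "
                    "%d degenerate)", len(excluded), int(too_few.sum()),
                    int(degenerate.sum()))
    return priors, excluded


def surrogate_meta_score(table: StudyEffectTable, presence_alpha: float = 0.1,
                         cutoff: float = 3.4,
                         precomputed: Optional[pd.DataFrame] = None
                         ) -> pd.DataFrame:
    """Stouffer-combined surrogate meta score with inclusive cutoff.

    Per gene, over studies passing the presence filter and with se > 0
    (zero-se studies are skipped with a warning):

        score = | sum_s z_s | / sqrt(S),   z_s = log2fc_mean_s / se_s

    If ``precomputed`` is given (columns gene, score) it bypasses the
    surrogate entirely; candidacy is still called at ``score >= cutoff``.
    """
    if precomputed is not None:
        out = precomputed[["gene", "score"]].copy()
        out["n_studies_used"] = np.nan
        out["is_candidate"] = out["score"] >= cutoff
        return out.sort_values("gene", kind="mergesort").reset_index(drop=True)

    df = table.data
    qual = df[df["presence_p"] < presence_alpha].copy()
    zero_se = qual["se"] == 0.0
    if zero_se.any():
        logger.warning("surrogate_meta_score: skipping %d study entries with "
                       "zero standard error", int(zero_se.sum()))
        qual = qual[~zero_se]
    qual["z"] = qual["log2fc_mean"] / qual["se"]
    agg = qual.groupby("gene")["z"].agg(zsum="sum", n="count")
    agg["score"] = np.abs(agg["zsum"]) / np.sqrt(agg["n"])

    all_genes = pd.Index(table.genes, name="gene")
    agg = agg.reindex(all_genes)
    out = pd.DataFrame({
        "gene": all_genes,
        "score": agg["score"].values,
        "n_studies_used": agg["n"].fillna(0).astype(int).values,
    })
    out["is_candidate"] = out["score"] >= cutoff
    out["is_candidate"] = out["is_candidate"].fillna(False)
    return out.reset_index(drop=True)


def signed_meta_metric(table: StudyEffectTable, presence_alpha: float = 0.1
                       ) -> pd.Series:
    """Signed Stouffer combination sum(z)/sqrt(S) per gene — the default
    ranking metric for preranked enrichment on the meta study."""
    df = table.data
    qual = df[(df["presence_p"] < presence_alpha) & (df["se"] > 0)].copy()
    qual["z"] = qual["log2fc_mean"] / qual["se"]
    agg = qual.groupby("gene")["z"].agg(zsum="sum", n="count")
    return (agg["zsum"] / np.sqrt(agg["n"])).rename("meta_metric")
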