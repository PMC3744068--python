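"""Iterative Signature Algorithm (ISA) biclustering and the anchor-gene
module filters.

ISA alternates between two standardized views of the expression matrix:
E_G (every gene row centered/scaled across samples) and E_C (every
sample column centered/scaled across genes).  From a seed gene set it
computes sample scores (mean of E_C over the current genes), keeps
samples whose score exceeds T_C standard deviations of the score vector,
then computes gene scores (mean of E_G over the kept samples) and keeps
genes above T_G standard deviations, iterating to a fixed point.  Runs
are repeated from many random seed sets over a threshold grid, near-
identical modules are deduplicated, and modules containing the anchor
gene with more than ``min_samples`` samples are merged when they share
more than 80% of their genes (share = |intersection| / min(|A|, |B|)).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (2.0, 2.2, 2.4, 2.5)


@dataclass
class IsaParams:
    gene_thresholds: Sequence[float] = DEFAULT_THRESHOLDS
    sample_thresholds: Sequence[float] = DEFAULT_THRESHOLDS
    n_seeds: int = 100
    seed_size: int = 10
    max_iter: int = 100
    convergence_corr: float = 0.999
    detection_alpha: float = 0.1
    detection_fraction: float = 0.5
    dedup_jaccard: float = 0.9
    rng_seed: int = 0

    def validate(self) -> None:
        if any(t <= 0 for t in list(self.gene_thresholds) + list(self.sample_thresholds)):
            raise ValueError("thresholds must be positive")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")


@dataclass
class IsaModule:
    """One converged bicluster: genes and samples with their scores, the
    thresholds that produced it and a seed-recovery robustness count."""

    gene_scores: Dict[str, float]
    sample_scores: Dict[str, float]
    gene_threshold: float
    sample_threshold: float
    robustness: int = 1

    @property
    def genes(self) -> set:
        return set(self.gene_scores)

    @property
    def samples(self) -> set:
        return set(self.sample_scores)


def normalize_two_ways(matrix: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-standardized (E_G) and sample-standardized (E_C) copies.

    Rows/columns with zero variance cannot be standardized and are
    dropped (from both outputs) with a warning.  Standardization uses
    the n-1 sample standard deviation.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("matrix must have at least 2 rows and 2 columns")
    row_sd = matrix.std(axis=1, ddof=1)
    col_sd = matrix.std(axis=0, ddof=1)
    bad_rows, bad_cols = row_sd == 0, col_sd == 0
    if bad_rows.any():
        logger.warning("normalize_two_ways: dropping %d zero-variance row(s)",
                       int(bad_rows.sum()))
    if bad_cols.any():
        logger.warning("normalize_two_ways: dropping %d zero-variance column(s)",
                       int(bad_cols.sum()))
    m = matrix.loc[~bad_rows, ~bad_cols]
    e_g = m.sub(m.mean(axis=1), axis=0).div(m.std(axis=1, ddof=1), axis=0)
    e_c = m.sub(m.mean(axis=0), axis=1).div(m.std(axis=0, ddof=1), axis=1)
    return e_g, e_c


def isa_iterate(e_g: pd.DataFrame, e_c: pd.DataFrame, seed_genes,
                gene_threshold: float, sample_threshold: float,
                max_iter: int = 100, convergence_corr: float = 0.999
                ) -> Optional[IsaModule]:
    """Iterate the ISA update from one seed gene set.

    Returns the converged module, or None when the run empties out or
    fails to converge within ``max_iter`` iterations (score-correlation
    > ``convergence_corr`` between consecutive iterations counts as
    converged, to absorb slow oscillations).
    """
    genes = np.asarray(e_g.index)
    samples = np.asarray(e_g.columns)
    eg = e_g.to_numpy(dtype=float)
    ec = e_c.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(genes)}

    gene_mask = np.zeros(len(genes), dtype=bool)
    for g in seed_genes:
        if g in gene_pos:
            gene_mask[gene_pos[g]] = True
    if not gene_mask.any():
        raise ValueError("seed gene set is empty or disjoint from the matrix")

    prev_scores = None
    for _ in range(max_iter):
        sample_scores = ec[gene_mask].mean(axis=0)
        s_cut = sample_threshold * sample_scores.std()
        sample_mask = sample_scores > s_cut
        if not sample_mask.any():
            return None
        gene_scores = eg[:, sample_mask].mean(axis=1)
        g_cut = gene_threshold * gene_scores.std()
        new_mask = gene_scores > g_cut
        if not new_mask.any():
            return None
        if np.array_equal(new_mask, gene_mask):
            gene_mask = new_mask
            break
        if prev_scores is not None:
            corr = np.corrcoef(gene_scores, prev_scores)[0, 1]
            if np.isfinite(corr) and corr > convergence_corr:
                gene_mask = new_mask
                break
        prev_scores = gene_scores
        gene_mask = new_mask
    else:
        logger.warning("isa_iterate: no convergence within %d iterations; "
                       "discarding run", max_iter)
        return None

    sample_scores = ec[gene_mask].mean(axis=0)
    sample_mask = sample_scores > sample_threshold * sample_scores.std()
    if not sample_mask.any():
        return None
    gene_scores = eg[:, sample_mask].mean(axis=1)
    return IsaModule(
        gene_scores={g: float(s) for g, s in zip(genes[gene_mask],
                                                 gene_scores[gene_mask])},
        sample_scores={s: float(v) for s, v in zip(samples[sample_mask],
                                                   sample_scores[sample_mask])},
        gene_threshold=gene_threshold,
        sample_threshold=sample_threshold,
    )


def _jaccard(a: set, b: set) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def run_isa(matrix: pd.DataFrame, params: IsaParams,
            detection_p: Optional[pd.DataFrame] = None) -> List[IsaModule]:
    """Full ISA sweep: detection filter, random seeds over the threshold
    grid, and Jaccard deduplication (keeping the more robust module)."""
    params.validate()
    if detection_p is not None:
        frac = (detection_p < params.detection_alpha).mean(axis=1)
        keep = frac.reindex(matrix.index).fillna(0) >= params.detection_fraction
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("run_isa: detection filter removed %d gene(s)", n_drop)
        matrix = matrix.loc[keep]
    e_g, e_c = normalize_two_ways(matrix)
    genes = np.asarray(e_g.index)
    rng = np.random.default_rng(params.rng_seed)

    modules: List[IsaModule] = []
    for t_g, t_c in product(params.gene_thresholds, params.sample_thresholds):
        for _ in range(params.n_seeds):
            seed = rng.choice(genes, size=min(params.seed_size, len(genes)),
                              replace=False)
            mod = isa_iterate(e_g, e_c, seed, t_g, t_c,
                              max_iter=params.max_iter,
                              convergence_corr=params.convergence_corr)
            if mod is None:
                continue
            for existing in modules:
                if _jaccard(existing.genes, mod.genes) > params.dedup_jaccard:
                    existing.robustness += 1
                    break
            else:
                modules.append(mod)
    modules.sort(key=lambda m: (-m.robustness, sorted(m.genes)))
    return modules


def anchor_filter_merge(modules: List[IsaModule], anchor: str,
                        min_samples: int = 5, merge_share: float = 0.8
                        ) -> List[IsaModule]:
    """Keep anchor-containing modules spanning more than ``min_samples``
    samples (strict), then merge any pair sharing more than
    ``merge_share`` of their genes — share = |A∩B| / min(|A|,|B|) — into
    their union, repeating to closure."""
    kept = [m for m in modules
            if anchor in m.genes and len(m.samples) > min_samples]
    if not kept:
        logger.warning("anchor_filter_merge: no module contains %r with more "
                       "than %d samples", anchor, min_samples)
        return []
    merged = True
    while merged:
        merged = False
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                a, b = kept[i], kept[j]
                share = len(a.genes & b.genes) / min(len(a.genes), len(b.genes))
                if share > merge_share:
                    union = IsaModule(
                        gene_scores={**b.gene_scores, **a.gene_scores},
                        sample_scores={**b.sample_scores, **a.sample_scores},
                        gene_threshold=min(a.gene_threshold, b.gene_threshold),
                        sample_threshold=min(a.sample_threshold, b.sample_threshold),
                        robustness=a.robustness + b.robustness,
                    )
                    kept = [m for k, m in enumerate(kept) if k not in (i, j)]
                    kept.append(union)
                    merged = True
                    break
            if merged:
                break
    return kept


def modules_to_frames(modules: List[IsaModule]) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format (gene, score, module) and (sample, score, module) tables."""
    gene_rows, sample_rows = [], []
    for i, m in enumerate(modules):
        for g in sorted(m.gene_scores):
            gene_rows.append({"module": i, "gene": g, "score": m.gene_scores[g],
                              "gene_threshold": m.gene_threshold,
                              "sample_threshold": m.sample_threshold,
                              "robustness": m.robustness})
        for s in sorted(m.sample_scores):
            sample_rows.append({"module": i, "sample": s,
                                "score": m.sample_scores[s]})
    return (pd.DataFrame(gene_rows, columns=["module", "gene", "score",
                                             "gene_threshold", "sample_threshold",
                                             "robustness"]),
            pd.DataFrame(sample_rows, columns=["module", "sample", "score"]))


class IterativeSignature(BaseEstimator):
    """Scikit-learn style wrapper around the ISA sweep.

    ``fit(X)`` expects samples in rows and genes in columns (sklearn
    orientation); fitted attributes follow the biclustering convention:

    rows_ : bool array (n_biclusters, n_samples)
    columns_ : bool array (n_biclusters, n_features)
    modules_ : list of :class:`IsaModule`
    """

    def __init__(self, gene_thresholds=DEFAULT_THRESHOLDS,
                 sample_thresholds=DEFAULT_THRESHOLDS, n_seeds: int = 100,
                 seed_size: int = 10, max_iter: int = 100,
                 random_state: int = 0):
        self.gene_thresholds = gene_thresholds
        self.sample_thresholds = sample_thresholds
        self.n_seeds = n_seeds
        self.seed_size = seed_size
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            matrix = X.T
        else:
            X = np.asarray(X, dtype=float)
            matrix = pd.DataFrame(
                X.T, index=[f"f{i}" for i in range(X.shape[1])],
                columns=[f"s{i}" for i in range(X.shape[0])])
        params = IsaParams(gene_thresholds=tuple(self.gene_thresholds),
                           sample_thresholds=tuple(self.sample_thresholds),
                           n_seeds=self.n_seeds, seed_size=self.seed_size,
                           max_iter=self.max_iter, rng_seed=self.random_state)
        self.modules_ = run_isa(matrix, params)
        samples = list(matrix.columns)
        features = list(matrix.index)
        self.rows_ = np.array([[s in m.samples for s in samples]
                               for m in self.modules_], dtype=bool)
        self.columns_ = np.array([[f in m.genes for f in features]
                                  for m in self.modules_], dtype=bool)
        return self
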