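"""Preranked gene-set enrichment analysis.

The enrichment score (ES) is the signed maximum deviation of a weighted
Kolmogorov-Smirnov running sum over the ranked list: genes in the set
("hits") increment the sum by |metric|^weight normalized over the set's
hits, genes outside it decrement by 1/(N - N_hits).  Significance comes
from a gene-label permutation null per set size; the normalized score
NES divides ES by the mean |null ES| of the same sign, and FDR q-values
follow the NES-based pooled-null procedure.  All randomness is driven by
an explicit seed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Set, Tuple

import numpy as np
import pandas as pd

from .io import GeneSetCollection

GSEA_COLUMNS = ["set", "size", "es", "nes", "p_perm", "fdr_q", "leading_edge"]


@dataclass
class RankedList:
    """Genes ordered by a real-valued metric, descending, ties broken by
    gene id so the order is deterministic."""

    genes: np.ndarray
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


def rank_genes(metric: pd.Series) -> RankedList:
    """Build a :class:`RankedList` from a gene-indexed metric series.

    NaN metrics are dropped; ordering is by metric descending, then gene
    id ascending for ties.
    """
    s = metric.dropna()
    if s.index.duplicated().any():
        raise ValueError("metric series has duplicate gene ids")
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return RankedList(np.asarray(order, dtype=object),
                      s.loc[order].to_numpy(dtype=float))


def _running_sum(weights_abs: np.ndarray, hit_mask: np.ndarray,
                 weight: float) -> np.ndarray:
    """KS running sum for one hit mask over the sorted metric."""
    n = weights_abs.shape[0]
    k = int(hit_mask.sum())
    hit_w = np.where(hit_mask, weights_abs ** weight, 0.0)
    total = hit_w.sum()
    if total == 0.0:                     # all-zero metrics inside the set
        hit_w = hit_mask.astype(float)
        total = hit_w.sum()
    steps = hit_w / total
    if k < n:
        steps = steps - (~hit_mask) / (n - k)
    return np.cumsum(steps)


def enrichment_score(ranked: RankedList, gene_set: Set[str],
                     weight: float = 1.0
                     ) -> Tuple[float, np.ndarray, List[str]]:
    """ES, the running sum, and the leading-edge genes of one set.

    Raises if the set is disjoint from the ranked list.
    """
    hit_mask = np.asarray([g in gene_set for g in ranked.genes])
    if not hit_mask.any():
        raise ValueError("gene set is disjoint from the ranked list")
    running = _running_sum(np.abs(ranked.metric), hit_mask, weight)
    i_max = int(np.argmax(np.abs(running)))
    es = float(running[i_max])
    if es >= 0:
        leading = [g for g, h in zip(ranked.genes[: i_max + 1], hit_mask[: i_max + 1]) if h]
    else:
        leading = [g for g, h in zip(ranked.genes[i_max:], hit_mask[i_max:]) if h]
    return es, running, leading


def _null_es(metric_abs: np.ndarray, k: int, n_perm: int, weight: float,
             rng: np.random.Generator) -> np.ndarray:
    """Vectorized null ES for random size-k gene sets."""
    n = metric_abs.shape[0]
    if k >= n:
        return np.ones(n_perm)
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    hits = np.zeros((n_perm, n), dtype=bool)
    hits[np.arange(n_perm)[:, None], idx] = True
    w = np.where(hits, metric_abs[None, :] ** weight, 0.0)
    totals = w.sum(axis=1, keepdims=True)
    degenerate = totals[:, 0] == 0.0
    if degenerate.any():
        w[degenerate] = hits[degenerate].astype(float)
        totals[degenerate] = k
    steps = w / totals - (~hits) / (n - k)
    cs = np.cumsum(steps, axis=1)
    pos, neg = cs.max(axis=1), cs.min(axis=1)
    return np.where(pos >= -neg, pos, neg)


def _normalize(es: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Divide each ES by the mean |null ES| of its own sign."""
    pos = null[null > 0]
    neg = null[null < 0]
    mean_pos = pos.mean() if pos.size else np.abs(null).mean() or 1.0
    mean_neg = -neg.mean() if neg.size else np.abs(null).mean() or 1.0
    return np.where(es >= 0, es / mean_pos, es / mean_neg)


def gsea_with_null(ranked: RankedList, collection: GeneSetCollection,
                   n_perm: int = 1000, seed: int = 0, weight: float = 1.0,
                   min_size: int = 1) -> pd.DataFrame:
    """Permutation GSEA over a whole collection.

    Sets disjoint from the ranked list (or below ``min_size`` after
    intersection) are silently skipped.  Each set gets its own
    size-matched gene-label permutation null (independent draws even
    for sets of equal size, so p-values are independent across sets);
    results are deterministic for a given seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    universe = set(ranked.genes)
    metric_abs = np.abs(ranked.metric)

    entries = []
    for name in collection:
        members = collection[name] & universe
        if len(members) < min_size:
            continue
        entries.append((name, members))

    rows = []
    null_nes_pool = []
    for name, members in entries:
        es, _, leading = enrichment_score(ranked, members, weight)
        null = _null_es(metric_abs, len(members), n_perm, weight, rng)
        p = (1 + int((np.abs(null) >= abs(es)).sum())) / (n_perm + 1)
        nes = float(_normalize(np.array([es]), null)[0])
        null_nes_pool.append(_normalize(null, null))
        rows.append({"set": name, "size": len(members), "es": es, "nes": nes,
                     "p_perm": p, "leading_edge": ",".join(sorted(leading))})

    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=GSEA_COLUMNS)

    pooled = np.concatenate(null_nes_pool)
    obs = out["nes"].to_numpy()
    q = np.empty(len(obs))
    n_null_pos = max(int((pooled >= 0).sum()), 1)
    n_null_neg = max(int((pooled < 0).sum()), 1)
    n_obs_pos = max(int((obs >= 0).sum()), 1)
    n_obs_neg = max(int((obs < 0).sum()), 1)
    for i, nes in enumerate(obs):
        if nes >= 0:
            num = (pooled >= nes).sum() / n_null_pos
            den = (obs >= nes).sum() / n_obs_pos
        else:
            num = (pooled <= nes).sum() / n_null_neg
            den = (obs <= nes).sum() / n_obs_neg
        q[i] = min(1.0, num / den) if den > 0 else 1.0
    # q never increases with |NES|: running min from weakest to strongest
    for sign in (1, -1):
        mask = (obs >= 0) if sign == 1 else (obs < 0)
        idx = np.where(mask)[0]
        order = idx[np.argsort(sign * obs[idx], kind="mergesort")]
        q[order] = np.minimum.accumulate(q[order])
    out["fdr_q"] = q
    return out[GSEA_COLUMNS].sort_values(["fdr_q", "p_perm", "set"],
                                         kind="mergesort").reset_index(drop=True)


def significant_sets(results: pd.DataFrame, q_threshold: float = 0.05) -> List[str]:
    return list(results.loc[results["fdr_q"] < q_threshold, "set"])
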