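"""Candidate assembly, overlap statistics, anchor correlations,
clustering and network export.

Candidate bookkeeping follows the source-union logic: a gene enters the
candidate table when it belongs to at least one source (anchor
neighborhood, significant pathway, co-expression module) and is
significant in at least one of the two studies.  Overlaps between
study-significant sets are tested with the one-sided hypergeometric
tail; heatmap dendrograms use the Canberra distance with complete
linkage.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import write_sif

logger = logging.getLogger(__name__)

CANDIDATE_COLUMNS = ["gene", "in_neighborhood", "in_pathway", "in_module",
                     "meta_significant", "heart_significant", "partial"]


# ---------------------------------------------------------------------------
# candidate assembly
# ---------------------------------------------------------------------------

def assemble_candidates(sources: Mapping[str, Set[str]],
                        meta_candidates: Set[str],
                        heart_candidates: Set[str],
                        meta_universe: Optional[Set[str]] = None,
                        heart_universe: Optional[Set[str]] = None,
                        ) -> Tuple[pd.DataFrame, Dict[str, Dict[str, int]]]:
    """Build the candidate table and per-source union counts.

    ``sources`` maps source names (e.g. "neighborhood", "pathway",
    "module") to gene sets.  A gene is a candidate iff it belongs to at
    least one source and is significant in at least one study.  The
    returned counts dict mirrors, per source: set size, per-study
    significant counts, their overlap, and the union — the bookkeeping
    that produces counts like 26 + 42 - 13 = 55.
    """
    significant_any = meta_candidates | heart_candidates
    counts: Dict[str, Dict[str, int]] = {}
    for name, members in sources.items():
        m = members & meta_candidates
        h = members & heart_candidates
        counts[name] = {
            "size": len(members),
            "meta_significant": len(m),
            "heart_significant": len(h),
            "overlap": len(m & h),
            "union": len(m | h),
        }
    all_sources = set().union(*sources.values()) if sources else set()
    genes = sorted(all_sources & significant_any)
    rows = []
    for g in genes:
        partial = False
        if meta_universe is not None and heart_universe is not None:
            partial = not (g in meta_universe and g in heart_universe)
        rows.append({
            "gene": g,
            **{f"in_{name}": g in members for name, members in sources.items()},
            "meta_significant": g in meta_candidates,
            "heart_significant": g in heart_candidates,
            "partial": partial,
        })
    columns = (["gene"] + [f"in_{name}" for name in sources]
               + ["meta_significant", "heart_significant", "partial"])
    table = pd.DataFrame(rows, columns=columns)
    return table, counts


# ---------------------------------------------------------------------------
# hypergeometric overlap / disease enrichment
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    """One-sided (enrichment) overlap test on a 2x2 table."""

    n_overlap: int
    n_a: int
    n_b: int
    n_universe: int
    odds_ratio: float
    p: float

    @property
    def table(self) -> Tuple[int, int, int, int]:
        a = self.n_overlap
        b = self.n_a - a
        c = self.n_b - a
        d = self.n_universe - a - b - c
        return a, b, c, d


def hypergeom_overlap(set_a: Set[str], set_b: Set[str],
                      universe: Set[str]) -> OverlapResult:
    """P(X >= |A∩B|) for drawing |B| genes from a universe containing
    |A| marked ones; odds ratio by the cross product (inf when a
    denominator cell is zero)."""
    universe = set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    a_in, b_in = set_a & universe, set_b & universe
    k = len(a_in & b_in)
    n_a, n_b, n_u = len(a_in), len(b_in), len(universe)
    p = float(stats.hypergeom.sf(k - 1, n_u, n_a, n_b))
    a, b, c, d = k, n_a - k, n_b - k, n_u - n_a - n_b + k
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return OverlapResult(k, n_a, n_b, n_u, odds, min(p, 1.0))


def disease_enrichment(evaluated: Set[str], significant: Set[str],
                       disease_genes: Iterable[str]) -> Dict[str, object]:
    """Disease-list coverage percentages plus hypergeometric enrichment.

    Reports the percentage of disease genes interrogated among the
    evaluated candidates, the percentage of those that are significant
    (both rounded to integers, as conventionally quoted), and the
    enrichment of the significant set for disease genes over the
    evaluated-candidate universe.
    """
    disease = set(disease_genes)
    evaluated = set(evaluated)
    significant = set(significant) & evaluated
    dis_eval = disease & evaluated
    dis_sig = disease & significant
    pct_eval = round(100.0 * len(dis_eval) / len(disease)) if disease else 0
    pct_sig = round(100.0 * len(dis_sig) / len(dis_eval)) if dis_eval else 0
    if dis_eval:
        overlap = hypergeom_overlap(dis_eval, significant, evaluated)
        p, odds = overlap.p, overlap.odds_ratio
    else:
        p, odds = 1.0, float("nan")
    return {
        "n_disease": len(disease),
        "n_disease_evaluated": len(dis_eval),
        "n_disease_significant": len(dis_sig),
        "pct_evaluated": pct_eval,
        "pct_significant": pct_sig,
        "enrichment_p": p,
        "odds_ratio": odds,
    }


# ---------------------------------------------------------------------------
# anchor correlation / concordance
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        return float("nan")
    xv, yv = x[mask], y[mask]
    if xv.std() == 0 or yv.std() == 0:
        return float("nan")         # undefined, never silently zero
    return float(np.corrcoef(xv, yv)[0, 1])


def anchor_correlation(heart_values: pd.DataFrame, meta_profiles: pd.DataFrame,
                       anchor: str, query_genes: Sequence[str]) -> pd.DataFrame:
    """Pearson correlation of each query gene with the anchor, in the
    heart samples and across the per-study meta effect profiles.

    ``meta_profiles`` is genes x studies (per-study log2fc means, NaN
    where absent).  Concordance requires the same non-zero sign in both
    datasets; the table is sorted by min(r_heart, r_meta) descending.
    """
    if anchor not in heart_values.index or anchor not in meta_profiles.index:
        raise ValueError(f"anchor {anchor!r} must be measured in both datasets")
    rows = []
    ah = heart_values.loc[anchor].to_numpy(dtype=float)
    am = meta_profiles.loc[anchor].to_numpy(dtype=float)
    for g in query_genes:
        r_h = (_pearson(heart_values.loc[g].to_numpy(dtype=float), ah)
               if g in heart_values.index else float("nan"))
        r_m = (_pearson(meta_profiles.loc[g].to_numpy(dtype=float), am)
               if g in meta_profiles.index else float("nan"))
        concordant = bool(np.isfinite(r_h) and np.isfinite(r_m)
                          and r_h * r_m > 0)
        rows.append({"gene": g, "r_heart": r_h, "r_meta": r_m,
                     "concordant": concordant})
    out = pd.DataFrame(rows, columns=["gene", "r_heart", "r_meta", "concordant"])
    rank = out[["r_heart", "r_meta"]].min(axis=1)
    out = out.assign(_rank=rank).sort_values(
        ["_rank", "gene"], ascending=[False, True], kind="mergesort",
        na_position="last").drop(columns="_rank")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# clustering / heatmap export
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    gene_linkage: np.ndarray
    sample_linkage: np.ndarray
    gene_order: List[str]
    sample_order: List[str]
    gene_newick: str
    sample_newick: str


def _linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(linkage, rd=False)

    def build(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return build(tree, tree.dist) + ";"


def cluster_heatmap(matrix: pd.DataFrame) -> ClusterResult:
    """Complete-linkage clustering of genes and samples under the
    Canberra distance d(x,y) = sum |x_i - y_i| / (|x_i| + |y_i|), with
    both-zero coordinates contributing 0."""
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples to cluster")
    gene_link = hierarchy.linkage(pdist(matrix.to_numpy(), metric="canberra"),
                                  method="complete")
    sample_link = hierarchy.linkage(pdist(matrix.to_numpy().T, metric="canberra"),
                                    method="complete")
    gene_order = [matrix.index[i] for i in hierarchy.leaves_list(gene_link)]
    sample_order = [matrix.columns[i] for i in hierarchy.leaves_list(sample_link)]
    return ClusterResult(
        gene_link, sample_link, gene_order, sample_order,
        _linkage_to_newick(gene_link, list(matrix.index)),
        _linkage_to_newick(sample_link, list(matrix.columns)),
    )


def reorder_matrix(matrix: pd.DataFrame, result: ClusterResult) -> pd.DataFrame:
    return matrix.loc[result.gene_order, result.sample_order]


def plot_heatmap(matrix: pd.DataFrame, result: ClusterResult, path) -> None:
    """Minimal clustered-heatmap figure (genes x samples)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    ordered = reorder_matrix(matrix, result)
    fig, ax = plt.subplots(figsize=(6, max(4, 0.08 * len(ordered))))
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(ordered.columns)))
    ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_xlabel("samples")
    ax.set_ylabel(f"{len(ordered)} genes")
    fig.colorbar(im, ax=ax, label="log2 ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def export_network(genes: Set[str], network: nx.Graph,
                   sif_path, attrs_path,
                   anchor: Optional[str] = None,
                   tbv: Optional[Mapping[str, float]] = None,
                   chromosomes: Optional[Mapping[str, str]] = None,
                   disease_genes: Optional[Set[str]] = None) -> pd.DataFrame:
    """Write the induced subgraph as SIF plus a node-attribute TSV.

    Isolated genes appear in the attribute table but not in the SIF.
    Returns the attribute table."""
    nodes = set(genes) | ({anchor} if anchor else set())
    sub = network.subgraph(n for n in nodes if n in network).copy()
    write_sif(sub, sif_path)
    disease_genes = disease_genes or set()
    rows = []
    for g in sorted(nodes):
        rows.append({
            "gene": g,
            "on_hsa21": (chromosomes or {}).get(g) == "HSA21",
            "disease_related": g in disease_genes,
            "tbv": (tbv or {}).get(g, float("nan")),
            "is_anchor": g == anchor,
            "degree": sub.degree(g) if g in sub else 0,
        })
    attrs = pd.DataFrame(rows, columns=["gene", "on_hsa21", "disease_related",
                                        "tbv", "is_anchor", "degree"])
    attrs.to_csv(attrs_path, sep="\t", index=False, float_format="%.17g")
    return attrs
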