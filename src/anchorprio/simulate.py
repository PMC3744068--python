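"""Synthetic study generator with known ground truth.

Emulates the shape of the real inputs the pipeline was designed for: a
16-study meta-analysis effect table, a 5-control / 10-case heart
expression study, a scale-free protein-interaction network, a pathway
collection and a disease gene list.  Differential effects are planted
preferentially on the anchor gene's radius-2 interaction neighborhood,
one co-expression bicluster containing the anchor is shifted into the
expression matrix, and the disease list overlaps the perturbed genes at
a configurable rate — so every downstream stage can be scored against
truth without any data download.

All randomness flows through one :class:`numpy.random.Generator`
(PCG64) seeded by ``rng_seed``; identical parameters produce
byte-identical files on every platform.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Set

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    CASE, CONTROL, ExpressionStudy, GeneSetCollection, StudyEffectTable,
    write_chromosomes_tsv, write_effect_table, write_expression_tsv,
    write_gene_list, write_gmt, write_sif,
)


@dataclass
class BiclusterSpec:
    """Planted co-expression block: ``n_genes`` x ``n_samples`` entries of
    the heart matrix shifted upward by ``shift`` log2 units."""

    n_genes: int = 40
    n_samples: int = 7
    shift: float = 2.0


@dataclass
class SimulationParams:
    """Knobs of the synthetic study.

    Defaults mirror the design the pipeline emulates: a 16-study
    meta-analysis prior source, 5 controls and 10 cases in the
    case/control study, a 2,000-gene desk-scale universe, log2 effect
    sizes around 1.0 against 0.5 log2 units of noise, and a 52-gene
    disease list overlapping the perturbed set.
    """

    n_genes: int = 2000
    n_meta_studies: int = 16
    n_controls: int = 5
    n_cases: int = 10
    anchor_gene: str = "FBN1"
    #: fraction of the anchor's radius-2 neighborhood that is perturbed
    perturbed_fraction: float = 0.5
    #: extra perturbed genes outside the neighborhood, relative to the
    #: in-neighborhood count; these seed the planted pathway
    outside_perturbed_fraction: float = 0.25
    effect_size_mean: float = 1.0
    effect_size_sd: float = 0.2
    #: probability a perturbed gene is upregulated (the anchor always is)
    up_fraction: float = 0.8
    noise_sd: float = 0.5
    bicluster: BiclusterSpec = field(default_factory=BiclusterSpec)
    #: probability a (gene, study) pair is scored as not expressed
    presence_missing_rate: float = 0.3
    #: fraction of null genes absent from the heart study's platform
    heart_coverage: float = 0.9
    n_pathways_null: int = 6
    pathway_size: int = 40
    disease_list_size: int = 52
    #: fraction of the disease list drawn from truly perturbed genes
    disease_overlap: float = 0.4
    hsa21_fraction: float = 0.05
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_meta_studies", "n_controls", "n_cases",
                     "disease_list_size", "pathway_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("perturbed_fraction", "outside_perturbed_fraction",
                     "presence_missing_rate", "heart_coverage",
                     "disease_overlap", "hsa21_fraction", "up_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        n_samples = self.n_controls + self.n_cases
        if self.bicluster.n_genes > self.n_genes or self.bicluster.n_samples > n_samples:
            raise ValueError(
                f"bicluster ({self.bicluster.n_genes} x {self.bicluster.n_samples}) "
                f"larger than the expression matrix ({self.n_genes} x {n_samples})"
            )


@dataclass
class SimulatedTruth:
    """Ground truth of one simulation run."""

    perturbed: Dict[str, float]          # gene -> true log2 effect
    bicluster_genes: Set[str]
    bicluster_samples: Set[str]
    enriched_pathways: Set[str]
    disease_genes: List[str]

    def to_json(self) -> str:
        payload = {
            "perturbed": {g: float(t) for g, t in sorted(self.perturbed.items())},
            "bicluster_genes": sorted(self.bicluster_genes),
            "bicluster_samples": sorted(self.bicluster_samples),
            "enriched_pathways": sorted(self.enriched_pathways),
            "disease_genes": list(self.disease_genes),
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulatedTruth":
        d = json.loads(text)
        return cls(d["perturbed"], set(d["bicluster_genes"]),
                   set(d["bicluster_samples"]), set(d["enriched_pathways"]),
                   list(d["disease_genes"]))


@dataclass
class SimulatedData:
    effects: StudyEffectTable
    heart: ExpressionStudy
    network: nx.Graph
    pathways: GeneSetCollection
    disease_genes: List[str]
    truth: SimulatedTruth


def _gene_names(params: SimulationParams) -> List[str]:
    names = [f"G{i:05d}" for i in range(params.n_genes)]
    # anchor relabeled from node index 2 of the preferential-attachment
    # graph: early enough to be a hub with a radius-2 neighborhood of
    # roughly 100-300 genes at the default universe size
    names[2] = params.anchor_gene
    return names


def simulate_network(params: SimulationParams, seed: int) -> nx.Graph:
    g = nx.barabasi_albert_graph(params.n_genes, 1, seed=int(seed))
    names = _gene_names(params)
    return nx.relabel_nodes(g, dict(enumerate(names)))


def simulate_all(params: SimulationParams) -> SimulatedData:
    """Generate the five pipeline inputs plus their ground truth."""
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    genes = _gene_names(params)
    anchor = params.anchor_gene

    network = simulate_network(params, seed=rng.integers(2**31))
    dist = nx.single_source_shortest_path_length(network, anchor, cutoff=2)
    neighborhood = sorted(g for g in dist if g != anchor)

    # --- true effects: preferentially inside the anchor neighborhood ----
    n_in = int(round(params.perturbed_fraction * len(neighborhood)))
    inside = list(rng.choice(neighborhood, size=min(n_in, len(neighborhood)),
                             replace=False))
    outside_pool = sorted(set(genes) - set(neighborhood) - {anchor})
    n_out = int(round(params.outside_perturbed_fraction * len(inside)))
    outside = list(rng.choice(outside_pool, size=min(n_out, len(outside_pool)),
                              replace=False))
    perturbed_genes = [anchor] + sorted(set(inside) | set(outside))

    theta: Dict[str, float] = {g: 0.0 for g in genes}
    for g in perturbed_genes:
        if params.effect_size_mean == 0.0:
            theta[g] = 0.0
            continue
        sign = 1.0 if (g == anchor or rng.random() < params.up_fraction) else -1.0
        magnitude = max(rng.normal(params.effect_size_mean, params.effect_size_sd), 0.0)
        theta[g] = sign * magnitude

    theta_vec = np.array([theta[g] for g in genes])

    # --- study-level effect table ---------------------------------------
    n_g, n_s = params.n_genes, params.n_meta_studies
    se = rng.uniform(0.15, 0.30, size=(n_g, n_s))
    means = theta_vec[:, None] + rng.normal(0.0, 1.0, size=(n_g, n_s)) * se
    present = rng.random((n_g, n_s)) >= params.presence_missing_rate
    # present transcripts get a detection p concentrated near zero,
    # absent ones a uniform p; only the <0.1 threshold matters downstream
    p_present = rng.beta(0.1, 10.0, size=(n_g, n_s))
    p_absent = rng.random((n_g, n_s))
    presence_p = np.where(present, p_present, p_absent)
    effects = StudyEffectTable(pd.DataFrame({
        "gene": np.repeat(genes, n_s),
        "study_id": np.tile([f"S{j:02d}" for j in range(n_s)], n_g),
        "log2fc_mean": means.ravel(),
        "se": se.ravel(),
        "presence_p": presence_p.ravel(),
    }))

    # --- heart case/control study ---------------------------------------
    samples = ([f"C{i:02d}" for i in range(params.n_controls)]
               + [f"D{i:02d}" for i in range(params.n_cases)])
    groups = {s: (CONTROL if s.startswith("C") else CASE) for s in samples}
    case_mask = np.array([groups[s] == CASE for s in samples])

    bic = params.bicluster
    in_pool = [g for g in inside if g != anchor]
    bic_extra = min(bic.n_genes - 1, len(in_pool))
    bic_genes = {anchor} | set(rng.choice(in_pool, size=bic_extra, replace=False))
    n_bic_ctrl = max(1, bic.n_samples // 3)
    n_bic_case = bic.n_samples - n_bic_ctrl
    bic_samples = set(rng.choice(samples[:params.n_controls], size=n_bic_ctrl,
                                 replace=False))
    bic_samples |= set(rng.choice(samples[params.n_controls:], size=n_bic_case,
                                  replace=False))

    baseline = rng.normal(8.0, 1.5, size=n_g)
    values = (baseline[:, None]
              + theta_vec[:, None] * case_mask[None, :]
              + rng.normal(0.0, params.noise_sd, size=(n_g, len(samples))))
    bic_gene_idx = np.array([g in bic_genes for g in genes])
    bic_sample_idx = np.array([s in bic_samples for s in samples])
    values[np.ix_(bic_gene_idx, bic_sample_idx)] += bic.shift

    # the heart platform misses a slice of the null genes (different
    # universes, as with real array platforms)
    keep = {anchor} | set(perturbed_genes) | bic_genes
    droppable = sorted(set(genes) - keep)
    n_drop = int(round((1.0 - params.heart_coverage) * len(droppable)))
    dropped = set(rng.choice(droppable, size=n_drop, replace=False))
    heart_genes = [g for g in genes if g not in dropped]

    chrom_draw = rng.random(n_g)
    chromosomes = {
        g: ("HSA21" if chrom_draw[i] < params.hsa21_fraction and g != anchor
            else ("HSA15" if g == anchor else "other"))
        for i, g in enumerate(genes)
    }

    heart = ExpressionStudy(
        study_id="synthetic_heart",
        values=pd.DataFrame(values, index=genes, columns=samples).loc[heart_genes],
        sample_groups=groups,
        gene_chromosomes=chromosomes,
    )

    # --- pathway collection ---------------------------------------------
    planted_core = sorted(set(outside) | {anchor})
    n_fill = max(params.pathway_size - len(planted_core), 0)
    n_fill_pert = min(n_fill * 3 // 4, max(len(inside) - 1, 0))
    fill_pert = list(rng.choice([g for g in inside if g not in planted_core],
                                size=n_fill_pert, replace=False))
    null_pool = sorted(set(genes) - set(perturbed_genes))
    fill_null = list(rng.choice(null_pool, size=n_fill - n_fill_pert, replace=False))
    sets = {"PLANTED_ECM": set(planted_core) | set(fill_pert) | set(fill_null)}
    descriptions = {"PLANTED_ECM": "synthetic enriched pathway (planted)"}
    for j in range(params.n_pathways_null):
        name = f"NULL_PW_{j:02d}"
        sets[name] = set(rng.choice(genes, size=params.pathway_size, replace=False))
        descriptions[name] = "synthetic null pathway"
    pathways = GeneSetCollection(sets, descriptions)

    # --- disease gene list -----------------------------------------------
    n_dis = params.disease_list_size
    n_from_pert = min(int(round(params.disease_overlap * n_dis)),
                      len(perturbed_genes))
    n_from_null = min(int(round(0.3 * n_dis)), len(null_pool))
    from_pert = list(rng.choice(perturbed_genes, size=n_from_pert, replace=False))
    from_null = list(rng.choice(null_pool, size=n_from_null, replace=False))
    n_external = n_dis - n_from_pert - n_from_null
    external = [f"EXT{j:03d}" for j in range(n_external)]
    disease_genes = sorted(set(from_pert) | set(from_null) | set(external))

    truth = SimulatedTruth(
        perturbed={g: theta[g] for g in perturbed_genes},
        bicluster_genes=bic_genes,
        bicluster_samples=bic_samples,
        enriched_pathways={"PLANTED_ECM"},
        disease_genes=disease_genes,
    )
    return SimulatedData(effects, heart, network, pathways, disease_genes, truth)


def write_simulated(data: SimulatedData, outdir) -> Dict[str, str]:
    """Write all five inputs plus the truth files; returns a name->path map."""
    import os
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "effects": os.path.join(outdir, "effects.tsv"),
        "expression": os.path.join(outdir, "expression.tsv"),
        "groups": os.path.join(outdir, "groups.tsv"),
        "chromosomes": os.path.join(outdir, "chromosomes.tsv"),
        "network": os.path.join(outdir, "network.sif"),
        "pathways": os.path.join(outdir, "pathways.gmt"),
        "disease_genes": os.path.join(outdir, "disease_genes.txt"),
        "truth_json": os.path.join(outdir, "truth.json"),
        "truth_tsv": os.path.join(outdir, "truth_effects.tsv"),
    }
    write_effect_table(data.effects, paths["effects"])
    write_expression_tsv(data.heart, paths["expression"], paths["groups"])
    write_chromosomes_tsv(data.heart.gene_chromosomes, paths["chromosomes"])
    write_sif(data.network, paths["network"])
    write_gmt(data.pathways, paths["pathways"])
    write_gene_list(data.disease_genes, paths["disease_genes"])
    with open(paths["truth_json"], "w") as fh:
        fh.write(data.truth.to_json())
    truth_df = pd.DataFrame(
        sorted(data.truth.perturbed.items()), columns=["gene", "true_theta"]
    )
    truth_df.to_csv(paths["truth_tsv"], sep="\t", index=False, float_format="%.17g")
    return paths


def simulation_params_from_dict(d: dict) -> SimulationParams:
    """Build :class:`SimulationParams` from a plain dict, rejecting
    unknown keys (used by the config layer)."""
    d = dict(d)
    bic = d.pop("bicluster", None)
    known = {f.name for f in SimulationParams.__dataclass_fields__.values()}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation parameter(s): {sorted(unknown)}")
    params = SimulationParams(**d)
    if bic is not None:
        known_b = set(BiclusterSpec.__dataclass_fields__)
        unknown_b = set(bic) - known_b
        if unknown_b:
            raise ValueError(f"unknown bicluster parameter(s): {sorted(unknown_b)}")
        params.bicluster = BiclusterSpec(**bic)
    params.validate()
    return params


def params_to_dict(params: SimulationParams) -> dict:
    return asdict(params)
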