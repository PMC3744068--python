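"""End-to-end pipeline orchestration with a single config file.

Stage order: simulate (or load) -> priors -> differential expression ->
neighborhood -> GSEA -> ISA -> candidate assembly -> TBV -> integration.
Every stage communicates with the next only through its declared output
files/tables; a manifest records input hashes and parameters so a rerun
with the same config is byte-identical in its non-log outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import zlib
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import bayes, de, gsea, integration, isa, neighborhood, prior
from .io import (
    GeneSetCollection, StudyEffectTable, read_chromosomes_tsv,
    read_edge_list, read_effect_table, read_expression_tsv, read_gene_list,
    read_gmt, write_result_tsv, write_sif,
)
from .simulate import (
    SimulatedData, SimulationParams, simulate_all,
    simulation_params_from_dict, write_simulated,
)

logger = logging.getLogger(__name__)

STAGES = ["simulate", "prior", "de", "neighborhood", "gsea", "isa",
          "assemble", "tbv", "integrate"]


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class GseaConfig:
    n_perm: int = 1000
    q_threshold: float = 0.05
    weight: float = 1.0


@dataclass
class IsaConfig:
    gene_thresholds: tuple = isa.DEFAULT_THRESHOLDS
    sample_thresholds: tuple = isa.DEFAULT_THRESHOLDS
    n_seeds: int = 100
    seed_size: int = 10
    max_iter: int = 100
    min_samples: int = 5
    merge_share: float = 0.8


@dataclass
class InputPaths:
    effects: str = ""
    expression: str = ""
    groups: str = ""
    chromosomes: str = ""
    network: str = ""
    pathways: str = ""
    disease_genes: str = ""


@dataclass
class RunConfig:
    """Schema-validated configuration for one pipeline run."""

    seed: int = 0
    output_dir: str = "anchorprio_run"
    anchor_gene: str = "FBN1"
    simulate: Optional[SimulationParams] = None
    inputs: Optional[InputPaths] = None
    presence_alpha: float = 0.1
    meta_score_cutoff: float = 3.4
    de_alpha: float = 0.1
    neighborhood_radius: int = 2
    gsea: GseaConfig = field(default_factory=GseaConfig)
    isa: IsaConfig = field(default_factory=IsaConfig)
    tbv_threshold: float = bayes.TBV_THRESHOLD
    overlap_alternative: str = "greater"
    write_figures: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")

        def build(sub_cls, value, name):
            if value is None or isinstance(value, sub_cls):
                return value
            fields = {f.name for f in dataclasses.fields(sub_cls)}
            extra = set(value) - fields
            if extra:
                raise ConfigError(f"unknown {name} key(s): {sorted(extra)}")
            return sub_cls(**value)

        if "simulate" in d and d["simulate"] is not None and not isinstance(
                d["simulate"], SimulationParams):
            try:
                d["simulate"] = simulation_params_from_dict(d["simulate"])
            except ValueError as exc:
                raise ConfigError(str(exc)) from exc
        d["inputs"] = build(InputPaths, d.get("inputs"), "inputs")
        d["gsea"] = build(GseaConfig, d.get("gsea", GseaConfig()), "gsea")
        d["isa"] = build(IsaConfig, d.get("isa", IsaConfig()), "isa")
        cfg = cls(**d)
        if cfg.simulate is None and cfg.inputs is None:
            raise ConfigError("config needs either a 'simulate' block or 'inputs' paths")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (zlib.crc32(f"{stage}:{global_seed}".encode()) ^ global_seed) % (2 ** 31)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _load_inputs(cfg: RunConfig):
    paths = cfg.inputs
    effects = read_effect_table(paths.effects)
    heart = read_expression_tsv(paths.expression, paths.groups,
                                study_id="heart")
    if paths.chromosomes:
        heart.gene_chromosomes = read_chromosomes_tsv(paths.chromosomes)
    network = read_edge_list(paths.network)
    pathways = read_gmt(paths.pathways)
    disease = read_gene_list(paths.disease_genes)
    return effects, heart, network, pathways, disease, None


def run_pipeline(cfg: RunConfig, data: Optional[SimulatedData] = None) -> dict:
    """Execute all stages; returns the aggregated run report (also
    written to ``report.json`` in the output directory)."""
    out = cfg.output_dir
    os.makedirs(out, exist_ok=True)
    manifest: Dict[str, object] = {"stages": [], "inputs": {}, "outputs": {},
                                   "seed": cfg.seed}
    current = "config"
    try:
        # ---- stage: simulate / load ----------------------------------
        current = "simulate"
        if data is not None:
            truth = data.truth
        elif cfg.simulate is not None:
            params = dataclasses.replace(
                cfg.simulate, rng_seed=stage_seed(cfg.seed, "simulate"))
            data = simulate_all(params)
            truth = data.truth
        else:
            effects, heart, network, pathways, disease, truth = _load_inputs(cfg)
            for name, p in dataclasses.asdict(cfg.inputs).items():
                if p:
                    manifest["inputs"][name] = _sha256(p)
            data = SimulatedData(effects, heart, network, pathways, disease,
                                 truth)
        if cfg.simulate is not None or truth is not None:
            sim_paths = write_simulated(data, os.path.join(out, "inputs"))
            manifest["inputs"] = {k: _sha256(p) for k, p in sim_paths.items()}
        effects, heart = data.effects, data.heart
        network, pathways = data.network, data.pathways
        disease = data.disease_genes
        truth = data.truth
        anchor = cfg.anchor_gene
        manifest["stages"].append("simulate")

        meta_universe = set(effects.genes)
        heart_universe = set(heart.genes)

        # ---- stage: priors / meta scores ------------------------------
        current = "prior"
        priors, excluded = prior.build_priors(effects, cfg.presence_alpha)
        scores = prior.surrogate_meta_score(effects, cfg.presence_alpha,
                                            cutoff=cfg.meta_score_cutoff)
        meta_candidates = set(scores.loc[scores["is_candidate"], "gene"])
        write_result_tsv(priors, os.path.join(out, "priors.tsv"))
        write_result_tsv(excluded, os.path.join(out, "prior_exclusions.tsv"))
        write_result_tsv(scores, os.path.join(out, "meta_scores.tsv"))
        manifest["stages"].append("prior")

        # ---- stage: differential expression ---------------------------
        current = "de"
        ratios = de.standardize(heart)
        tt = de.shrinkage_t(ratios)
        heart_candidates = de.select_heart_candidates(tt, cfg.de_alpha)
        write_result_tsv(tt.results_, os.path.join(out, "de_results.tsv"))
        with open(os.path.join(out, "de_summary.json"), "w") as fh:
            json.dump({"lambda_star": tt.lambda_star_,
                       "v_median": tt.v_median_, "df": tt.df_,
                       "n_candidates": len(heart_candidates),
                       "alpha": cfg.de_alpha}, fh, indent=1, sort_keys=True)
        manifest["stages"].append("de")

        # ---- stage: neighborhood --------------------------------------
        current = "neighborhood"
        nb = neighborhood.ego_extract(network, anchor,
                                      radius=cfg.neighborhood_radius)
        nb_meta = neighborhood.restrict_to_universe(nb, meta_universe)
        nb_heart = neighborhood.restrict_to_universe(nb, heart_universe)
        logger.info("neighborhood: %d members; %d in meta universe, %d in "
                    "heart universe", len(nb.members), len(nb_meta), len(nb_heart))
        write_result_tsv(nb.to_frame(), os.path.join(out, "neighborhood.tsv"))
        write_sif(neighborhood.induced_subgraph(network, nb.members, anchor),
                  os.path.join(out, "neighborhood.sif"))
        manifest["stages"].append("neighborhood")

        # ---- stage: GSEA over pathways --------------------------------
        current = "gsea"
        meta_metric = prior.signed_meta_metric(effects, cfg.presence_alpha)
        heart_metric = pd.Series(tt.t_star_, index=tt.genes_, name="t_star")
        ranked_meta = gsea.rank_genes(meta_metric)
        ranked_heart = gsea.rank_genes(heart_metric)
        g_seed = stage_seed(cfg.seed, "gsea")
        res_meta = gsea.gsea_with_null(ranked_meta, pathways,
                                       n_perm=cfg.gsea.n_perm, seed=g_seed,
                                       weight=cfg.gsea.weight, min_size=3)
        res_heart = gsea.gsea_with_null(ranked_heart, pathways,
                                        n_perm=cfg.gsea.n_perm, seed=g_seed + 1,
                                        weight=cfg.gsea.weight, min_size=3)
        sig_pw = (set(gsea.significant_sets(res_meta, cfg.gsea.q_threshold))
                  | set(gsea.significant_sets(res_heart, cfg.gsea.q_threshold)))
        pathway_genes = set()
        for name in sig_pw:
            pathway_genes |= pathways[name] & (meta_universe | heart_universe)
        res_meta.insert(0, "study", "meta")
        res_heart.insert(0, "study", "heart")
        write_result_tsv(pd.concat([res_meta, res_heart], ignore_index=True),
                         os.path.join(out, "gsea_pathways.tsv"))
        manifest["stages"].append("gsea")

        # ---- stage: ISA modules ---------------------------------------
        current = "isa"
        isa_params = isa.IsaParams(
            gene_thresholds=tuple(cfg.isa.gene_thresholds),
            sample_thresholds=tuple(cfg.isa.sample_thresholds),
            n_seeds=cfg.isa.n_seeds, seed_size=cfg.isa.seed_size,
            max_iter=cfg.isa.max_iter, rng_seed=stage_seed(cfg.seed, "isa"))
        modules = isa.run_isa(ratios.values, isa_params)
        anchor_modules = isa.anchor_filter_merge(
            modules, anchor, min_samples=cfg.isa.min_samples,
            merge_share=cfg.isa.merge_share)
        module_genes = set().union(*(m.genes for m in anchor_modules)) \
            if anchor_modules else set()
        # enrichment of anchor modules in both studies, as with pathways
        module_gsea = pd.DataFrame(columns=["study"] + gsea.GSEA_COLUMNS)
        if anchor_modules:
            mod_coll = GeneSetCollection(
                {f"ISA_MODULE_{i}": m.genes for i, m in enumerate(anchor_modules)},
                {f"ISA_MODULE_{i}": "anchor co-expression module"
                 for i in range(len(anchor_modules))})
            gm = gsea.gsea_with_null(ranked_meta, mod_coll,
                                     n_perm=cfg.gsea.n_perm, seed=g_seed + 2,
                                     weight=cfg.gsea.weight, min_size=3)
            gh = gsea.gsea_with_null(ranked_heart, mod_coll,
                                     n_perm=cfg.gsea.n_perm, seed=g_seed + 3,
                                     weight=cfg.gsea.weight, min_size=3)
            gm.insert(0, "study", "meta")
            gh.insert(0, "study", "heart")
            module_gsea = pd.concat([gm, gh], ignore_index=True)
        gene_tab, sample_tab = isa.modules_to_frames(anchor_modules)
        write_result_tsv(gene_tab, os.path.join(out, "isa_modules.tsv"))
        write_result_tsv(sample_tab, os.path.join(out, "isa_samples.tsv"))
        write_result_tsv(module_gsea, os.path.join(out, "gsea_modules.tsv"))
        with open(os.path.join(out, "isa_summary.json"), "w") as fh:
            json.dump({"n_modules_total": len(modules),
                       "n_anchor_modules": len(anchor_modules),
                       "module_sizes": sorted(len(m.genes) for m in anchor_modules),
                       "thresholds": {"genes": list(cfg.isa.gene_thresholds),
                                      "samples": list(cfg.isa.sample_thresholds)}},
                      fh, indent=1, sort_keys=True)
        manifest["stages"].append("isa")

        # ---- stage: candidate assembly --------------------------------
        current = "assemble"
        sources = {"neighborhood": nb.members & (meta_universe | heart_universe),
                   "pathway": pathway_genes,
                   "module": module_genes}
        candidates, source_counts = integration.assemble_candidates(
            sources, meta_candidates, heart_candidates,
            meta_universe, heart_universe)
        write_result_tsv(candidates, os.path.join(out, "candidates.tsv"))
        manifest["stages"].append("assemble")

        # ---- stage: TBV ------------------------------------------------
        current = "tbv"
        likelihoods = bayes.case_likelihoods(ratios)
        cand_genes = set(candidates["gene"])
        post, no_prior, no_data = bayes.posterior_update(
            priors[priors["gene"].isin(cand_genes)],
            likelihoods[likelihoods["gene"].isin(cand_genes)],
            threshold=cfg.tbv_threshold)
        chromosomes = heart.gene_chromosomes
        decision = bayes.tbv_decision(post, chromosomes, cfg.tbv_threshold)
        post_out = post.copy()
        post_out["chromosome"] = [chromosomes.get(g, "NA") for g in post_out["gene"]]
        write_result_tsv(post_out, os.path.join(out, "posterior.tsv"))
        thr_report = bayes.threshold_sensitivity(post, rounded=cfg.tbv_threshold)
        manifest["stages"].append("tbv")

        # ---- stage: integration ---------------------------------------
        current = "integrate"
        both_universe = meta_universe & heart_universe
        overlap_rows = []
        for name, members in sources.items():
            members_both = members & both_universe
            ov = integration.hypergeom_overlap(
                members_both & meta_candidates,
                members_both & heart_candidates, both_universe)
            overlap_rows.append({"comparison": f"{name}_meta_vs_heart",
                                 "overlap": ov.n_overlap, "n_a": ov.n_a,
                                 "n_b": ov.n_b, "universe": ov.n_universe,
                                 "odds_ratio": ov.odds_ratio, "p": ov.p})
        overlaps = pd.DataFrame(overlap_rows)
        write_result_tsv(overlaps, os.path.join(out, "overlaps.tsv"))

        disease_stats = integration.disease_enrichment(
            cand_genes & set(post["gene"]), decision.all_significant, disease)
        # same question over the whole measured universe: are the TBV
        # calls enriched for the disease list at all?
        full_universe = meta_universe | heart_universe
        dis_in_universe = set(disease) & full_universe
        ov_univ = integration.hypergeom_overlap(
            dis_in_universe, decision.all_significant & full_universe,
            full_universe)
        disease_stats["universe_enrichment_p"] = ov_univ.p
        disease_stats["universe_odds_ratio"] = ov_univ.odds_ratio
        with open(os.path.join(out, "disease_enrichment.json"), "w") as fh:
            json.dump(disease_stats, fh, indent=1, sort_keys=True, default=float)

        meta_profiles = effects.data.pivot(index="gene", columns="study_id",
                                           values="log2fc_mean")
        hsa21_genes = sorted(g for g in decision.all_significant
                             if chromosomes.get(g) == "HSA21")
        corr = integration.anchor_correlation(
            ratios.values, meta_profiles, anchor, hsa21_genes) \
            if hsa21_genes else pd.DataFrame(
                columns=["gene", "r_heart", "r_meta", "concordant"])
        write_result_tsv(corr, os.path.join(out, "anchor_correlation.tsv"))

        cluster_genes = sorted(decision.non_hsa21 & set(ratios.values.index))
        if len(cluster_genes) >= 2:
            cl = integration.cluster_heatmap(ratios.values.loc[cluster_genes])
            with open(os.path.join(out, "dendrogram_genes.nwk"), "w") as fh:
                fh.write(cl.gene_newick + "\n")
            with open(os.path.join(out, "dendrogram_samples.nwk"), "w") as fh:
                fh.write(cl.sample_newick + "\n")
            integration.reorder_matrix(
                ratios.values.loc[cluster_genes], cl
            ).to_csv(os.path.join(out, "heatmap_matrix.tsv"), sep="\t",
                     index_label="gene", float_format="%.17g")
            if cfg.write_figures:
                integration.plot_heatmap(ratios.values.loc[cluster_genes], cl,
                                         os.path.join(out, "heatmap.png"))

        integration.export_network(
            decision.all_significant, network,
            os.path.join(out, "network.sif"),
            os.path.join(out, "network_attrs.tsv"),
            anchor=anchor, tbv=dict(zip(post["gene"], post["tbv"])),
            chromosomes=chromosomes, disease_genes=set(disease))
        manifest["stages"].append("integrate")

        # ---- report ----------------------------------------------------
        report = {
            "seed": cfg.seed,
            "anchor": anchor,
            "n_genes_meta": len(meta_universe),
            "n_genes_heart": len(heart_universe),
            "n_meta_candidates": len(meta_candidates),
            "n_heart_candidates": len(heart_candidates),
            "neighborhood_size": len(nb.members),
            "neighborhood_in_meta": len(nb_meta),
            "neighborhood_in_heart": len(nb_heart),
            "n_significant_pathways": len(sig_pw),
            "n_anchor_modules": len(anchor_modules),
            "module_union_size": len(module_genes),
            "source_counts": source_counts,
            "n_candidates": len(cand_genes),
            "n_no_prior": len(no_prior),
            "n_no_data": len(no_data),
            "n_tbv_significant": len(decision.all_significant),
            "n_tbv_significant_non_hsa21": len(decision.non_hsa21),
            "n_tbv_significant_hsa21": len(decision.hsa21),
            "tbv_threshold": thr_report,
            "disease": disease_stats,
            "overlap_tests": overlap_rows,
        }
        if truth is not None:
            perturbed = {g for g, t in truth.perturbed.items() if t != 0.0}
            sig = decision.all_significant
            n_null = len(meta_universe | heart_universe) - len(perturbed)
            report["truth_eval"] = {
                "n_perturbed": len(perturbed),
                "sensitivity": (len(sig & perturbed) / len(perturbed)
                                if perturbed else float("nan")),
                "false_positive_rate": (len(sig - perturbed) / n_null
                                        if n_null else float("nan")),
            }
        with open(os.path.join(out, "report.json"), "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=float)

        for fname in sorted(os.listdir(out)):
            fpath = os.path.join(out, fname)
            if os.path.isfile(fpath) and fname != "manifest.json":
                manifest["outputs"][fname] = _sha256(fpath)
        manifest["config"] = json.loads(json.dumps(
            dataclasses.asdict(cfg), default=str))
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return report
    except (ConfigError, StageError):
        raise
    except Exception as exc:
        raise StageError(f"stage {current!r} failed: {exc}") from exc
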