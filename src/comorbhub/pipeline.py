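"""End-to-end orchestration.

``simulate`` writes a complete synthetic input bundle to disk;
``run`` executes the stages in order — differential expression,
co-expression modules, disease gene sets, PPI hub triangulation,
enrichment/immune scoring, survival stratification, miRNA network —
each stage reading its inputs from disk and writing its outputs before
the next begins, so any stage can be re-run from the on-disk
intermediates. A machine-readable run report is produced at the end.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression as coexpr
from . import disease_sets, enrichment, io as chio, mirna as mirna_mod
from . import network as net_mod
from . import preprocess as prep
from . import survival as surv_mod
from .containers import ExpressionMatrix
from .synthio import DATASETS, SynthConfig, generate_all

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "simulate", "run", "StageError"]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All input paths and every tunable threshold, with the analysis
    defaults: |log2FC| > 1, adj.p < 0.05, top 5000 MAD genes, scale-free
    R^2 > 0.85, STRING score >= 0.4, MCODE (2, 2, 0.2, haircut, no fluff),
    MCC top 20, relevance >= 10, PMIDs > 0, ORA adj.p < 0.05, |NES| > 1,
    Spearman rho > 0.3, 30-day follow-up minimum."""

    # input files
    expression_a1: str = ""
    phenotype_a1: str = ""
    expression_a2: str = ""
    phenotype_a2: str = ""
    ppi_edges: str = ""
    relevance_table: str = ""
    curation_table: str = ""
    mirna_list_a: str = ""
    mirna_list_b: str = ""
    mirna_targets: str = ""
    pathways_gmt: str = ""
    immune_gmt: str = ""
    outdir: str = "comorbhub_out"
    disease_a_name: str = "disease_A"
    disease_b_name: str = "disease_B"
    # preprocessing
    log_transform: bool = False
    quantile_norm: bool = False
    # thresholds (analysis defaults)
    lfc: float = 1.0
    alpha: float = 0.05
    mad_top: int = 5000
    outlier_sigma: float = 3.0
    r2_min: float = 0.85
    min_module_size: int = 30
    cut_height: float = 0.99
    max_power: int = 20
    min_score: float = 0.4
    mcode_degree_cutoff: int = 2
    mcode_k_core: int = 2
    mcode_node_score_cutoff: float = 0.2
    mcode_haircut: bool = True
    mcode_fluff: bool = False
    mcc_top: int = 20
    relevance_min: float = 10.0
    pmid_min: int = 1
    ora_alpha: float = 0.05
    shared_top_n: int = 20
    nes_min: float = 1.0
    gsea_n_perm: int = 200
    cor_min: float = 0.3
    followup_min: float = 30.0
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def out(self, *parts) -> Path:
        p = Path(self.outdir).joinpath(*parts)
        p.parent.mkdir(parents=True, exist_ok=True)
        return p


# ------------------------------------------------------------------ simulate

def simulate(synth_config: SynthConfig, outdir) -> PipelineConfig:
    """Generate the full synthetic input bundle on disk and return a
    PipelineConfig wired to it (plus truth.json for recovery scoring)."""
    outdir = Path(outdir)
    indir = outdir / "inputs"
    indir.mkdir(parents=True, exist_ok=True)
    bundle = generate_all(synth_config)
    paths = {}
    for name in DATASETS:
        expr = bundle["datasets"][name]
        paths[name] = (indir / f"expression_{name}.tsv", indir / f"phenotype_{name}.tsv")
        chio.write_expression_tsv(expr, paths[name][0])
        chio.write_phenotype_tsv(expr, paths[name][1])
    chio.write_string_tsv(bundle["ppi"], indir / "ppi_edges.tsv")
    bundle["relevance"].to_csv(indir / "disease_b_relevance.tsv", sep="\t", index=False)
    bundle["curation"].to_csv(indir / "disease_b_curation.tsv", sep="\t", index=False)
    chio.write_gene_list(bundle["mirna_list_a"], indir / "mirna_disease_a.txt")
    chio.write_gene_list(bundle["mirna_list_b"], indir / "mirna_disease_b.txt")
    pd.DataFrame(
        [(m, g) for m, genes in bundle["mirna_targets"].items() for g in genes],
        columns=["mirna", "target"],
    ).to_csv(indir / "mirna_targets.tsv", sep="\t", index=False)
    chio.write_gmt(bundle["pathways"], indir / "pathways.gmt")
    chio.write_gmt(bundle["immune"], indir / "immune_signatures.gmt")
    chio.write_truth(bundle["truth"], indir / "truth.json")
    cfg = PipelineConfig(
        expression_a1=str(paths[DATASETS[0]][0]),
        phenotype_a1=str(paths[DATASETS[0]][1]),
        expression_a2=str(paths[DATASETS[1]][0]),
        phenotype_a2=str(paths[DATASETS[1]][1]),
        ppi_edges=str(indir / "ppi_edges.tsv"),
        relevance_table=str(indir / "disease_b_relevance.tsv"),
        curation_table=str(indir / "disease_b_curation.tsv"),
        mirna_list_a=str(indir / "mirna_disease_a.txt"),
        mirna_list_b=str(indir / "mirna_disease_b.txt"),
        mirna_targets=str(indir / "mirna_targets.tsv"),
        pathways_gmt=str(indir / "pathways.gmt"),
        immune_gmt=str(indir / "immune_signatures.gmt"),
        outdir=str(outdir / "results"),
        log_transform=False,  # synthetic expression is already log2-like
        seed=synth_config.seed,
    )
    cfg.to_yaml(outdir / "pipeline.yaml")
    return cfg


# -------------------------------------------------------------------- stages

def _load_dataset(cfg: PipelineConfig, which: int) -> ExpressionMatrix:
    expr_path = cfg.expression_a1 if which == 1 else cfg.expression_a2
    pheno_path = cfg.phenotype_a1 if which == 1 else cfg.phenotype_a2
    if not Path(expr_path).exists():
        raise FileNotFoundError(expr_path)
    raw = chio.read_expression_tsv(expr_path, pheno_path)
    return prep.preprocess(
        raw,
        log_transform=cfg.log_transform,
        collapse=True,
        quantile_norm=cfg.quantile_norm,
    )


def stage_de(cfg: PipelineConfig) -> dict:
    """Both DE configurations on both datasets; direction-consistent sets."""
    sets: dict[str, dict] = {}
    for label, moderated in (("moderated", True), ("ordinary", False)):
        per_ds = []
        for which in (1, 2):
            expr = _load_dataset(cfg, which)
            de = prep.fit_de(expr, moderated=moderated)
            de.table.to_csv(cfg.out("de", f"de_dataset{which}_{label}.tsv"), sep="\t")
            per_ds.append(prep.classify_degs(de, lfc=cfg.lfc, alpha=cfg.alpha))
        up, down = prep.intersect_consistent(per_ds[0], per_ds[1])
        sets[label] = {"up": sorted(up), "down": sorted(down)}
    chio.write_json(sets, cfg.out("de", "deg_sets.json"))
    return sets


def stage_wgcna(cfg: PipelineConfig) -> dict:
    """Per-dataset co-expression modules and the strongest trait module."""
    out: dict[str, dict] = {}
    for which in (1, 2):
        expr = _load_dataset(cfg, which)
        report = coexpr.detect_outlier_samples(expr, n_sigma=cfg.outlier_sigma)
        report.table.to_csv(cfg.out("wgcna", f"outliers_dataset{which}.tsv"), sep="\t")
        expr = expr.subset_samples(report.retained)
        expr = coexpr.select_variable_genes(expr, k=cfg.mad_top)
        scan = coexpr.pick_soft_threshold(
            expr, powers=range(1, cfg.max_power + 1), r2_min=cfg.r2_min
        )
        scan.table.to_csv(cfg.out("wgcna", f"softthreshold_dataset{which}.tsv"), sep="\t")
        adj = coexpr.adjacency(expr, scan.chosen_beta)
        t = coexpr.tom(adj)
        assignment = coexpr.detect_modules(
            1.0 - t, min_module_size=cfg.min_module_size, cut_height=cfg.cut_height
        )
        trait = (expr.sample_group == "case").astype(int)
        assignment = coexpr.complete_assignment(expr, assignment, trait)
        assignment.labels.rename("module").to_csv(
            cfg.out("wgcna", f"modules_dataset{which}.tsv"), sep="\t"
        )
        assignment.module_trait.to_csv(
            cfg.out("wgcna", f"module_trait_dataset{which}.tsv"), sep="\t"
        )
        strongest_genes = assignment.module_genes(assignment.strongest_module)
        out[f"dataset{which}"] = {
            "chosen_beta": scan.chosen_beta,
            "excluded_samples": report.excluded,
            "strongest_module": assignment.strongest_module,
            "strongest_module_genes": sorted(strongest_genes),
            "n_modules": len(assignment.modules),
        }
    chio.write_json(out, cfg.out("wgcna", "summary.json"))
    return out


def stage_sets(cfg: PipelineConfig) -> dict:
    deg_sets = chio.read_json(cfg.out("de", "deg_sets.json"))
    wgcna = chio.read_json(cfg.out("wgcna", "summary.json"))
    disease_a, provenance = disease_sets.derive_disease_a(
        (set(deg_sets["moderated"]["up"]), set(deg_sets["moderated"]["down"])),
        (set(deg_sets["ordinary"]["up"]), set(deg_sets["ordinary"]["down"])),
        wgcna["dataset1"]["strongest_module_genes"],
        wgcna["dataset2"]["strongest_module_genes"],
    )
    relevance = pd.read_csv(cfg.relevance_table, sep="\t")
    curation = pd.read_csv(cfg.curation_table, sep="\t")
    disease_b = disease_sets.filter_disease_b(
        relevance, curation, relevance_min=cfg.relevance_min, pmid_min=cfg.pmid_min
    )
    common = disease_sets.common_hubs(disease_a, disease_b)
    chio.write_gene_list(disease_a, cfg.out("sets", "disease_a_genes.txt"))
    chio.write_gene_list(disease_b, cfg.out("sets", "disease_b_genes.txt"))
    chio.write_gene_list(common, cfg.out("sets", "common_hub_genes.txt"))
    chio.write_json(provenance, cfg.out("sets", "disease_a_provenance.json"))
    result = {
        "disease_a_genes": disease_a,
        "disease_b_genes": disease_b,
        "common_hub_genes": common,
    }
    chio.write_json(result, cfg.out("sets", "summary.json"))
    return result


def _triangulate_disease(cfg: PipelineConfig, graph, label: str) -> list[str]:
    if graph.number_of_nodes() < 3 or graph.number_of_edges() == 0:
        logger.warning("%s PPI subnetwork too small; no key hubs", label)
        return []
    cent = net_mod.centralities(graph)
    cent.to_csv(cfg.out("hubs", f"centrality_{label}.tsv"), sep="\t")
    clusters = net_mod.mcode(
        graph,
        degree_cutoff=cfg.mcode_degree_cutoff,
        k_core=cfg.mcode_k_core,
        node_score_cutoff=cfg.mcode_node_score_cutoff,
        haircut=cfg.mcode_haircut,
        fluff=cfg.mcode_fluff,
    )
    pd.DataFrame(
        [
            {"rank": c.rank, "score": c.score, "n": len(c.members),
             "edges": c.edge_count, "members": ";".join(c.members)}
            for c in clusters
        ]
    ).to_csv(cfg.out("hubs", f"mcode_{label}.tsv"), sep="\t", index=False)
    ranking = net_mod.mcc(graph, top_n=cfg.mcc_top)
    ranking.to_csv(cfg.out("hubs", f"mcc_{label}.tsv"), sep="\t")
    top_cluster = clusters[0] if clusters else None
    return net_mod.triangulate(cent, top_cluster, ranking)


def stage_hubs(cfg: PipelineConfig) -> dict:
    sets = chio.read_json(cfg.out("sets", "summary.json"))
    full = net_mod.load_network(cfg.ppi_edges, min_score=cfg.min_score)
    keys = {}
    for label, genes in (
        ("disease_a", sets["disease_a_genes"]),
        ("disease_b", sets["disease_b_genes"]),
    ):
        sub = full.subgraph([g for g in genes if g in full]).copy()
        sub.remove_nodes_from([n for n in sub if sub.degree(n) == 0])
        keys[label] = _triangulate_disease(cfg, sub, label)
        chio.write_gene_list(keys[label], cfg.out("hubs", f"key_hubs_{label}.txt"))
        chio.write_graphml(sub, cfg.out("hubs", f"network_{label}.graphml"))
    key = disease_sets.key_hubs(keys["disease_a"], keys["disease_b"])
    chio.write_gene_list(key, cfg.out("hubs", "key_hub_genes.txt"))
    result = {**{f"key_{k}": v for k, v in keys.items()}, "key_hub_genes": key}
    chio.write_json(result, cfg.out("hubs", "summary.json"))
    return result


def stage_enrich(cfg: PipelineConfig) -> dict:
    sets = chio.read_json(cfg.out("sets", "summary.json"))
    expr = _load_dataset(cfg, 1)
    universe = set(expr.gene_ids)
    pathways = chio.read_gmt(cfg.pathways_gmt)
    immune = chio.read_gmt(cfg.immune_gmt)
    summary: dict = {}

    ora_tables = {}
    for label in ("disease_a", "disease_b"):
        query = set(sets[f"{label}_genes"]) & universe
        if query:
            res = enrichment.ora(query, pathways, universe)
            res.to_csv(cfg.out("enrich", f"ora_{label}.tsv"), sep="\t")
            ora_tables[label] = res
    if len(ora_tables) == 2:
        shared = enrichment.shared_terms(
            ora_tables["disease_a"], ora_tables["disease_b"], top_n=cfg.shared_top_n
        )
    else:
        shared = []
    chio.write_gene_list(shared, cfg.out("enrich", "shared_terms.txt"))
    summary["shared_terms"] = shared

    # per-hub GSEA: rank genes by high-vs-low median-split contrast in cases
    rng = np.random.default_rng(cfg.seed)
    cases = expr.samples_in_group("case")
    gsea_sig: dict[str, list[str]] = {}
    for hub in sets["common_hub_genes"]:
        if hub not in expr.values.index:
            continue
        split = surv_mod.median_split(expr, hub, samples=cases)
        high = split.index[split == "high"]
        low = split.index[split == "low"]
        ranked = expr.values[list(high)].mean(axis=1) - expr.values[list(low)].mean(axis=1)
        res = enrichment.gsea_collection(
            ranked, pathways, n_perm=cfg.gsea_n_perm, rng=rng,
            nes_min=cfg.nes_min, alpha=cfg.alpha,
        )
        res.to_csv(cfg.out("enrich", f"gsea_{hub}.tsv"), sep="\t")
        gsea_sig[hub] = sorted(res.index[res["significant"]])
    summary["gsea_significant"] = gsea_sig

    scores = enrichment.ssgsea(expr, immune)
    scores.to_csv(cfg.out("enrich", "ssgsea_scores.tsv"), sep="\t")
    infil = enrichment.compare_infiltration(scores, expr.sample_group)
    infil.to_csv(cfg.out("enrich", "infiltration.tsv"), sep="\t")
    summary["infiltration_significant"] = sorted(infil.index[infil["p"] < cfg.alpha])

    hubs_in_expr = [g for g in sets["common_hub_genes"] if g in expr.values.index]
    if hubs_in_expr:
        cors = enrichment.correlate_genes_cells(
            expr.subset_genes(hubs_in_expr), scores,
            cor_min=cfg.cor_min, alpha=cfg.alpha,
        )
        cors.to_csv(cfg.out("enrich", "gene_cell_correlations.tsv"), sep="\t", index=False)
        summary["n_flagged_correlations"] = int(cors["flagged"].sum())
    chio.write_json(summary, cfg.out("enrich", "summary.json"))
    return summary


def stage_survival(cfg: PipelineConfig) -> dict:
    sets = chio.read_json(cfg.out("sets", "summary.json"))
    expr = _load_dataset(cfg, 1)
    if expr.survival is None or expr.survival.empty:
        raise ValueError("dataset 1 phenotype table carries no survival records")
    genes = [g for g in sets["common_hub_genes"] if g in expr.values.index]
    if not genes:
        chio.write_json({"significant_genes": []}, cfg.out("survival", "summary.json"))
        return {"significant_genes": []}
    table = surv_mod.survival_by_gene(
        expr, expr.survival, genes, min_days=cfg.followup_min
    )
    table.to_csv(cfg.out("survival", "logrank_summary.tsv"), sep="\t")
    result = {"significant_genes": sorted(table.index[table["p"] < cfg.alpha])}
    chio.write_json(result, cfg.out("survival", "summary.json"))
    return result


def stage_mirna(cfg: PipelineConfig) -> dict:
    sets = chio.read_json(cfg.out("sets", "summary.json"))
    list_a = chio.read_gene_list(cfg.mirna_list_a)
    list_b = chio.read_gene_list(cfg.mirna_list_b)
    targets_df = pd.read_csv(cfg.mirna_targets, sep="\t")
    target_map: dict[str, list[str]] = {}
    for m, g in zip(targets_df["mirna"], targets_df["target"]):
        target_map.setdefault(str(m), []).append(str(g))
    shared = mirna_mod.shared_mirnas(list_a, list_b)
    edges, unconnected = mirna_mod.hub_targets(
        shared, target_map, sets["common_hub_genes"]
    )
    net = mirna_mod.build_network(cfg.disease_a_name, cfg.disease_b_name, shared, edges)
    mirna_mod.export_network(net, cfg.out("mirna", "network.sif"), "sif")
    mirna_mod.export_network(net, cfg.out("mirna", "network.graphml"), "graphml")
    chio.write_gene_list(shared, cfg.out("mirna", "shared_mirnas.txt"))
    chio.write_gene_list(unconnected, cfg.out("mirna", "unconnected_mirnas.txt"))
    result = {
        "shared_mirnas": shared,
        "n_edges": len(edges),
        "targeted_hubs": sorted({g for _, g in edges}),
        "unconnected_mirnas": unconnected,
    }
    chio.write_json(result, cfg.out("mirna", "summary.json"))
    return result


_STAGES = [
    ("de", stage_de),
    ("wgcna", stage_wgcna),
    ("sets", stage_sets),
    ("hubs", stage_hubs),
    ("enrich", stage_enrich),
    ("survival", stage_survival),
    ("mirna", stage_mirna),
]


def _manifest(outdir: Path) -> dict[str, str]:
    out = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "report.json":
            out[str(p.relative_to(outdir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def run(cfg: PipelineConfig) -> dict:
    """Execute every stage in order and write ``report.json``.

    A stage failure raises StageError naming the stage; outputs of earlier
    stages are retained on disk.
    """
    report: dict = {"config": asdict(cfg), "stages": {}}
    for name, fn in _STAGES:
        logger.info("running stage %s", name)
        try:
            result = fn(cfg)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, str(exc)) from exc
        report["stages"][name] = result
    report["manifest"] = _manifest(Path(cfg.outdir))
    chio.write_json(report, Path(cfg.outdir) / "report.json")
    return report
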