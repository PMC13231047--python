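"""Synthetic two-disease study generator.

Emulates the data structure of a comorbidity hub-gene study without any
downloads: two case/control expression cohorts for the profiled disease
(A) generated from a latent-factor Gaussian block model with planted
co-expression modules and planted direction-consistent DEGs; dual-source
gene-association tables for the literature-mined disease (B) with planted
hub genes above the filtering thresholds and decoys straddling them; a
scored protein-interaction edge table; exponential survival times whose
hazard is log-linear in mean planted-hub expression; miRNA-disease lists
with a planted shared subset targeting the hubs; and GMT gene-set
collections including 28 immune-cell signatures, one of which is
up-shifted in cases.

Expression is emitted on a log2-like scale (baseline around 7) so the
pipeline's log2(x+1) step is toggled off for synthetic input. Every
generator derives its own child seed from the one global seed, so adding
generators never perturbs existing outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SyntheticTruth

__all__ = [
    "SynthConfig",
    "generate_expression",
    "generate_ppi",
    "generate_disease_associations",
    "generate_survival",
    "generate_mirna_maps",
    "generate_signatures",
    "generate_all",
]

DATASETS = ("disease_a_1", "disease_a_2")


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator.

    The defaults are the desk-scale study conditions the test-suite runs
    under: two planted modules of 100 genes at latent correlation 0.8 with
    100 unstructured background genes, 40 case / 40 control samples per
    cohort, log2 effect size 2 for planted DEGs at unit expression SD, and
    6 planted shared hub genes.
    """

    n_genes: int = 300
    n_samples_case: int = 40
    n_samples_control: int = 40
    module_sizes: tuple[int, ...] = (100, 100)
    module_latent_cor: float = 0.8
    n_planted_hubs: int = 6
    n_extra_up: int = 10
    n_extra_down: int = 10
    de_effect_log2: float = 2.0
    noise_sd: float = 1.0
    trait_shift: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 0.5
    survival_hazard_log_hr: float = 1.0
    baseline_hazard: float = 1.0 / 730.0  # per day
    censor_rate: float = 0.3
    ppi_within_module_p: float = 0.3
    ppi_background_p: float = 0.01
    hub_wiring_frac: float = 0.5  # fraction of its module each hub is wired to (>= 0.5)
    n_mirnas: int = 30
    n_shared_mirnas: int = 12
    targets_per_mirna: int = 5
    n_disease_b_extra: int = 40
    n_immune_sets: int = 28
    immune_set_size: int = 10
    n_pathway_decoys: int = 8
    pathway_set_size: int = 30
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_samples_case": self.n_samples_case,
            "n_samples_control": self.n_samples_control,
            "n_planted_hubs": self.n_planted_hubs,
            "n_mirnas": self.n_mirnas,
            "targets_per_mirna": self.targets_per_mirna,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1 (got {v})")
        for name in ("module_latent_cor", "censor_rate", "ppi_within_module_p", "ppi_background_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1] (got {v})")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum(module_sizes) exceeds n_genes")
        if self.n_planted_hubs + self.n_extra_up + self.n_extra_down > self.module_sizes[0]:
            raise ValueError("planted DE genes exceed the first module's size")
        if self.n_shared_mirnas > self.n_mirnas:
            raise ValueError("n_shared_mirnas exceeds n_mirnas")

    # -------------------------------------------------------------- layout

    @property
    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def module_membership(self) -> dict[str, int]:
        genes = self.gene_ids
        membership = {g: 0 for g in genes}
        start = 0
        for m, size in enumerate(self.module_sizes, start=1):
            for g in genes[start : start + size]:
                membership[g] = m
            start += size
        return membership

    def planted_gene_sets(self) -> tuple[list[str], list[str], list[str]]:
        """(hubs, extra up DEGs, extra down DEGs), all inside module 1."""
        genes = self.gene_ids
        h = self.n_planted_hubs
        u = self.n_extra_up
        d = self.n_extra_down
        return genes[:h], genes[h : h + u], genes[h + u : h + u + d]


def _rng(config: SynthConfig, stream: str) -> np.random.Generator:
    key = zlib.adler32(stream.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), key]))


def _make_truth(config: SynthConfig) -> SyntheticTruth:
    hubs, extra_up, extra_down = config.planted_gene_sets()
    de = {g: "up" for g in hubs + extra_up}
    de.update({g: "down" for g in extra_down})
    return SyntheticTruth(
        planted_hubs=list(hubs),
        module_membership=config.module_membership(),
        de_direction=de,
        mirna_targets={},
        association_scores={},
        below_threshold_decoys=[],
        shared_mirnas=[],
    )


def generate_expression(
    config: SynthConfig,
) -> tuple[dict[str, ExpressionMatrix], SyntheticTruth]:
    """Two case/control cohorts for disease A from the latent-factor block
    model: member genes load sqrt(rho) on their module factor and
    sqrt(1-rho) on idiosyncratic noise (scaled by ``noise_sd``); the first
    module's factor is shifted by ``trait_shift`` in cases; planted DEGs
    add +/- ``de_effect_log2`` to case samples."""
    config.validate()
    truth = _make_truth(config)
    membership = truth.module_membership
    genes = config.gene_ids
    rho = config.module_latent_cor
    n_case, n_ctrl = config.n_samples_case, config.n_samples_control
    n_samples = n_case + n_ctrl
    datasets: dict[str, ExpressionMatrix] = {}
    for di, name in enumerate(DATASETS, start=1):
        rng = _rng(config, f"expression:{name}")
        sample_ids = [f"D{di}S{j:03d}" for j in range(1, n_samples + 1)]
        groups = pd.Series(
            ["case"] * n_case + ["control"] * n_ctrl, index=sample_ids
        )
        is_case = np.array([g == "case" for g in groups])
        baseline = rng.normal(config.baseline_mean, config.baseline_sd, len(genes))
        factors = rng.standard_normal((config.n_modules, n_samples))
        factors[0, is_case] += config.trait_shift
        eps = rng.standard_normal((len(genes), n_samples))
        x = np.empty((len(genes), n_samples))
        for gi, g in enumerate(genes):
            m = membership[g]
            if m == 0:
                signal = eps[gi]
            else:
                signal = np.sqrt(rho) * factors[m - 1] + np.sqrt(1.0 - rho) * eps[gi]
            x[gi] = baseline[gi] + config.noise_sd * signal
            d = truth.de_direction.get(g)
            if d == "up":
                x[gi, is_case] += config.de_effect_log2
            elif d == "down":
                x[gi, is_case] -= config.de_effect_log2
        datasets[name] = ExpressionMatrix(
            pd.DataFrame(x, index=genes, columns=sample_ids), groups
        )
    return datasets, truth


def generate_ppi(truth: SyntheticTruth, config: SynthConfig) -> pd.DataFrame:
    """STRING-dialect edge table: within-module pairs with probability
    ``ppi_within_module_p``, other pairs with ``ppi_background_p``;
    planted hubs additionally wired to at least half their module;
    combined scores uniform integers in [400, 1000]."""
    rng = _rng(config, "ppi")
    genes = config.gene_ids
    membership = truth.module_membership
    edges: set[tuple[str, str]] = set()
    n = len(genes)
    for i in range(n):
        gi = genes[i]
        mi = membership[gi]
        for j in range(i + 1, n):
            gj = genes[j]
            p = (
                config.ppi_within_module_p
                if mi != 0 and membership[gj] == mi
                else config.ppi_background_p
            )
            if p > 0 and rng.random() < p:
                edges.add((gi, gj))
    for hub in truth.planted_hubs:
        m = membership[hub]
        members = [g for g in genes if membership[g] == m and g != hub]
        frac = max(0.5, config.hub_wiring_frac)
        n_wire = int(np.ceil(frac * len(members)))
        for g in rng.choice(members, size=n_wire, replace=False):
            edges.add(tuple(sorted((hub, g))))
    rows = [
        (a, b, int(rng.integers(400, 1001))) for a, b in sorted(edges)
    ]
    return pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])


def generate_disease_associations(
    truth: SyntheticTruth, config: SynthConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dual-source association tables for disease B.

    Planted hubs pass both filters (relevance >= 10, PMIDs > 0); the extra
    planted DEGs become below-threshold decoys (each fails exactly one
    filter); a configured number of background genes pass both filters
    (disease-B-only genes); a few background genes appear in one source
    only."""
    rng = _rng(config, "associations")
    hubs, extra_up, extra_down = config.planted_gene_sets()
    genes = config.gene_ids
    background = [g for g in genes if truth.module_membership[g] == 0]
    extras = list(
        rng.choice(background, size=min(config.n_disease_b_extra, len(background)), replace=False)
    )
    single_source = [g for g in background if g not in extras][:5]

    rel_rows, cur_rows = [], []
    for g in hubs + extras:
        rel = float(np.round(rng.uniform(10.0, 50.0), 2))
        pm = int(rng.integers(1, 25))
        rel_rows.append((g, rel))
        cur_rows.append((g, pm))
        truth.association_scores[g] = {"relevance": rel, "pmid_count": pm}
    decoys = list(extra_up) + list(extra_down)
    for i, g in enumerate(decoys):
        if i % 2 == 0:  # fails the relevance filter, passes the PMID one
            rel = float(np.round(rng.uniform(5.0, 9.99), 2))
            pm = int(rng.integers(1, 10))
        else:  # passes relevance, fails PMIDs
            rel = float(np.round(rng.uniform(10.0, 30.0), 2))
            pm = 0
        rel_rows.append((g, rel))
        cur_rows.append((g, pm))
        truth.association_scores[g] = {"relevance": rel, "pmid_count": pm}
    for g in single_source:
        rel_rows.append((g, float(np.round(rng.uniform(10.0, 30.0), 2))))
    truth.below_threshold_decoys = decoys
    relevance = pd.DataFrame(rel_rows, columns=["gene_id", "relevance"])
    relevance.insert(1, "source", "relevance_source")
    curation = pd.DataFrame(cur_rows, columns=["gene_id", "pmid_count"])
    curation.insert(1, "source", "curation_source")
    return relevance, curation


def generate_survival(
    expr: ExpressionMatrix, truth: SyntheticTruth, config: SynthConfig
) -> pd.DataFrame:
    """Exponential survival for the case samples: hazard
    h0 * exp(beta * z) with z the standardized mean planted-hub expression
    and beta = ``survival_hazard_log_hr``; censored records (probability
    ``censor_rate``) are cut at a uniform fraction of the true time."""
    rng = _rng(config, "survival")
    cases = expr.samples_in_group("case")
    hub_expr = expr.values.loc[truth.planted_hubs, cases].mean(axis=0)
    z = (hub_expr - hub_expr.mean()) / hub_expr.std(ddof=1)
    rows = []
    for s in cases:
        hazard = config.baseline_hazard * np.exp(config.survival_hazard_log_hr * z[s])
        t = rng.exponential(1.0 / hazard)
        if rng.random() < config.censor_rate:
            t *= 1.0 - rng.random()  # fraction in (0, 1]
            event = 0
        else:
            event = 1
        rows.append((s, float(t), event))
    return pd.DataFrame(rows, columns=["sample_id", "time_days", "event"]).set_index(
        "sample_id"
    )


def generate_mirna_maps(
    truth: SyntheticTruth, config: SynthConfig
) -> tuple[list[str], list[str], dict[str, list[str]]]:
    """Two disease miRNA lists with a planted shared subset, plus a
    miRNA -> target map in which every shared miRNA targets at least one
    planted hub."""
    rng = _rng(config, "mirna")
    mirnas = [f"mir-{i:04d}" for i in range(1, config.n_mirnas + 1)]
    shared = mirnas[: config.n_shared_mirnas]
    rest = mirnas[config.n_shared_mirnas :]
    half = len(rest) // 2
    list_a = shared + rest[:half]
    list_b = shared + rest[half:]
    genes = config.gene_ids
    non_hub = [g for g in genes if g not in truth.planted_hubs]
    targets: dict[str, list[str]] = {}
    for i, m in enumerate(mirnas):
        picked = set(rng.choice(non_hub, size=config.targets_per_mirna, replace=False))
        if m in shared:
            picked.add(truth.planted_hubs[i % len(truth.planted_hubs)])
        targets[m] = sorted(picked)
    truth.mirna_targets = targets
    truth.shared_mirnas = list(shared)
    return list_a, list_b, targets


def generate_signatures(
    truth: SyntheticTruth, config: SynthConfig
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """(pathway collection, immune collection).

    The immune collection has exactly ``n_immune_sets`` signatures; the
    first is drawn from the planted up-regulated genes so it is up-shifted
    in case samples. The pathway collection has one set per planted module
    plus random decoy sets."""
    rng = _rng(config, "signatures")
    hubs, extra_up, _ = config.planted_gene_sets()
    up_genes = list(hubs) + list(extra_up)
    genes = config.gene_ids
    null_pool = [
        g
        for g in genes
        if g not in truth.de_direction  # exclude planted DEGs from null sets
    ]
    immune: dict[str, list[str]] = {}
    size = config.immune_set_size
    immune["immune_cell_01"] = sorted(
        rng.choice(up_genes, size=min(size, len(up_genes)), replace=False)
    )
    for i in range(2, config.n_immune_sets + 1):
        immune[f"immune_cell_{i:02d}"] = sorted(
            rng.choice(null_pool, size=size, replace=False)
        )
    pathways: dict[str, list[str]] = {}
    for m in range(1, config.n_modules + 1):
        members = [g for g in genes if truth.module_membership[g] == m]
        pathways[f"pathway_module_{m}"] = sorted(
            rng.choice(members, size=min(config.pathway_set_size, len(members)), replace=False)
        )
    for d in range(1, config.n_pathway_decoys + 1):
        pathways[f"pathway_decoy_{d}"] = sorted(
            rng.choice(null_pool, size=min(config.pathway_set_size, len(null_pool)), replace=False)
        )
    return pathways, immune


def generate_all(config: SynthConfig) -> dict:
    """Run every generator; returns a bundle dict plus the shared truth."""
    datasets, truth = generate_expression(config)
    ppi = generate_ppi(truth, config)
    relevance, curation = generate_disease_associations(truth, config)
    surv = generate_survival(datasets[DATASETS[0]], truth, config)
    ds1 = datasets[DATASETS[0]]
    ds1.survival = surv
    list_a, list_b, targets = generate_mirna_maps(truth, config)
    pathways, immune = generate_signatures(truth, config)
    return {
        "datasets": datasets,
        "truth": truth,
        "ppi": ppi,
        "relevance": relevance,
        "curation": curation,
        "survival": surv,
        "mirna_list_a": list_a,
        "mirna_list_b": list_b,
        "mirna_targets": targets,
        "pathways": pathways,
        "immune": immune,
    }
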