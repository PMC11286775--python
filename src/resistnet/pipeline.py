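"""End-to-end orchestration: filter -> contrasts -> activity -> comparison ->
seeds -> network integration -> clustering -> enrichment -> optional cohort
and synergy arms.  Every intermediate table is written as TSV and a plain-
text summary report collects the headline numbers; all randomness flows
from named seeds in the config."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity as activity_mod
from . import compare as compare_mod
from . import diffexp, enrich, network
from . import synergy as synergy_mod
from .dataio import read_gmt, read_matrix, read_ppi_edges, read_regulons

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    counts: str | None = None
    proteins: str | None = None
    metadata: str | None = None
    regulons: str | None = None
    ppi: str | None = None
    gene_sets: str | None = None
    cohort: str | None = None
    cohort_metadata: str | None = None
    synergy_single: list = field(default_factory=list)
    synergy_combo: str | None = None
    contrasts: list = field(default_factory=list)  # list of [A, B]
    fdr: float = 0.10
    nes_min: float = 5.0
    ppi_score: float = 0.4
    ora_min_size: int = 40
    ora_alpha: float = 0.05
    min_count: int = 10
    min_fraction: float = 0.2
    n_null_networks: int = 10
    gsea_n_perm: int = 2000
    seed_rewire: int = 11
    seed_louvain: int = 12
    seed_gsea: int = 13
    outdir: str = "pipeline_out"

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1 or not 0 <= self.ppi_score <= 1:
            raise ValueError("threshold out of range")
        if not 0 < self.min_fraction <= 1 or not 0 < self.ora_alpha < 1:
            raise ValueError("threshold out of range")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _log2_matrix(mat):
    from .dataio import ExpressionMatrix

    vals = mat.data.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logged = np.where(vals > 0, np.log2(np.maximum(vals, 1e-300)), np.nan)
    return ExpressionMatrix(
        pd.DataFrame(logged, index=mat.data.index, columns=mat.data.columns),
        mat.conditions,
        "intensity",
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every configured stage; returns the report directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: list[str] = ["# Pipeline report", ""]
    stage = "setup"
    try:
        rna_contrasts, prot_contrasts, activities = {}, {}, {}
        if config.counts:
            stage = "rna-diffexp"
            counts = read_matrix(config.counts, "count", config.metadata)
            counts = diffexp.filter_features(counts, config.min_count, config.min_fraction)
            factors = diffexp.size_factors(counts)
            factors.to_csv(out / "size_factors.tsv", sep="\t")
            report += ["## RNA differential expression", f"features after filter: {len(counts.feature_ids)}"]
            for a, b in config.contrasts:
                res = diffexp.nb_contrast(counts, pair=(a, b), factors=factors)
                res.write(out / f"rna_{a}_vs_{b}.tsv")
                rna_contrasts[(a, b)] = res
                report.append(f"DEGs (q<{config.fdr}) {b} vs {a}: {len(res.significant(config.fdr))}")
        if config.proteins:
            stage = "protein-diffexp"
            prot = read_matrix(config.proteins, "intensity", config.metadata)
            prot = diffexp.quantile_normalize(_log2_matrix(prot))
            report += ["", "## Protein differential expression"]
            for a, b in config.contrasts:
                res = diffexp.lm_contrast(prot, pair=(a, b))
                res.write(out / f"protein_{a}_vs_{b}.tsv")
                prot_contrasts[(a, b)] = res
                report.append(
                    f"DE proteins (q<{config.fdr}) {b} vs {a}: {len(res.significant(config.fdr))}"
                )
        if config.regulons and rna_contrasts:
            stage = "activity"
            regulons = read_regulons(config.regulons)
            report += ["", "## Virtual protein activity"]
            for pair, res in rna_contrasts.items():
                sig = activity_mod.make_signature(res)
                act = activity_mod.viper_contrast(
                    sig, regulons, fdr=config.fdr, nes_min=config.nes_min
                )
                act.write(out / f"activity_{pair[0]}_vs_{pair[1]}.tsv")
                activities[pair] = act
                report.append(
                    f"activated regulators {pair[1]} vs {pair[0]}: "
                    f"{len(act.significant_regulators())}"
                )
        if len(rna_contrasts) >= 2:
            stage = "compare"
            report += ["", "## Contrast comparison"]
            sig_sets = {
                f"{a}_vs_{b}": rna_contrasts[(a, b)].significant(config.fdr)
                for a, b in rna_contrasts
            }
            ji = compare_mod.pairwise_jaccard(sig_sets)
            ji.to_csv(out / "jaccard_matrix.tsv", sep="\t")
            universe = len(next(iter(rna_contrasts.values())).table)
            for (pa, pb) in itertools.combinations(rna_contrasts, 2):
                ov = compare_mod.overlap_test(
                    rna_contrasts[pa].significant(config.fdr),
                    rna_contrasts[pb].significant(config.fdr),
                    universe,
                )
                r, p = compare_mod.foldchange_correlation(rna_contrasts[pa], rna_contrasts[pb])
                report.append(
                    f"{pa} vs {pb}: JI={ov.jaccard:.3f} (P={ov.pval:.3g}), R={r:.3f} (P={p:.3g})"
                )
        if config.ppi and activities and prot_contrasts:
            stage = "integration"
            ppi = read_ppi_edges(config.ppi, config.ppi_score)
            report += ["", "## Network integration"]
            cluster_sets = {}
            for pair in activities:
                if pair not in prot_contrasts:
                    continue
                seeds = network.select_seeds(
                    prot_contrasts[pair], activities[pair], config.fdr, config.nes_min
                )
                seeds.table.to_csv(out / f"seeds_{pair[0]}_vs_{pair[1]}.tsv", sep="\t")
                report.append(f"seeds {pair[1]} vs {pair[0]}: {len(seeds)}")
                if len([s for s in seeds.proteins if s in ppi]) < 2:
                    report.append("  (fewer than 2 seeds on the PPI; integration skipped)")
                    continue
                prot_sig = prot_contrasts[pair].significant(config.fdr)
                act_sig = activities[pair].significant_regulators()
                directions = {
                    f: ("up" if v > 0 else "down")
                    for f, v in prot_contrasts[pair].log2fc.dropna().items()
                    if f in prot_sig
                }
                graph = network.geodesic_subgraph(
                    ppi, seeds, directions=directions, significant=prot_sig | act_sig
                )
                graph.nodes.to_csv(out / f"subgraph_nodes_{pair[0]}_vs_{pair[1]}.tsv", sep="\t")
                nulls = network.rewire_null(
                    ppi, config.n_null_networks, seed=config.seed_rewire
                )
                null_sizes = []
                for g0 in nulls:
                    try:
                        null_sizes.append(
                            network.geodesic_subgraph(g0, seeds).graph.number_of_nodes()
                        )
                    except ValueError:
                        continue
                ov = network.subgraph_enrichment(
                    graph, prot_sig | act_sig, set(ppi.nodes), seeds, null_sizes
                )
                emp = getattr(ov, "empirical_size_p", float("nan"))
                report.append(
                    f"  subgraph: {graph.graph.number_of_nodes()} nodes / "
                    f"{graph.graph.number_of_edges()} edges; enrichment OR={ov.odds_ratio:.3f} "
                    f"(P={ov.pval:.3g}; empirical size P={emp:.3g})"
                )
                clusters = network.louvain_cluster(graph, seed=config.seed_louvain)
                clusters.activity.to_csv(
                    out / f"clusters_{pair[0]}_vs_{pair[1]}.tsv", sep="\t"
                )
                cluster_sets[pair] = clusters
                report.append(
                    f"  clusters: {len(clusters.clusters)} (Q={clusters.modularity:.3f}); "
                    f"labels: {list(clusters.activity['label'])}"
                )
            if len(cluster_sets) >= 2:
                pa, pb = list(cluster_sets)[:2]
                mat, best = network.match_clusters(cluster_sets[pa], cluster_sets[pb])
                mat.to_csv(out / "cluster_match_jaccard.tsv", sep="\t")
                report.append(f"  cluster matching {pa} -> {pb}: {best}")
        if config.cohort and config.gene_sets:
            stage = "cohort"
            cohort = read_matrix(config.cohort, "intensity", config.cohort_metadata)
            sets = read_gmt(config.gene_sets)
            report += ["", "## Cohort enrichment"]
            lv = sorted(cohort.conditions.unique())  # ranking = second level over first
            res = diffexp.lm_contrast(cohort, pair=(lv[0], lv[1]))
            ranking = res.log2fc.dropna()
            for name, members in sets.items():
                gres = enrich.gsea_preranked(
                    ranking, members, name, n_perm=config.gsea_n_perm, seed=config.seed_gsea
                )
                report.append(
                    f"GSEA {name}: NES={gres.nes:.3f}, P={gres.pval:.3g}, "
                    f"leading edge {len(gres.leading_edge)}/{gres.set_size}"
                )
                if len(gres.leading_edge) >= 2:
                    scores = enrich.gsva_scores(cohort, {name: set(gres.leading_edge)})
                    scores.scores.to_csv(out / f"gsva_{name}.tsv", sep="\t")
                    p = enrich.score_group_test(scores)
                    report.append(f"  leading-edge activity score group test: P={p:.3g}")
        if config.synergy_single and config.synergy_combo:
            stage = "synergy"
            report += ["", "## Drug synergy"]
            fits = []
            for path in config.synergy_single:
                df = pd.read_csv(path, sep="\t")
                dr = synergy_mod.DoseResponse(
                    str(df["drug"].iloc[0]), df["dose_nM"].to_numpy(), df["viability"].to_numpy()
                )
                fit = synergy_mod.median_effect_fit(dr)
                fits.append(fit)
                report.append(f"{fit.drug}: m={fit.m:.3f}, Dm(IC50)={fit.dm:.1f} nM, r={fit.r:.4f}")
            combo_df = pd.read_csv(config.synergy_combo, sep="\t")
            combos = [
                synergy_mod.ComboMeasurement(r.doseA_nM, r.doseB_nM, r.viability)
                for r in combo_df.itertuples()
            ]
            result = synergy_mod.combination_index(fits[0], fits[1], combos)
            result.table.to_csv(out / "combination_index.tsv", sep="\t", index=False)
            report.append(f"CI per point: {[round(c, 3) for c in result.table['ci']]}")
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        (out / "report.txt").write_text("\n".join(report) + "\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    (out / "report.txt").write_text("\n".join(report) + "\n")
    return out
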