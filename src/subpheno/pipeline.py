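"""End-to-end orchestration of the simulated subphenotype-to-genotype run.

``run_pipeline`` executes the stages in dependency order on a generated
workspace: growth classification, trio de novo filtering, network
expansion with ontology enrichment, morphometric comparisons, and the
single-cell expression-shift analysis. Each output directory carries a
provenance record (configuration hash, seed, per-file checksums) and a
summary report; reruns under the same configuration and seed are
byte-identical and idempotent.

The demo workspace is deliberately smaller than the generator defaults
(fewer trio variants, a reduced count matrix) so a full run with report
completes in seconds; stage-level entry points accept full-size inputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import anndata as ad
import pandas as pd

from . import growth, morpho, network, scshift, simulate, trios
from .config import PipelineConfig

__all__ = ["demo_sim_config", "run_pipeline"]


def demo_sim_config(seed: int = 0) -> simulate.SimConfig:
    """Generator settings for the quick demo workspace."""
    return simulate.SimConfig(
        seed=seed,
        cohort=simulate.CohortConfig(n_probands=600),
        trios=simulate.TrioConfig(n_families=2, n_inherited=500, n_denovo=20),
        edges=simulate.EdgeConfig(n_genes=200, n_seeds=12),
        morpho=simulate.MorphoConfig(),
        sc=simulate.ScConfig(n_cells_per_condition=250, n_genes=600,
                             n_clusters=3, target_set_size=30),
    )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(
    config: PipelineConfig,
    outdir,
    sim_config: simulate.SimConfig | None = None,
) -> dict:
    """Run the requested stages into ``outdir`` and return the report dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    sim_config = sim_config or demo_sim_config(seed)
    report: dict = {"config_hash": config.hash, "seed": seed, "stages": {}}

    sim_dir = outdir / "inputs"
    growth_files = simulate.gen_growth_cohort(sim_config.cohort, sim_dir / "growth", seed)
    trio_files = simulate.gen_trio_vcf(sim_config.trios, sim_dir / "trios", seed + 1)
    net_files = simulate.gen_edges_and_morpho(
        sim_config.edges, sim_config.morpho, sim_dir / "network_morpho", seed + 2)
    sc_files = simulate.gen_sc_counts(
        sim_config.sc, sim_dir / "sc", seed + 3,
        conditions=("knockdown", "kd_control", "overexpression", "oe_control"),
        effect_conditions=("overexpression",),
    )
    report["stages"]["simulate"] = {"workspace": sim_dir.name}

    if "classify" in config.stages:
        hc = growth.GrowthReferenceTable.from_tsv(growth_files["reference"],
                                                  "head_circumference_cm")
        ht = growth.GrowthReferenceTable.from_tsv(growth_files["reference"], "height_cm")
        ratio = growth.GrowthReferenceTable.from_tsv(growth_files["reference"],
                                                     "cv_height_ratio")
        cohort = pd.read_csv(growth_files["cohort"], sep="\t")
        calls = growth.classify_cohort(
            cohort, hc, ht, ratio,
            threshold_sd=config.threshold_sd, so_percentile=config.so_percentile,
            ratio_cutoff=config.ratio_cutoff,
        )
        calls_path = outdir / "subphenotype_calls.tsv"
        calls.to_csv(calls_path, sep="\t", index=False, float_format="%.6f")
        counts = calls["subtype"].value_counts().to_dict()
        report["stages"]["classify"] = {
            "n_probands": int(len(calls)),
            "n_macrocephaly": int(calls["macrocephaly"].sum()),
            "n_megalencephaly": int(calls["megalencephaly"].fillna(False).sum()),
            "subtype_counts": {k: int(v) for k, v in sorted(counts.items())},
            "output": calls_path.name,
        }

    if "denovo" in config.stages:
        annotation = trios.read_annotation_tsv(trio_files["annotation"])
        all_qualifying = []
        for fam_id, vcf_path in sorted(trio_files["vcfs"].items()):
            variants, samples = trios.read_trio_vcf(vcf_path)
            family = trios.TrioFamily(fam_id, *samples[:3])
            normalized = [w for v in variants for w in trios.normalize_variant(v)]
            annotated = trios.annotate_variants(normalized, annotation)
            denovo = trios.find_denovo(annotated, family)
            qualifying = [
                v for v in denovo
                if trios.is_lgd(v.consequence) and trios.is_rare(v, config.max_af)
            ]
            all_qualifying.extend(qualifying)
        cnvs = trios.filter_cnvs(trios.read_cnv_tsv(trio_files["cnvs"]))
        pli_map = pd.read_csv(trio_files["pli"], sep="\t").set_index("gene")["pli"].to_dict()
        candidates = trios.aggregate_candidates(
            all_qualifying, cnvs, pli_map, pli_cutoff=config.pli_cutoff,
            cohort="simulated")
        cand_path = outdir / "candidate_genes.tsv"
        candidates.to_csv(cand_path, sep="\t", index=False, float_format="%.6g")
        stats_report = trios.burden_tests({
            "carrier_rate_vs_controls": {
                "kind": "carrier_rate",
                "carriers_a": int(len({v.proband_id for v in all_qualifying})),
                "n_a": len(trio_files["vcfs"]),
                "carriers_b": max(len(trio_files["vcfs"]) // 2, 1),
                "n_b": len(trio_files["vcfs"]),
            },
        })
        stats_path = outdir / "burden_stats.json"
        _write_json(stats_path, stats_report)
        report["stages"]["denovo"] = {
            "n_qualifying_variants": len(all_qualifying),
            "n_candidate_genes": int(len(candidates)),
            "n_cnvs_included": len(cnvs),
            "output": cand_path.name,
        }

    if "network" in config.stages:
        edges = network.read_edge_tsv(net_files["edges"],
                                      min_score=config.min_combined_score)
        seeds = [s for s in Path(net_files["seeds"]).read_text().split() if s]
        nodes, induced = network.expand_network(seeds, edges, k=config.top_k)
        nodes_path = outdir / "network_nodes.tsv"
        nodes.to_csv(nodes_path, sep="\t", index=False)
        induced.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
        terms = network.read_annotation_tsv(net_files["terms"])
        background = sorted(edges.genes | {t for term in terms for t in term.genes})
        enrichment = network.enrich_terms(set(nodes["gene"]) & set(background),
                                          terms, background)
        enr_path = outdir / "term_enrichment.tsv"
        enrichment.to_csv(enr_path, sep="\t", index=False, float_format="%.6g")
        pooled = {t.term_id: set(t.genes) for t in terms}
        frac, covered, total = network.ontology_coverage(seeds, pooled)
        report["stages"]["network"] = {
            "n_nodes": int(len(nodes)),
            "n_seeds": len(seeds),
            "top_term": str(enrichment.iloc[0]["term_id"]) if len(enrichment) else None,
            "seed_ontology_coverage": f"{covered}/{total}",
            "output": enr_path.name,
        }

    if "morpho" in config.stages:
        table = morpho.load_feature_tsv(net_files["morpho"])
        features = ["total_area", "body_length", "eye_distance", "telencephalon_width"]
        comparisons = morpho.compare_features(
            table, features, "test", "control", m=config.bonferroni_family)
        morpho_path = outdir / "morpho_comparisons.tsv"
        comparisons.to_csv(morpho_path, sep="\t", index=False, float_format="%.6g")
        report["stages"]["morpho"] = {
            "n_significant": int((comparisons["p_adjusted"] <= config.alpha).sum()),
            "comparisons": int(len(comparisons)),
            "output": morpho_path.name,
        }

    if "sc" in config.stages:
        per_cond = []
        for cond, files in sorted(sc_files["conditions"].items()):
            per_cond.append(scshift.read_condition_mtx(
                files["counts"], files["cells"], files["genes"]))
        adata = ad.concat(per_cond, merge="same")
        adata.obs_names_make_unique()
        adata = scshift.qc_filter(
            adata, mito_ribo_max=config.mito_ribo_max,
            min_features=config.min_features, nfeat_sd=config.nfeat_sd)
        adata = scshift.normalize(adata, n_variable=config.n_variable_genes)
        k = min(config.k_broad, adata.n_obs)
        adata = scshift.cluster_cells(adata, n_pcs=config.n_pcs, k=k)
        adata.obs.reset_index().rename(columns={"index": "cell_id"}).to_csv(
            outdir / "cell_clusters.tsv", sep="\t", index=False, float_format="%.6f")
        targets = [t for t in Path(sc_files["targets"]).read_text().split() if t]
        model_results = {}
        fc_tables = {}
        for model, (test, ctl) in {"kd": ("knockdown", "kd_control"),
                                   "oe": ("overexpression", "oe_control")}.items():
            sub = adata[adata.obs["condition"].isin([test, ctl])].copy()
            sub = scshift.downsample_to_match(sub, test, ctl, seed=seed + 7)
            de = scshift.de_wilcoxon(
                sub, test, ctl, logfc_floor=config.logfc_floor,
                min_pct=config.min_pct_de)
            de.to_csv(outdir / f"de_{model}.tsv", sep="\t", index=False,
                      float_format="%.6g")
            expressed = scshift.average_log2fc(
                sub, test, ctl, expression_floor=config.expression_floor)
            fc_tables[model] = expressed
            enr = scshift.target_set_enrichment(
                de, targets, expressed["gene"], alpha=config.alpha)
            model_results[model] = {"n_degs": int(len(de[de["p_adj"] <= config.alpha])),
                                    "enrichment": enr}
        shift = scshift.build_shift_table(fc_tables["kd"], fc_tables["oe"], targets)
        shift.to_csv(outdir / "shift_table.tsv", sep="\t", index=False,
                     float_format="%.6g")
        shift_stats = scshift.geneset_shift_test(shift)
        report["stages"]["sc"] = {
            "n_cells_post_qc": int(adata.n_obs),
            "models": model_results,
            "shift_test": shift_stats,
        }

    # provenance over every emitted file
    checksums = {
        str(p.relative_to(outdir)): _checksum(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name not in ("provenance.json", "report.json", "report.txt")
    }
    _write_json(outdir / "provenance.json", {
        "config": config.to_dict(), "config_hash": config.hash,
        "sim_config": sim_config.to_dict(), "checksums": checksums,
    })
    _write_json(outdir / "report.json", report)
    lines = [f"subpheno pipeline report (config {config.hash}, seed {seed})", ""]
    for stage, info in report["stages"].items():
        lines.append(f"[{stage}]")
        lines += [f"  {k}: {v}" for k, v in info.items()]
        lines.append("")
    (outdir / "report.txt").write_text("\n".join(lines))
    return report
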