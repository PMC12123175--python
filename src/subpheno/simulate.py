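"""Synthetic-data generators with machine-readable ground truth.

Every pipeline input — growth reference curves and proband anthropometry,
trio VCFs with annotation and CNV tables, scored interaction edge tables
with ontology annotations, larval morphometric feature tables, and
clustered negative-binomial single-cell count matrices — can be generated
here with known truth, so each stage is testable without any external
download. All generators are deterministic under their seed and write the
exact file dialects the pipeline readers consume (VCF 4.2, Matrix Market,
TSV).

Defaults emulate the study conditions the pipeline was designed for: a
cohort of 1847 probands with a planted macrocephalic fraction, six trio
families with 5000 inherited and 50 de novo variants each, ~4% planted
multiplicative shifts on larval features at 35 larvae per group, and
negative-binomial counts (dispersion 0.5) for 500 cells per condition over
2000 genes with a 0.8x planted downshift on a 50-gene target set in the
overexpression-analog condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.io import mmwrite

__all__ = [
    "CohortConfig",
    "TrioConfig",
    "EdgeConfig",
    "MorphoConfig",
    "ScConfig",
    "SimConfig",
    "gen_growth_cohort",
    "gen_trio_vcf",
    "gen_edges_and_morpho",
    "gen_sc_counts",
]


@dataclass
class CohortConfig:
    n_probands: int = 1847
    macro_fraction: float = 0.36
    hc_height_correlation: float = 0.3


@dataclass
class TrioConfig:
    n_families: int = 6
    n_inherited: int = 5000
    n_denovo: int = 50
    lgd_fraction: float = 0.2
    af_beta: tuple = (0.3, 8.0)
    af_zero_mass: float = 0.3
    n_cnvs_per_family: int = 4


@dataclass
class EdgeConfig:
    n_genes: int = 400
    mean_degree: float = 6.0
    score_range: tuple = (150, 999)
    n_seeds: int = 20
    n_terms: int = 15
    term_size: int = 25


@dataclass
class MorphoConfig:
    n_per_group: int = 35
    effects: dict = field(default_factory=lambda: {
        "total_area": 0.95,
        "body_length": 0.96,
        "eye_distance": 0.97,
        "telencephalon_width": 0.97,
        "head_trunk_angle": 1.0,
    })
    noise_cv: float = 0.02


@dataclass
class ScConfig:
    n_cells_per_condition: int = 500
    n_genes: int = 2000
    n_clusters: int = 5
    nb_dispersion: float = 0.5
    target_set_size: int = 50
    target_effect: float = 0.8
    n_samples_per_condition: int = 3
    qc_violator_fraction: float = 0.03


@dataclass
class SimConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    trios: TrioConfig = field(default_factory=TrioConfig)
    edges: EdgeConfig = field(default_factory=EdgeConfig)
    morpho: MorphoConfig = field(default_factory=MorphoConfig)
    sc: ScConfig = field(default_factory=ScConfig)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# growth cohort

FEATURE_BASELINES = {  # plausible 3-dpf larval scales (mm, mm^2, degrees)
    "total_area": 2.6,
    "body_length": 3.5,
    "eye_distance": 0.48,
    "telencephalon_width": 0.30,
    "head_trunk_angle": 65.0,
    "midbrain_area": 0.042,
    "forebrain_area": 0.021,
}


def _reference_frame() -> pd.DataFrame:
    """Smooth synthetic reference curves shaped like published standards.

    Head circumference and height means rise monotonically from 4 to 17
    years; SDs grow mildly with age. The cerebral-volume-to-height ratio
    reference is flat-ish around 12 cm^3/cm. All three measures are emitted
    in a single long table keyed by ``measure``.
    """
    ages = np.arange(48, 205, 12, dtype=float)  # months, 4-17 y
    t = (ages - ages[0]) / (ages[-1] - ages[0])
    rows = []
    for sex, hc0, hc1, ht0, ht1 in (("M", 51.0, 56.5, 103.0, 176.0),
                                    ("F", 50.1, 55.4, 102.0, 163.0)):
        for age, ti in zip(ages, t):
            rows.append(("head_circumference_cm", sex, age,
                         hc0 + (hc1 - hc0) * (1 - (1 - ti) ** 2), 1.4 + 0.3 * ti))
            rows.append(("height_cm", sex, age,
                         ht0 + (ht1 - ht0) * ti, 4.3 + 3.2 * ti))
            rows.append(("cv_height_ratio", sex, age, 12.0 - 2.0 * ti, 1.1))
    return pd.DataFrame(rows, columns=["measure", "sex", "age_months", "mean", "sd"])


def gen_growth_cohort(cfg: CohortConfig, outdir, seed: int) -> dict:
    """Write growth reference + proband cohort TSVs with planted macrocephaly.

    Probands draw (head-circumference, height) z-scores from a bivariate
    normal with the configured correlation; the planted macrocephalic
    fraction instead draws its head-circumference z from the truncated
    normal tail above 1.5 SD. A cerebral-volume measurement consistent with
    a z-score correlated with head size is attached so the megalencephaly
    call is exercised too.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    ref = _reference_frame()
    ref_path = outdir / "growth_reference.tsv"
    ref.to_csv(ref_path, sep="\t", index=False)

    n = cfg.n_probands
    sex = rng.choice(["M", "F"], size=n)
    age = rng.uniform(48, 204, size=n)
    planted = rng.random(n) < cfg.macro_fraction
    rho = cfg.hc_height_correlation
    z_hc = rng.standard_normal(n)
    z_hc[planted] = stats.truncnorm.ppf(rng.random(planted.sum()), 1.5, np.inf)
    z_ht = rho * z_hc + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    z_ratio = 0.8 * z_hc + 0.6 * rng.standard_normal(n)

    def interp(measure, sex_i, age_i):
        sub = ref[(ref["measure"] == measure) & (ref["sex"] == sex_i)]
        a = sub["age_months"].to_numpy()
        return (np.interp(age_i, a, sub["mean"].to_numpy()),
                np.interp(age_i, a, sub["sd"].to_numpy()))

    hc = np.empty(n)
    ht = np.empty(n)
    cv = np.empty(n)
    for i in range(n):
        m, s = interp("head_circumference_cm", sex[i], age[i])
        hc[i] = m + z_hc[i] * s
        m, s = interp("height_cm", sex[i], age[i])
        ht[i] = m + z_ht[i] * s
        m, s = interp("cv_height_ratio", sex[i], age[i])
        cv[i] = (m + z_ratio[i] * s) * ht[i]

    ids = [f"P{i:05d}" for i in range(n)]
    cohort = pd.DataFrame({
        "proband_id": ids, "sex": sex, "age_months": age,
        "head_circumference_cm": hc, "height_cm": ht, "cerebral_volume_cm3": cv,
    })
    cohort_path = outdir / "cohort.tsv"
    cohort.to_csv(cohort_path, sep="\t", index=False, float_format="%.6f")
    truth = pd.DataFrame({
        "proband_id": ids, "planted_macro": planted,
        "z_hc": z_hc, "z_ht": z_ht, "z_ratio": z_ratio,
    })
    truth_path = outdir / "truth_growth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False, float_format="%.6f")
    return {"reference": ref_path, "cohort": cohort_path, "truth": truth_path}


# ---------------------------------------------------------------------------
# trios

BASES = "ACGT"
CONSEQUENCES_LGD = ("frameshift", "stop_gained", "splice_site")
CONSEQUENCES_OTHER = ("missense", "synonymous", "other")


def _random_allele_pair(rng) -> tuple[str, str]:
    """Random SNV or already-minimal indel allele pair."""
    kind = rng.random()
    if kind < 0.7:  # SNV
        ref = BASES[rng.integers(4)]
        alt = BASES[(BASES.index(ref) + 1 + rng.integers(3)) % 4]
    elif kind < 0.85:  # insertion
        ref = BASES[rng.integers(4)]
        alt = ref + "".join(BASES[j] for j in rng.integers(0, 4, rng.integers(1, 5)))
    else:  # deletion
        anchor = BASES[rng.integers(4)]
        ref = anchor + "".join(BASES[j] for j in rng.integers(0, 4, rng.integers(1, 5)))
        alt = anchor
    return ref, alt


def _write_vcf(path, records, samples):
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted({r[0] for r in records}, key=str):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, gts in sorted(records, key=lambda r: (r[0], r[1])):
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def gen_trio_vcf(cfg: TrioConfig, outdir, seed: int) -> dict:
    """Write per-family trio VCFs plus annotation/CNV tables and truth.

    Inherited variants are Mendelian-consistent: a random heterozygous
    parent transmits with probability 1/2. De novo variants appear as
    heterozygous in the proband with both parents homozygous reference.
    Consequence labels, Beta-distributed continental allele frequencies
    (with a point mass at 0), dbSNP flags, gene assignments and pLI scores
    are drawn with the configured mixtures; the truth table records, per
    variant, its origin and whether it survives each filter.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_genes = 300
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    pli = {g: (rng.uniform(0.9, 1.0) if rng.random() < 0.2 else rng.uniform(0.0, 0.9))
           for g in genes}
    a, b = cfg.af_beta

    vcf_paths = {}
    ann_rows = []
    truth_rows = []
    cnv_rows = []
    n_total = cfg.n_inherited + cfg.n_denovo
    # one global position pool so variant keys are unique across families
    all_positions = rng.choice(np.arange(1_000, 20_000_000),
                               size=n_total * cfg.n_families, replace=False)
    for fam in range(cfg.n_families):
        fam_id = f"FAM{fam:02d}"
        proband, father, mother = f"{fam_id}_p", f"{fam_id}_f", f"{fam_id}_m"
        chroms = rng.integers(1, 5, n_total)
        positions = all_positions[fam * n_total:(fam + 1) * n_total]
        origin = np.array(["inherited"] * cfg.n_inherited + ["denovo"] * cfg.n_denovo)
        rng.shuffle(origin)
        records = []
        for i in range(n_total):
            chrom, pos = str(chroms[i]), int(positions[i])
            ref, alt = _random_allele_pair(rng)
            key = f"{chrom}:{pos}:{ref}:{alt}"
            if origin[i] == "denovo":
                gt_p, gt_f, gt_m = "0/1", "0/0", "0/0"
            else:
                carrier_is_father = rng.random() < 0.5
                transmitted = rng.random() < 0.5
                gt_p = "0/1" if transmitted else "0/0"
                gt_f = "0/1" if carrier_is_father else "0/0"
                gt_m = "0/0" if carrier_is_father else "0/1"
            records.append((chrom, pos, ref, alt, (gt_p, gt_f, gt_m)))
            is_denovo_carried = origin[i] == "denovo"
            if is_denovo_carried:
                cons = (CONSEQUENCES_LGD[rng.integers(3)]
                        if rng.random() < cfg.lgd_fraction
                        else CONSEQUENCES_OTHER[rng.integers(3)])
            else:
                cons = CONSEQUENCES_OTHER[rng.integers(3)]
            afs = {}
            for pop in ("afr", "amr", "eas", "eur", "sas"):
                afs[pop] = 0.0 if rng.random() < cfg.af_zero_mass \
                    else float(rng.beta(a, b))
            gene = genes[int(rng.integers(n_genes))]
            in_dbsnp = bool(rng.random() < 0.5)
            ann_rows.append({
                "key": key, "consequence": cons,
                **{f"af_{p}": afs[p] for p in afs},
                "in_dbsnp": in_dbsnp, "genes": gene, "pli": pli[gene],
            })
            rare = all(v < 0.002 for v in afs.values())
            lgd = cons in CONSEQUENCES_LGD
            truth_rows.append({
                "family_id": fam_id, "proband_id": proband, "key": key,
                "origin": origin[i], "proband_carries": gt_p == "0/1",
                "consequence": cons, "gene": gene,
                "is_lgd": lgd, "is_rare": rare,
                "qualifying": bool(origin[i] == "denovo" and gt_p == "0/1"
                                   and lgd and rare),
            })
        path = outdir / f"{fam_id}.vcf"
        _write_vcf(path, records, [proband, father, mother])
        vcf_paths[fam_id] = path
        for c in range(cfg.n_cnvs_per_family):
            start = int(rng.integers(1_000, 4_000_000))
            n_hit = int(rng.integers(1, 5))
            cnv_rows.append({
                "chrom": str(rng.integers(1, 5)), "start": start,
                "end": start + int(rng.integers(5_000, 200_000)),
                "cn": int(rng.choice([0, 1, 3, 4])),
                "precise": bool(rng.random() < 0.7),
                "exonic": bool(rng.random() < 0.7),
                "genes": ",".join(genes[j] for j in rng.choice(n_genes, n_hit, replace=False)),
                "proband_id": proband,
            })

    ann = pd.DataFrame(ann_rows)
    ann_path = outdir / "annotation.tsv"
    ann.to_csv(ann_path, sep="\t", index=False, float_format="%.6g")
    cnvs = pd.DataFrame(cnv_rows)
    cnvs["passes_filter"] = (cnvs["precise"] & cnvs["exonic"]
                             & (cnvs["genes"].str.count(",") + 1 <= 2))
    cnv_path = outdir / "cnvs.tsv"
    cnvs.drop(columns="passes_filter").to_csv(cnv_path, sep="\t", index=False)
    truth = pd.DataFrame(truth_rows)
    truth_path = outdir / "truth_trios.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    cnv_truth_path = outdir / "truth_cnvs.tsv"
    cnvs.to_csv(cnv_truth_path, sep="\t", index=False)
    pli_path = outdir / "pli.tsv"
    pd.DataFrame({"gene": genes, "pli": [pli[g] for g in genes]}).to_csv(
        pli_path, sep="\t", index=False, float_format="%.6g")
    return {
        "vcfs": vcf_paths, "annotation": ann_path, "cnvs": cnv_path,
        "truth": truth_path, "cnv_truth": cnv_truth_path, "pli": pli_path,
    }


# ---------------------------------------------------------------------------
# edges, ontology, morphometrics

def gen_edges_and_morpho(
    edge_cfg: EdgeConfig, morpho_cfg: MorphoConfig, outdir, seed: int
) -> dict:
    """Write a scored edge table, term annotations with one planted enriched
    term, seed list, and group-shifted morphometric features.

    Edges form an Erdos-Renyi-style random graph at the configured mean
    degree with combined scores uniform over the configured range. The
    planted term draws most of its genes from the seed set and its top
    interactors, so hypergeometric enrichment should rank it first. Larval
    features are log-normal around plausible 3-dpf baselines with the
    configured per-feature multiplicative group effects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n = edge_cfg.n_genes
    genes = [f"G{i:04d}" for i in range(n)]
    n_edges = int(n * edge_cfg.mean_degree / 2)
    pairs = set()
    while len(pairs) < n_edges:
        i, j = rng.integers(0, n, 2)
        if i != j:
            pairs.add((min(i, j), max(i, j)))
    lo, hi = edge_cfg.score_range
    edges = pd.DataFrame(
        [(genes[i], genes[j], int(rng.integers(lo, hi + 1))) for i, j in sorted(pairs)],
        columns=["gene_a", "gene_b", "combined_score"],
    )
    edges_path = outdir / "edges.tsv"
    edges.to_csv(edges_path, sep="\t", index=False)

    degree = pd.concat([edges["gene_a"], edges["gene_b"]]).value_counts()
    connected = [g for g in genes if degree.get(g, 0) > 0]
    seeds = sorted(rng.choice(connected, size=edge_cfg.n_seeds, replace=False))
    seeds_path = outdir / "seeds.txt"
    seeds_path.write_text("\n".join(seeds) + "\n")

    # planted enriched term: predominantly seed genes, lightly padded, so
    # the expanded network is strongly over-represented in it
    n_from_seeds = min(len(seeds), edge_cfg.term_size - 2)
    n_pad = min(edge_cfg.term_size - n_from_seeds, max(2, n_from_seeds // 4))
    planted_genes = set(rng.choice(seeds, size=n_from_seeds, replace=False))
    pool = [g for g in genes if g not in planted_genes]
    planted_genes |= set(rng.choice(pool, size=n_pad, replace=False))
    term_rows = [("T0000", "planted_enriched_term", g) for g in sorted(planted_genes)]
    for t in range(1, edge_cfg.n_terms):
        members = rng.choice(genes, size=edge_cfg.term_size, replace=False)
        term_rows += [(f"T{t:04d}", f"background_term_{t}", g) for g in sorted(members)]
    terms = pd.DataFrame(term_rows, columns=["term_id", "term_name", "gene"])
    terms_path = outdir / "terms.tsv"
    terms.to_csv(terms_path, sep="\t", index=False)

    rows = []
    for group, is_test in (("control", False), ("test", True)):
        for i in range(morpho_cfg.n_per_group):
            row = {"larva_id": f"{group}_{i:03d}", "group": group}
            for feat, base in FEATURE_BASELINES.items():
                effect = morpho_cfg.effects.get(feat, 1.0) if is_test else 1.0
                row[feat] = base * effect * float(
                    np.exp(rng.normal(0, morpho_cfg.noise_cv)))
            rows.append(row)
    morpho = pd.DataFrame(rows)
    morpho_path = outdir / "morpho.tsv"
    morpho.to_csv(morpho_path, sep="\t", index=False, float_format="%.6f")

    truth = {
        "planted_term": "T0000",
        "seeds": list(map(str, seeds)),
        "morpho_effects": morpho_cfg.effects,
    }
    truth_path = outdir / "truth_network_morpho.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return {
        "edges": edges_path, "terms": terms_path, "seeds": seeds_path,
        "morpho": morpho_path, "truth": truth_path,
    }


# ---------------------------------------------------------------------------
# single-cell counts

def _nb_counts(rng, mu, dispersion):
    """Negative-binomial draws via the gamma-Poisson mixture, var = mu + a*mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def gen_sc_counts(
    cfg: ScConfig, outdir, seed: int,
    conditions: tuple = ("overexpression", "oe_control"),
    effect_conditions: tuple = ("overexpression",),
    plant_qc_violators: bool = True,
) -> dict:
    """Write MTX counts + cell/gene TSVs per condition, with planted truth.

    Gene means are log-normal; each cell belongs to one of ``n_clusters``
    populations whose marker-gene block is boosted 8-fold; counts are
    negative binomial at the configured dispersion with log-normal cell
    size factors. In ``effect_conditions`` the designated target-set genes
    are scaled by ``target_effect``. Mito/ribo percentages and planted QC
    violators (high mito, high ribo, low features, high features) are
    synthesized per cell; the truth table records both the planted
    violators and the full rule-derived removal set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    G = cfg.n_genes
    gene_ids = [f"gene{i:05d}" for i in range(G)]
    gene_mean = np.exp(rng.normal(0.0, 1.0, G)).clip(max=30)
    # disjoint marker blocks, one per cluster
    block = max(G // (cfg.n_clusters * 10), 5)
    marker_blocks = [np.arange(c * block, (c + 1) * block) for c in range(cfg.n_clusters)]
    marker_genes = np.concatenate(marker_blocks)
    non_markers = np.setdiff1d(np.arange(G), marker_genes)
    targets = rng.choice(non_markers, size=cfg.target_set_size, replace=False)
    target_ids = sorted(gene_ids[i] for i in targets)
    cluster_probs = rng.dirichlet(np.full(cfg.n_clusters, 8.0))

    paths = {}
    qc_truth_rows = []
    planted_all: dict[str, list] = {"high_mito": [], "high_ribo": [],
                                    "low_features": [], "high_features": []}
    for cond in conditions:
        n = cfg.n_cells_per_condition
        cell_ids = [f"{cond}_c{i:05d}" for i in range(n)]
        samples = [f"{cond}_s{i % cfg.n_samples_per_condition}" for i in range(n)]
        clusters = rng.choice(cfg.n_clusters, size=n, p=cluster_probs)
        size = np.exp(rng.normal(0, 0.25, n))
        mu = np.outer(size, gene_mean)
        for c in range(cfg.n_clusters):
            mu[np.ix_(clusters == c, marker_blocks[c])] *= 8.0
        if cond in effect_conditions:
            mu[:, targets] *= cfg.target_effect
        counts = _nb_counts(rng, mu, cfg.nb_dispersion)

        pct_mito = rng.uniform(0.5, 4.5, n)
        pct_ribo = rng.uniform(0.5, 4.5, n)
        planted = {"high_mito": [], "high_ribo": [], "low_features": [],
                   "high_features": []}
        if plant_qc_violators:
            n_viol = max(int(cfg.qc_violator_fraction * n), 4)
            viol = rng.choice(n, size=n_viol, replace=False)
            for j, cell in enumerate(viol):
                rule = ("high_mito", "high_ribo", "low_features", "high_features")[j % 4]
                planted[rule].append(cell_ids[cell])
                if rule == "high_mito":
                    pct_mito[cell] = rng.uniform(5.5, 15)
                elif rule == "high_ribo":
                    pct_ribo[cell] = rng.uniform(5.5, 15)
                elif rule == "low_features":
                    keep = rng.choice(G, size=min(120, G // 2), replace=False)
                    row = np.zeros(G, dtype=counts.dtype)
                    row[keep] = np.maximum(counts[cell, keep], 1)
                    counts[cell] = row
                else:  # high_features: detect nearly every gene
                    counts[cell] = np.maximum(counts[cell], 1)
            for rule, cells_hit in planted.items():
                planted_all[rule].extend(cells_hit)
        n_features = (counts > 0).sum(axis=1)

        cells = pd.DataFrame({
            "cell_id": cell_ids,
            "sample_id": samples,
            "condition": cond,
            "percent_mito": pct_mito,
            "percent_ribo": pct_ribo,
            "n_features": n_features,
            "true_cluster": clusters,
        })
        # rule-derived removal set (same rules qc_filter applies), recorded
        # as truth so tests can check the filter end to end
        removed = (pct_mito > 5) | (pct_ribo > 5) | (n_features < 200)
        for s in set(samples):
            m = np.array(samples) == s
            mu_f, sd_f = n_features[m].mean(), n_features[m].std(ddof=0)
            removed |= (np.array(samples) == s) & (n_features > mu_f + 2 * sd_f)
        for cid, rm in zip(cell_ids, removed):
            qc_truth_rows.append({"cell_id": cid, "condition": cond,
                                  "removed": bool(rm)})

        cond_dir = outdir / cond
        cond_dir.mkdir(exist_ok=True)
        mtx_path = cond_dir / "counts.mtx"
        mmwrite(str(mtx_path), sparse.csr_matrix(counts.T.astype(np.int64)))
        cells_path = cond_dir / "cells.tsv"
        cells.to_csv(cells_path, sep="\t", index=False, float_format="%.6f")
        genes_path = cond_dir / "genes.tsv"
        pd.DataFrame({"gene_id": gene_ids, "symbol": gene_ids}).to_csv(
            genes_path, sep="\t", index=False)
        paths[cond] = {"counts": mtx_path, "cells": cells_path, "genes": genes_path}

    targets_path = outdir / "target_genes.txt"
    targets_path.write_text("\n".join(target_ids) + "\n")
    # human->zebrafish style ortholog map covering all genes, with a few
    # one-to-many expansions and a few unmapped human symbols
    human = [g.upper() for g in gene_ids]
    map_rows = [{"human_symbol": h, "zebrafish_symbol": g}
                for h, g in zip(human, gene_ids)]
    for i in range(0, min(20, G), 2):
        map_rows.append({"human_symbol": human[i], "zebrafish_symbol": gene_ids[i] + "b"})
    ortho = pd.DataFrame(map_rows)
    ortho_path = outdir / "ortholog_map.tsv"
    ortho.to_csv(ortho_path, sep="\t", index=False)

    qc_truth = pd.DataFrame(qc_truth_rows)
    qc_truth_path = outdir / "truth_qc.tsv"
    qc_truth.to_csv(qc_truth_path, sep="\t", index=False)
    truth = {
        "target_genes": target_ids,
        "target_effect": cfg.target_effect,
        "effect_conditions": list(effect_conditions),
        "planted_qc_violators": planted_all if plant_qc_violators else {},
        "n_clusters": cfg.n_clusters,
    }
    truth_path = outdir / "truth_sc.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return {
        "conditions": paths, "targets": targets_path, "ortholog_map": ortho_path,
        "qc_truth": qc_truth_path, "truth": truth_path,
    }
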