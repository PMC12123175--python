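"""De novo, likely gene-disruptive, rare variant discovery in trios.

The filtering chain mirrors standard trio-based candidate-gene discovery:

1. normalize every variant to its minimal left-aligned representation so
   that proband/parent comparisons operate on canonical keys;
2. keep variants carried by the proband and absent from both parents
   (*de novo*);
3. keep likely gene-disruptive (LGD) consequences — frameshift, stop-gain,
   splice-site;
4. keep rare variants — minor allele frequency below 0.2% in all five
   continental reference populations (trio mode) or absent from dbSNP
   (non-trio mode);
5. include copy-number variants that are precise, exonic and impact at most
   two genes;
6. aggregate to candidate genes with recurrence (distinct probands) and a
   constraint flag (pLI > 0.9).

Burden comparisons between groups use a two-proportion chi-squared test
(1 df, no continuity correction by default) for carrier rates and a
two-sided Fisher's exact test for 2x2 gene-set-by-group tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotatedVariant",
    "TrioFamily",
    "CnvCall",
    "minimal_representation",
    "normalize_variant",
    "find_denovo",
    "is_lgd",
    "is_rare",
    "filter_cnvs",
    "aggregate_candidates",
    "carrier_chi2",
    "fisher_2x2",
    "burden_tests",
    "read_trio_vcf",
    "read_annotation_tsv",
    "read_cnv_tsv",
    "annotate_variants",
]

LGD_CONSEQUENCES = frozenset({"frameshift", "stop_gained", "splice_site"})
POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")


@dataclass
class AnnotatedVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: dict = field(default_factory=dict)  # sample -> (a0, a1) allele idx or None
    consequence: str = "other"
    pop_af: dict = field(default_factory=dict)
    in_dbsnp: bool = False
    genes: tuple = ()
    pli: dict = field(default_factory=dict)  # gene -> pLI
    proband_id: str | None = None

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def carries(self, sample: str) -> bool | None:
        """Whether ``sample`` carries the alternate allele (None if missing)."""
        gt = self.genotypes.get(sample)
        if gt is None or any(a is None for a in gt):
            return None
        return any(a == 1 for a in gt)


@dataclass
class TrioFamily:
    family_id: str
    proband_id: str
    father_id: str | None = None
    mother_id: str | None = None
    proband_affected: bool = True
    sibling_ids: tuple = ()

    def __post_init__(self):
        if self.proband_id in (self.father_id, self.mother_id):
            raise ValueError("proband id must differ from parent ids")

    @property
    def is_trio(self) -> bool:
        return self.father_id is not None and self.mother_id is not None


@dataclass
class CnvCall:
    chrom: str
    start: int  # 0-based half-open
    end: int
    copy_number: int
    precise: bool
    genes_impacted: tuple
    exonic: bool
    proband_id: str | None = None

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("CNV start must be < end")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:CN{self.copy_number}"


def minimal_representation(
    pos: int, ref: str, alt: str, chrom_seq: str | None = None
) -> tuple[int, str, str]:
    """Trim and left-align one allele pair to its canonical representation.

    Right-trims the common suffix, left-trims the common prefix, then — when
    ``chrom_seq`` (the full 1-based chromosome sequence as a 0-indexed
    string) is provided — left-shifts indels while the trailing base matches
    the reference base preceding the current position.
    """
    if ref == alt:
        raise ValueError("ref and alt must differ")
    ref, alt = ref.upper(), alt.upper()
    if chrom_seq is not None:
        if chrom_seq[pos - 1 : pos - 1 + len(ref)].upper() != ref:
            raise ValueError(
                f"ref allele {ref!r} inconsistent with reference context at pos {pos}"
            )
        # vt-normalize style: right-trim shared suffix, extending left from
        # the reference whenever an allele empties, then left-trim
        while True:
            if ref and alt and ref[-1] == alt[-1]:
                ref, alt = ref[:-1], alt[:-1]
            elif (not ref or not alt) and pos > 1:
                prev = chrom_seq[pos - 2].upper()
                ref, alt = prev + ref, prev + alt
                pos -= 1
            else:
                break
    else:
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_variant(
    v: AnnotatedVariant, reference: dict[str, str] | None = None
) -> list[AnnotatedVariant]:
    """Split multiallelic records and canonicalize each allele pair.

    ``v.alt`` may be a comma-separated ALT list straight from a VCF record;
    one biallelic :class:`AnnotatedVariant` is returned per alternate
    allele, with genotypes recoded so allele index 1 means "carries this
    alternate". ``reference`` maps chromosome name to its sequence and
    enables left-alignment of indels.
    """
    alts = v.alt.split(",") if isinstance(v.alt, str) else list(v.alt)
    out = []
    for alt_idx, alt in enumerate(alts, start=1):
        chrom_seq = reference.get(v.chrom) if reference else None
        pos, ref, alt_n = minimal_representation(v.pos, v.ref, alt, chrom_seq)
        genotypes = {}
        for sample, gt in v.genotypes.items():
            if gt is None:
                genotypes[sample] = None
            else:
                genotypes[sample] = tuple(
                    None if a is None else (1 if a == alt_idx else 0) for a in gt
                )
        out.append(replace(v, pos=pos, ref=ref, alt=alt_n, genotypes=genotypes))
    return out


def find_denovo(
    variants: list[AnnotatedVariant],
    family: TrioFamily,
    raw_string_match: bool = False,
) -> list[AnnotatedVariant]:
    """Variants carried by the proband and absent from both parents.

    Requires both parents genotyped at the site: a missing parental
    genotype at a proband-carried site excludes the variant (conservative)
    and is logged. With ``raw_string_match`` the proband's variant keys are
    compared verbatim against the parents' carried keys without requiring
    per-site genotypes (the historical exact-string filter); normalized-key
    matching is the default.
    """
    if not family.is_trio:
        raise ValueError(f"family {family.family_id} is not a complete trio")
    if raw_string_match:
        parent_keys = {
            v.key
            for v in variants
            if v.carries(family.father_id) or v.carries(family.mother_id)
        }
        return [
            replace(v, proband_id=family.proband_id)
            for v in variants
            if v.carries(family.proband_id) and v.key not in parent_keys
        ]
    out = []
    for v in variants:
        if not v.carries(family.proband_id):
            continue
        dad = v.carries(family.father_id)
        mom = v.carries(family.mother_id)
        if dad is None or mom is None:
            logger.info("excluding %s: missing parental genotype", v.key)
            continue
        if not dad and not mom:
            out.append(replace(v, proband_id=family.proband_id))
    return out


def is_lgd(consequence: str) -> bool:
    """Likely gene-disruptive: frameshift, stop-gain or splice-site."""
    return consequence in LGD_CONSEQUENCES


def is_rare(
    v: AnnotatedVariant,
    max_af: float = 0.002,
    require_absent_dbsnp: bool = False,
) -> bool:
    """Rare by continental allele frequencies, or by dbSNP absence.

    Trio mode (default): AF strictly below ``max_af`` in all five
    continental populations; a population absent from the annotation is
    treated as frequency 0. Non-trio mode (``require_absent_dbsnp``):
    the variant must not be recorded in dbSNP.
    """
    if require_absent_dbsnp:
        return not v.in_dbsnp
    for pop in POPULATIONS:
        if pop not in v.pop_af:
            logger.debug("%s: population %s AF absent, treated as 0", v.key, pop)
        if v.pop_af.get(pop, 0.0) >= max_af:
            return False
    return True


def filter_cnvs(cnvs: list[CnvCall], max_genes: int = 2) -> list[CnvCall]:
    """Keep CNVs that are precise, exonic and impact at most ``max_genes``."""
    return [
        c for c in cnvs
        if c.precise and c.exonic and len(c.genes_impacted) <= max_genes
    ]


def aggregate_candidates(
    denovo_lgd_variants: list[AnnotatedVariant],
    cnvs: list[CnvCall] | None = None,
    pli_map: dict[str, float] | None = None,
    pli_cutoff: float = 0.9,
    cohort: str = "cohort",
) -> pd.DataFrame:
    """Aggregate qualifying variants and CNVs to candidate-gene records.

    One row per gene, with recurrence counted as distinct probands (two
    variants in one proband count once), the contributing variant keys, and
    a constraint flag for pLI > ``pli_cutoff``. A CNV spanning several genes
    contributes its key to each impacted gene.
    """
    pli_map = pli_map or {}
    per_gene: dict[str, dict] = {}

    def add(gene: str, variant_key: str, proband: str | None, pli: float | None):
        rec = per_gene.setdefault(gene, {"variant_ids": [], "probands": set(), "pli": None})
        rec["variant_ids"].append(variant_key)
        if proband is not None:
            rec["probands"].add(proband)
        if pli is not None:
            rec["pli"] = pli

    for v in denovo_lgd_variants:
        if not v.genes:
            logger.info("variant %s has no gene annotation; skipped", v.key)
            continue
        if len(v.genes) > 1:
            logger.info("variant %s overlaps multiple genes: %s", v.key, v.genes)
        for gene in v.genes:
            add(gene, v.key, v.proband_id, v.pli.get(gene, pli_map.get(gene)))
    for c in cnvs or []:
        for gene in c.genes_impacted:
            add(gene, c.key, c.proband_id, pli_map.get(gene))

    rows = [
        {
            "gene": gene,
            "n_probands": max(len(rec["probands"]), 1),
            "variant_ids": ",".join(rec["variant_ids"]),
            "pli": rec["pli"],
            "pli_flag": bool(rec["pli"] is not None and rec["pli"] > pli_cutoff),
            "cohort": cohort,
        }
        for gene, rec in per_gene.items()
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["gene", "n_probands", "variant_ids", "pli", "pli_flag", "cohort"]
        )
    return df.sort_values(["n_probands", "gene"], ascending=[False, True]).reset_index(
        drop=True
    )


def _zero_margin(table: np.ndarray) -> bool:
    return (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()


def carrier_chi2(
    carriers_a: int, n_a: int, carriers_b: int, n_b: int, yates: bool = False
) -> dict:
    """Two-proportion chi-squared comparison of carrier rates (1 df).

    No continuity correction by default; returns the contingency table used.
    """
    table = np.array(
        [[carriers_a, n_a - carriers_a], [carriers_b, n_b - carriers_b]], dtype=float
    )
    if _zero_margin(table):
        warnings.warn("zero-margin contingency table; p set to 1")
        return {"statistic": 0.0, "p": 1.0, "table": table.tolist(), "test": "chi2"}
    stat, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return {"statistic": float(stat), "p": float(p), "table": table.tolist(), "test": "chi2"}


def fisher_2x2(table) -> dict:
    """Two-sided Fisher's exact test with the table echoed back."""
    table = np.asarray(table, dtype=float)
    if _zero_margin(table):
        warnings.warn("zero-margin contingency table; p set to 1")
        return {"odds_ratio": np.nan, "p": 1.0, "table": table.tolist(), "test": "fisher"}
    odds, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
    return {"odds_ratio": float(odds), "p": float(p), "table": table.tolist(), "test": "fisher"}


def burden_tests(group_tables: dict, yates: bool = False) -> dict:
    """Run the burden comparisons described by ``group_tables``.

    ``group_tables`` maps a comparison label to either
    ``{"kind": "carrier_rate", "carriers_a":…, "n_a":…, "carriers_b":…, "n_b":…}``
    (chi-squared) or ``{"kind": "fisher", "table": [[a,b],[c,d]]}``.
    """
    report = {}
    for label, spec in group_tables.items():
        kind = spec.get("kind", "fisher")
        if kind == "carrier_rate":
            report[label] = carrier_chi2(
                spec["carriers_a"], spec["n_a"], spec["carriers_b"], spec["n_b"],
                yates=yates,
            )
        elif kind == "fisher":
            report[label] = fisher_2x2(spec["table"])
        else:
            raise ValueError(f"unknown test kind {kind!r}")
    return report


# ---------------------------------------------------------------------------
# I/O

def read_trio_vcf(path) -> tuple[list[AnnotatedVariant], list[str]]:
    """Read a VCF into raw (un-normalized) variants plus its sample list."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants = []
    for rec in vcf:
        genotypes = {}
        for sample, gt in zip(samples, rec.genotypes):
            alleles = tuple(None if a == -1 else int(a) for a in gt[:2])
            genotypes[sample] = alleles
        variants.append(
            AnnotatedVariant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=",".join(rec.ALT),
                genotypes=genotypes,
            )
        )
    return variants, samples


def read_annotation_tsv(path) -> pd.DataFrame:
    """Read the per-variant annotation table keyed by normalized variant key."""
    df = pd.read_csv(path, sep="\t", dtype={"key": str})
    df["in_dbsnp"] = df["in_dbsnp"].astype(bool)
    df = df.set_index("key")
    if df.index.duplicated().any():
        logger.warning("duplicate annotation keys; keeping first occurrence")
        df = df[~df.index.duplicated(keep="first")]
    return df


def read_cnv_tsv(path) -> list[CnvCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        CnvCall(
            chrom=str(r["chrom"]),
            start=int(r["start"]),
            end=int(r["end"]),
            copy_number=int(r["cn"]),
            precise=bool(r["precise"]),
            exonic=bool(r["exonic"]),
            genes_impacted=tuple(str(r["genes"]).split(",")) if pd.notna(r["genes"]) and str(r["genes"]) else (),
            proband_id=str(r["proband_id"]) if "proband_id" in df.columns else None,
        )
        for r in df.to_dict("records")
    ]


def annotate_variants(
    variants: list[AnnotatedVariant], annotation: pd.DataFrame
) -> list[AnnotatedVariant]:
    """Attach consequence/AF/dbSNP/gene/pLI annotation by normalized key."""
    out = []
    for v in variants:
        if v.key not in annotation.index:
            logger.debug("no annotation for %s", v.key)
            out.append(v)
            continue
        row = annotation.loc[v.key]
        genes = tuple(str(row["genes"]).split(",")) if pd.notna(row["genes"]) and str(row["genes"]) else ()
        pli = {}
        if "pli" in row and pd.notna(row["pli"]):
            pli = {g: float(row["pli"]) for g in genes}
        out.append(
            replace(
                v,
                consequence=str(row["consequence"]),
                pop_af={p: float(row[f"af_{p.lower()}"]) for p in POPULATIONS
                        if f"af_{p.lower()}" in row and pd.notna(row[f"af_{p.lower()}"])},
                in_dbsnp=bool(row["in_dbsnp"]),
                genes=genes,
                pli=pli,
            )
        )
    return out
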