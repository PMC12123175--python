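"""Trio variant filtering: normalization, de novo detection, burden tests."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from subpheno import trios
from subpheno.trios import AnnotatedVariant, CnvCall, TrioFamily


def oracle_normalize(pos, ref, alt, seq):
    """Independent canonicalization: rebuild both haplotypes and take the
    leftmost minimal difference (anchor base kept for indels)."""
    hap_ref = seq
    hap_alt = seq[: pos - 1] + alt + seq[pos - 1 + len(ref):]
    lr, la = len(hap_ref), len(hap_alt)
    # maximal common suffix first, so the difference window is leftmost
    j = 0
    while j < min(lr, la) and hap_ref[lr - 1 - j] == hap_alt[la - 1 - j]:
        j += 1
    i = 0
    while i < min(lr, la) - j and hap_ref[i] == hap_alt[i]:
        i += 1
    r = hap_ref[i: lr - j]
    a = hap_alt[i: la - j]
    p = i + 1
    if not r or not a:  # indel: re-anchor on the preceding base
        p -= 1
        r = hap_ref[p - 1] + r
        a = hap_alt[p - 1] + a
    return p, r, a


class TestNormalization:
    def test_minimal_snv_unchanged(self):
        assert trios.minimal_representation(100, "A", "T") == (100, "A", "T")

    def test_documented_indel(self):
        seq = "G" * 98 + "CATGGG" + "A" * 30
        pos, ref, alt = trios.minimal_representation(100, "AT", "AATT", seq)
        assert (pos, ref, alt) == oracle_normalize(100, "AT", "AATT", seq)

    def test_random_indels_match_oracle(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        seq = "".join(bases[i] for i in rng.integers(0, 4, 3000))
        checked = 0
        for _ in range(1000):
            pos = int(rng.integers(50, 2900))
            ref_len = int(rng.integers(1, 6))
            ref = seq[pos - 1: pos - 1 + ref_len]
            if rng.random() < 0.5:  # deletion: alt is anchor base
                alt = ref[0]
            else:  # insertion after the anchor
                alt = ref + "".join(bases[i] for i in rng.integers(0, 4, rng.integers(1, 5)))
            if ref == alt:
                continue
            got = trios.minimal_representation(pos, ref, alt, seq)
            assert got == oracle_normalize(pos, ref, alt, seq)
            checked += 1
        assert checked > 800

    def test_multiallelic_split(self):
        v = AnnotatedVariant("1", 50, "A", "T,C",
                             genotypes={"p": (0, 2), "f": (0, 1), "m": (0, 0)})
        out = trios.normalize_variant(v)
        assert [w.alt for w in out] == ["T", "C"]
        assert out[0].carries("p") is False and out[1].carries("p") is True
        assert out[0].carries("f") is True and out[1].carries("f") is False


def _variant(key_pos, gt_p, gt_f, gt_m, **kw):
    return AnnotatedVariant("1", key_pos, "A", "G",
                            genotypes={"p": gt_p, "f": gt_f, "m": gt_m}, **kw)


FAMILY = TrioFamily("fam", "p", "f", "m")


class TestFindDenovo:
    def test_proband_only_retained(self):
        v = _variant(10, (0, 1), (0, 0), (0, 0))
        assert [w.key for w in trios.find_denovo([v], FAMILY)] == [v.key]

    def test_parent_carrier_excluded(self):
        v = _variant(10, (0, 1), (0, 1), (0, 0))
        assert trios.find_denovo([v], FAMILY) == []

    def test_missing_parent_genotype_excluded(self):
        v = _variant(10, (0, 1), (None, None), (0, 0))
        assert trios.find_denovo([v], FAMILY) == []

    def test_generator_truth_recovered(self, trio_workspace):
        truth = pd.read_csv(trio_workspace["truth"], sep="\t")
        annotation = trios.read_annotation_tsv(trio_workspace["annotation"])
        for fam_id, vcf_path in trio_workspace["vcfs"].items():
            variants, samples = trios.read_trio_vcf(vcf_path)
            family = TrioFamily(fam_id, *samples[:3])
            normalized = [w for v in variants for w in trios.normalize_variant(v)]
            denovo = trios.find_denovo(trios.annotate_variants(normalized, annotation),
                                       family)
            fam_truth = truth[truth["family_id"] == fam_id]
            expected = set(fam_truth[fam_truth["origin"] == "denovo"]["key"])
            assert {v.key for v in denovo} == expected


class TestPredicates:
    @pytest.mark.parametrize("consequence,expected", [
        ("frameshift", True), ("stop_gained", True), ("splice_site", True),
        ("missense", False), ("synonymous", False), ("other", False),
    ])
    def test_lgd(self, consequence, expected):
        assert trios.is_lgd(consequence) is expected

    def test_rare_all_zero(self):
        v = _variant(1, (0, 1), (0, 0), (0, 0),
                     pop_af={p: 0.0 for p in trios.POPULATIONS})
        assert trios.is_rare(v) is True

    def test_rare_one_common_population(self):
        afs = {p: 0.0 for p in trios.POPULATIONS}
        afs["EUR"] = 0.003
        assert trios.is_rare(_variant(1, (0, 1), (0, 0), (0, 0), pop_af=afs)) is False

    def test_rare_boundary_strict(self):
        afs = {p: 0.0 for p in trios.POPULATIONS}
        afs["SAS"] = 0.002
        assert trios.is_rare(_variant(1, (0, 1), (0, 0), (0, 0), pop_af=afs)) is False

    def test_rare_dbsnp_mode(self):
        v = _variant(1, (0, 1), (0, 0), (0, 0), in_dbsnp=True)
        assert trios.is_rare(v, require_absent_dbsnp=True) is False

    def test_filter_composition_order_independent(self, trio_workspace):
        annotation = trios.read_annotation_tsv(trio_workspace["annotation"])
        fam_id, vcf_path = sorted(trio_workspace["vcfs"].items())[0]
        variants, samples = trios.read_trio_vcf(vcf_path)
        family = TrioFamily(fam_id, *samples[:3])
        annotated = trios.annotate_variants(
            [w for v in variants for w in trios.normalize_variant(v)], annotation)
        a = [v for v in trios.find_denovo(annotated, family)
             if trios.is_lgd(v.consequence) and trios.is_rare(v)]
        pre = [v for v in annotated if trios.is_rare(v) and trios.is_lgd(v.consequence)]
        b = trios.find_denovo(pre, family)
        assert {v.key for v in a} == {v.key for v in b}
        for v in a:
            assert trios.is_lgd(v.consequence) and trios.is_rare(v)


class TestCnvFilter:
    def _cnv(self, precise, exonic, n_genes):
        return CnvCall("1", 100, 200, 3, precise,
                       tuple(f"G{i}" for i in range(n_genes)), exonic)

    def test_rules(self):
        kept = trios.filter_cnvs([
            self._cnv(True, True, 2),
            self._cnv(True, True, 3),
            self._cnv(False, True, 1),
            self._cnv(True, False, 1),
        ])
        assert len(kept) == 1 and len(kept[0].genes_impacted) == 2


class TestAggregation:
    def test_recurrence_counts_distinct_probands(self):
        vs = [
            _variant(i, (0, 1), (0, 0), (0, 0), genes=("CHD8",), proband_id=p)
            for i, p in enumerate(["p1", "p2", "p3", "p3"], start=1)
        ]
        out = trios.aggregate_candidates(vs)
        assert out.loc[out["gene"] == "CHD8", "n_probands"].item() == 3

    def test_duplication_spanning_two_genes(self):
        cnv = CnvCall("1", 100, 109_100, 3, True, ("YTHDF2", "GMEB1"), True,
                      proband_id="p1")
        out = trios.aggregate_candidates([], [cnv])
        assert set(out["gene"]) == {"YTHDF2", "GMEB1"}
        assert (out["variant_ids"] == cnv.key).all()

    def test_pli_flag(self):
        v = _variant(1, (0, 1), (0, 0), (0, 0), genes=("PTEN",), proband_id="p1")
        out = trios.aggregate_candidates([v], pli_map={"PTEN": 0.97})
        assert out["pli_flag"].item()
        out2 = trios.aggregate_candidates([v], pli_map={"PTEN": 0.9})
        assert not out2["pli_flag"].item()

    def test_empty_input(self):
        assert trios.aggregate_candidates([]).empty


def oracle_fisher(a, b, c, d):
    """Exhaustive two-sided Fisher p by integer hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    total = math.comb(n, c1)
    p_obs = Fraction(math.comb(r1, a) * math.comb(r2, c), total)
    p = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), total)
        if pk <= p_obs * Fraction(1 + 1e-12):
            p += pk
    return float(min(p, Fraction(1)))


class TestBurdenStats:
    def test_identical_proportions(self):
        res = trios.carrier_chi2(10, 100, 10, 100)
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_fisher_matches_enumeration(self):
        res = trios.fisher_2x2([[2, 8], [1, 99]])
        assert res["p"] == pytest.approx(oracle_fisher(2, 8, 1, 99), abs=1e-10)

    def test_fisher_odds_ratio_scale_invariant(self):
        r1 = trios.fisher_2x2([[3, 7], [2, 18]])
        r2 = trios.fisher_2x2([[6, 14], [4, 36]])
        assert r1["odds_ratio"] == pytest.approx(r2["odds_ratio"])

    def test_zero_margin_table(self):
        with pytest.warns(UserWarning, match="zero-margin"):
            res = trios.fisher_2x2([[0, 0], [3, 5]])
        assert res["p"] == 1.0

    def test_chi2_matches_textbook_formula(self):
        # hand formula: chi2 = n(ad-bc)^2 / (r1 r2 c1 c2)
        a, b, c, d = 12, 18, 5, 25
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        res = trios.carrier_chi2(a, a + b, c, c + d)
        assert res["statistic"] == pytest.approx(expected)

    def test_burden_report_structure(self):
        report = trios.burden_tests({
            "rates": {"kind": "carrier_rate", "carriers_a": 5, "n_a": 26,
                      "carriers_b": 4, "n_b": 24},
            "missense": {"kind": "fisher", "table": [[2, 8], [1, 99]]},
        })
        assert set(report) == {"rates", "missense"}
        assert report["missense"]["test"] == "fisher"
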