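"""Instrument loading, harmonization, HWE testing, QC, pruning and proxies."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from heightmr.instruments import (
    GenotypeMatrix,
    HarmonizeAction,
    InstrumentRecord,
    LDTable,
    exclude_bmi_overlap,
    flip_dosage,
    harmonize_alleles,
    hwe_test,
    load_instruments,
    prune_ld,
    qc_filter,
    substitute_proxies,
)
from conftest import write_instrument_tsv


def _record(snp_id="rs1", ea="A", oa="G", eaf=0.3, beta=0.05, se=0.01, pval=1e-9):
    return InstrumentRecord(snp_id, "1", 1000, ea, oa, eaf, beta, se, pval, "EAS")


class TestLoadInstruments:
    def test_well_formed_file_roundtrips(self, tmp_path):
        p = write_instrument_tsv(
            tmp_path / "inst.tsv",
            [("rs1", 0.2, 0.03, 0.004, 1e-10), ("rs2", 0.4, -0.02, 0.005, 1e-8),
             ("rs3", 0.5, 0.01, 0.004, 2e-6)],
        )
        recs = load_instruments(p)
        assert [r.snp_id for r in recs] == ["rs1", "rs2", "rs3"]
        assert recs[1].beta_height == -0.02
        assert recs[0].source == "EAS"

    def test_101_rows_load_as_101_records(self, tmp_path):
        rows = [(f"rs{i}", 0.1 + 0.003 * (i % 100), 0.02, 0.004, 1e-9) for i in range(101)]
        p = write_instrument_tsv(tmp_path / "inst.tsv", rows)
        assert len(load_instruments(p)) == 101

    @pytest.mark.parametrize(
        "bad_row, fragment",
        [
            (("rsX", 1.2, 0.02, 0.004, 1e-9), "eaf"),
            (("rsX", 0.2, 0.02, -0.004, 1e-9), "se"),
            (("rsX", 0.2, 0.02, 0.004, 1.5), "p-value"),
        ],
    )
    def test_invalid_row_rejected_with_line_number(self, tmp_path, bad_row, fragment):
        p = write_instrument_tsv(
            tmp_path / "inst.tsv", [("rs1", 0.2, 0.03, 0.004, 1e-10), bad_row]
        )
        with pytest.raises(ValueError, match="line 3") as exc:
            load_instruments(p)
        assert fragment in str(exc.value)

    def test_duplicate_snp_id_rejected(self, tmp_path):
        p = write_instrument_tsv(
            tmp_path / "inst.tsv",
            [("rs1", 0.2, 0.03, 0.004, 1e-10), ("rs1", 0.3, 0.01, 0.004, 1e-9)],
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_instruments(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "inst.tsv"
        p.write_text("snp_id\tchrom\npos\n")
        with pytest.raises(ValueError, match="missing required column"):
            load_instruments(p)


class TestHarmonize:
    @pytest.mark.parametrize(
        "study_ea, study_oa, action",
        [
            ("A", "G", HarmonizeAction.KEEP),
            ("G", "A", HarmonizeAction.FLIP_DOSAGE),
            ("T", "C", HarmonizeAction.KEEP),  # same alleles on the other strand
            ("C", "T", HarmonizeAction.FLIP_DOSAGE),
        ],
    )
    def test_unambiguous_orientations(self, study_ea, study_oa, action):
        h = harmonize_alleles(_record(), study_ea, study_oa, 0.3)
        assert h.action is action

    def test_irreconcilable_alleles_excluded(self):
        h = harmonize_alleles(_record(), "A", "C", 0.3)
        assert h.action is HarmonizeAction.EXCLUDE
        assert h.reason == "allele_mismatch"

    def test_palindromic_near_half_frequency_excluded(self):
        rec = _record(ea="A", oa="T", eaf=0.48)
        h = harmonize_alleles(rec, "A", "T", 0.48)
        assert h.action is HarmonizeAction.EXCLUDE

    def test_palindromic_oriented_by_frequency(self):
        rec = _record(ea="C", oa="G", eaf=0.2)
        assert harmonize_alleles(rec, "C", "G", 0.22).action is HarmonizeAction.KEEP
        assert harmonize_alleles(rec, "C", "G", 0.78).action is HarmonizeAction.FLIP_DOSAGE

    def test_double_flip_restores_dosages(self, rng):
        d = rng.integers(0, 3, size=50).astype(float)
        assert np.array_equal(flip_dosage(flip_dosage(d)), d)


def hwe_enumeration_oracle(n_hom_effect, n_het, n_hom_other):
    """Exact rational-arithmetic HWE test by full enumeration."""
    n = n_hom_effect + n_het + n_hom_other
    na = 2 * n_hom_effect + n_het
    nb = 2 * n - na
    if na == 0 or nb == 0:
        return 1.0
    weights = {}
    for h in range(na % 2, min(na, nb) + 1, 2):
        a, b = (na - h) // 2, (nb - h) // 2
        weights[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(a) * math.factorial(h) * math.factorial(b),
        )
    total = sum(weights.values())
    obs = weights[n_het]
    return float(Fraction(sum(w for w in weights.values() if w <= obs), total))


class TestHWE:
    def test_monomorphic_is_one(self):
        assert hwe_test(50, 0, 0) == 1.0

    def test_complete_het_deficit_is_tiny(self):
        assert hwe_test(50, 0, 50) < 1e-20

    @pytest.mark.parametrize(
        "counts",
        [(25, 50, 25), (10, 5, 85), (0, 1, 99), (40, 20, 40), (3, 4, 5), (1, 98, 1)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_test(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), abs=1e-12
        )

    @given(
        st.integers(0, 70), st.integers(0, 70), st.integers(0, 60)
    )
    def test_matches_oracle_for_totals_up_to_200(self, a, b, c):
        if a + b + c == 0:
            return
        assert hwe_test(a, b, c) == pytest.approx(
            hwe_enumeration_oracle(a, b, c), abs=1e-12
        )

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)


def _matrix_from_columns(cols, n):
    snp_ids = sorted(cols)
    d = np.column_stack([cols[s] for s in snp_ids])
    subjects = [f"P{i}" for i in range(n)]
    return GenotypeMatrix(subjects, snp_ids, d)


class TestQCFilter:
    def _matrix(self, rng, n=400):
        cols = {
            "rs_ok": rng.binomial(2, 0.3, n).astype(float),
            "rs_maf": rng.binomial(2, 0.04, n).astype(float),
            "rs_call": rng.binomial(2, 0.3, n).astype(float),
            "rs_hwe": np.repeat([2.0, 0.0], n // 2),  # no heterozygotes at all
        }
        cols["rs_call"][: int(n * 0.07)] = np.nan
        return _matrix_from_columns(cols, n)

    def test_reasons_and_kept(self, rng):
        gm = self._matrix(rng)
        res = qc_filter(gm, gm.subject_ids)
        assert res.excluded["rs_maf"] == "maf"
        assert res.excluded["rs_call"] == "call_rate"
        assert res.excluded["rs_hwe"] == "hwe"
        assert res.kept == ["rs_ok"]

    def test_idempotent(self, rng):
        gm = self._matrix(rng)
        first = qc_filter(gm, gm.subject_ids)
        sub = gm.subset(snp_ids=first.kept)
        second = qc_filter(sub, sub.subject_ids)
        assert second.kept == first.kept
        assert second.excluded == {}

    def test_thresholds_inclusive_on_keep_side(self):
        n = 100
        d = np.tile([0.0, 1.0, 1.0, 2.0], n // 4)  # eaf 0.5, HWE-ish
        gm = GenotypeMatrix([f"P{i}" for i in range(n)], ["rs1"], d[:, None])
        res = qc_filter(gm, gm.subject_ids, maf_min=0.5, call_rate_min=1.0)
        assert res.kept == ["rs1"]

    def test_empty_control_set_errors(self, rng):
        gm = self._matrix(rng)
        with pytest.raises(ValueError, match="control"):
            qc_filter(gm, [])


class TestPruneLD:
    def test_stronger_pvalue_wins(self):
        a = _record("rsA", pval=1e-10)
        b = _record("rsB", pval=1e-8)
        ld = LDTable([("rsA", "rsB", 0.3)])
        kept = prune_ld([a, b], ld)
        assert [r.snp_id for r in kept] == ["rsA"]

    def test_independent_set_untouched_and_order_preserved(self):
        recs = [_record(f"rs{i}", pval=10 ** -(i + 3)) for i in range(5)]
        kept = prune_ld(list(reversed(recs)), LDTable())
        assert [r.snp_id for r in kept] == [r.snp_id for r in reversed(recs)]

    def test_block_of_linked_snps_reduced_to_one(self):
        # 36 SNPs all linked to the strongest one: 35 removed
        recs = [_record(f"rs{i:02d}", pval=1e-20 if i == 0 else 1e-9) for i in range(36)]
        ld = LDTable([("rs00", f"rs{i:02d}", 0.5) for i in range(1, 36)])
        kept = prune_ld(recs, ld)
        assert len(kept) == len(recs) - 35

    @given(st.integers(0, 2**32 - 1))
    def test_greedy_rule_verified_exhaustively(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 13))
        recs = [_record(f"rs{i:02d}", pval=float(rng.uniform(1e-12, 1e-4))) for i in range(m)]
        pairs = []
        for i in range(m):
            for j in range(i + 1, m):
                if rng.random() < 0.4:
                    pairs.append((recs[i].snp_id, recs[j].snp_id, float(rng.uniform(0, 1))))
        ld = LDTable(pairs)
        kept = prune_ld(recs, ld)
        kept_ids = [r.snp_id for r in kept]
        # every kept pair independent
        for i, a in enumerate(kept_ids):
            for b in kept_ids[i + 1 :]:
                assert ld.r2(a, b) <= 0.1
        # every dropped SNP conflicts with a better-ranked kept SNP
        rank = {r.snp_id: (r.pval_height, i) for i, r in enumerate(recs)}
        for r in recs:
            if r.snp_id in kept_ids:
                continue
            assert any(
                ld.r2(r.snp_id, k) > 0.1 and rank[k] < rank[r.snp_id] for k in kept_ids
            )


class TestProxiesAndBMI:
    def test_absent_snp_substituted_by_high_ld_proxy(self):
        mapping = substitute_proxies(
            ["rs234886"], ["rs2237886"], [("rs234886", "rs2237886", 0.95)]
        )
        assert mapping["rs234886"] == "rs2237886"

    def test_low_ld_proxy_dropped(self):
        mapping = substitute_proxies(["rs1"], ["rs2"], [("rs1", "rs2", 0.85)])
        assert mapping["rs1"] is None

    def test_present_snp_maps_to_itself(self):
        mapping = substitute_proxies(["rs1"], ["rs1", "rs2"], [("rs1", "rs2", 0.99)])
        assert mapping["rs1"] == "rs1"

    def test_best_proxy_selected(self):
        mapping = substitute_proxies(
            ["rs1"],
            ["rs2", "rs3"],
            [("rs1", "rs2", 0.92), ("rs1", "rs3", 0.97)],
        )
        assert mapping["rs1"] == "rs3"

    def test_bmi_overlap_removed_by_membership_and_ld(self):
        recs = [_record("rs1"), _record("rs2"), _record("rs3")]
        ld = LDTable([("rs2", "bmi9", 0.2), ("rs3", "bmi9", 0.05)])
        out = exclude_bmi_overlap(recs, ["rs1", "bmi9"], ld)
        assert [r.snp_id for r in out] == ["rs3"]


class TestReadDosageVCF:
    VCF_TEXT = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\tP3\n"
        "1\t100\trs1\tG\tA\t.\tPASS\t.\tGT:DS\t0/1:1.1\t1/1:1.9\t0/0:0.0\n"
        "1\t200\trs2\tT\tC\t.\tPASS\t.\tGT:DS\t0/0:0.2\t./.:.\t0/1:0.8\n"
    )

    def test_ds_field_read_with_missing_as_nan(self, tmp_path):
        from heightmr.instruments import read_dosage_vcf

        p = tmp_path / "toy.vcf"
        p.write_text(self.VCF_TEXT)
        gm, alleles = read_dosage_vcf(p, return_alleles=True)
        assert gm.subject_ids == ["P1", "P2", "P3"]
        assert gm.snp_ids == ["rs1", "rs2"]
        assert gm.dosages[0, 0] == pytest.approx(1.1)
        assert np.isnan(gm.dosages[1, 1])
        # effect allele is ALT
        row = alleles.set_index("snp_id").loc["rs1"]
        assert (row["effect_allele"], row["other_allele"]) == ("A", "G")


class TestGenotypeMatrix:
    def test_call_rate_and_eaf(self):
        d = np.array([[0.0, 2.0], [1.0, np.nan], [2.0, 2.0], [1.0, 0.0]])
        gm = GenotypeMatrix(["a", "b", "c", "d"], ["s1", "s2"], d)
        assert gm.call_rate == pytest.approx([1.0, 0.75])
        assert gm.sample_eaf == pytest.approx([0.5, 4.0 / 6.0])

    def test_out_of_range_dosage_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 2\]"):
            GenotypeMatrix(["a"], ["s1"], np.array([[2.5]]))

    def test_subset_and_counts(self, rng):
        d = rng.binomial(2, 0.4, size=(30, 3)).astype(float)
        gm = GenotypeMatrix([f"P{i}" for i in range(30)], ["x", "y", "z"], d)
        sub = gm.subset(subject_ids=["P0", "P5"], snp_ids=["z"])
        assert sub.dosages.shape == (2, 1)
        hom_e, het, hom_o = gm.genotype_counts("y")
        assert hom_e + het + hom_o == 30
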