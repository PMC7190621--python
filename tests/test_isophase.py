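"""FLNC SNP calling, phasing, demultiplexing, TPM and imbalance screening."""

import math
from collections import Counter
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from haplopipe import synthetic_data as sd
from haplopipe.isophase import (
    allelic_proportion,
    call_snps,
    demultiplex,
    filter_transcript_alignments,
    fisher_one_sided,
    phase_reads,
    pileup_from_reads,
    snp_concordance,
    tissue_imbalance_test,
    tpm_normalize,
)
from oracles import fisher_tail_oracle


class TestFilterTranscriptAlignments:
    @pytest.mark.parametrize(
        "coverage,identity,kept",
        [
            (0.995, 0.96, True),
            (0.98, 0.99, False),   # coverage gate
            (0.995, 0.94, False),  # identity gate
            (0.99, 0.95, True),    # boundaries are inclusive
        ],
    )
    def test_gates(self, coverage, identity, kept):
        df = pd.DataFrame([{"transcript": "t1", "coverage": coverage, "identity": identity}])
        assert (len(filter_transcript_alignments(df)) == 1) is kept


class TestFisherOneSided:
    def test_no_signal_gives_p_one(self):
        assert fisher_one_sided([[0, 10], [0, 10]]) == pytest.approx(1.0)

    def test_fully_separated_table(self):
        assert fisher_one_sided([[10, 0], [0, 10]]) == pytest.approx(
            1 / math.comb(20, 10), abs=1e-15
        )

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_one_sided([[-1, 5], [2, 3]])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_one_sided([[0, 0], [0, 0]])

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(500):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, 4))
            if a + b + c + d == 0:
                a = 1
            p = fisher_one_sided([[a, b], [c, d]])
            assert abs(p - fisher_tail_oracle(a, b, c, d)) < 1e-12


class TestCallSnps:
    def test_balanced_heterozygous_position_is_significant(self):
        pile = [Counter({"A": 50, "G": 50})]
        calls = call_snps(pile)
        assert len(calls) == 1 and calls[0].significant
        assert {calls[0].ref_base, calls[0].alt_base} == {"A", "G"}

    def test_error_level_minor_base_is_not_significant(self):
        calls = call_snps([Counter({"A": 199, "G": 1})])
        assert len(calls) == 1 and not calls[0].significant

    def test_monomorphic_positions_are_not_tested(self):
        calls = call_snps([Counter({"A": 100}), Counter({"C": 40, "T": 40})])
        assert [c.position for c in calls] == [1]

    def test_empty_pileup_gives_empty_list(self):
        assert call_snps([]) == []

    def test_bonferroni_counts_only_tested_positions(self):
        het = Counter({"A": 30, "G": 30})
        alone = call_snps([het])[0]
        with_monomorphic = call_snps([het, Counter({"C": 99}), Counter({"T": 5})])[0]
        assert with_monomorphic.p_adjusted == alone.p_adjusted
        with_more_tests = call_snps([het] + [Counter({"A": 20, "C": 20})] * 3)[0]
        assert with_more_tests.p_adjusted >= alone.p_adjusted


def _flnc_frame(strings, gene="g1", tissue="brain"):
    return pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(len(strings))],
            "gene_id": gene,
            "isoform_id": "i1",
            "tissue": tissue,
            "alleles": strings,
        }
    )


class TestPhaseReads:
    def test_noiseless_two_haplotype_recovery(self):
        flnc = _flnc_frame(["ACG"] * 30 + ["GTA"] * 20)
        calls = call_snps(pileup_from_reads(flnc))
        res = phase_reads(flnc, calls)
        assert (res.hap1, res.hap2) == ("ACG", "GTA")
        assert res.n_ambiguous == 0
        assert all(
            v == ("hap1" if flnc.set_index("read_id").loc[k, "alleles"] == "ACG" else "hap2")
            for k, v in res.assignments.items()
        )

    def test_read_covering_only_agreeing_positions_is_ambiguous(self):
        flnc = _flnc_frame(["AAC"] * 20 + ["AAG"] * 20 + ["AA-"])
        calls = call_snps(pileup_from_reads(flnc))
        res = phase_reads(flnc, calls)
        # only position 2 separates the haplotypes; "AA-" fits both
        assert res.assignments["r40"] == "ambiguous"

    def test_partial_read_joins_unique_compatible_haplotype(self):
        flnc = _flnc_frame(["ACG"] * 20 + ["GTA"] * 20 + ["-C-"])
        res = phase_reads(flnc, call_snps(pileup_from_reads(flnc)))
        assert res.assignments["r40"] == "hap1"

    def test_single_complete_string_warns(self, caplog):
        flnc = _flnc_frame(["ACG"] * 30 + ["AC-"] * 3)
        calls = call_snps(pileup_from_reads(_flnc_frame(["ACG"] * 30 + ["GTA"] * 20)))
        with caplog.at_level("WARNING"):
            res = phase_reads(flnc, calls)
        assert res.hap2 is None
        assert any("single haplotype" in r.message for r in caplog.records)

    def test_requires_a_significant_snp(self):
        flnc = _flnc_frame(["ACG"] * 10)
        with pytest.raises(ValueError):
            phase_reads(flnc, [])

    def test_simulated_gene_recovers_haplotypes_and_assignments(self):
        models = {"g1": ["i1"]}
        snps = sd.make_snp_table(["g1"], 5, seed=61)
        flnc, truth = sd.gen_flnc_reads(models, snps, {"brain": 0.5}, 300, 0.005, seed=62)
        res = phase_reads(flnc, call_snps(pileup_from_reads(flnc)))
        mat, pat = truth.extra["haplotype_strings"]["g1"]
        assert {res.hap1, res.hap2} == {mat, pat}
        hap_of = {res.hap1: "hap1", res.hap2: "hap2"}
        want = {
            rid: hap_of[mat if h == "maternal" else pat]
            for rid, h in truth.haplotype_of_read.items()
        }
        correct = sum(res.assignments[r] == want[r] for r in want)
        assert correct / len(want) >= 0.95


class TestDemultiplexAndTpm:
    def test_counts_split_by_haplotype(self):
        flnc = _flnc_frame(["ACG"] * 10 + ["GTA"] * 6)
        assignments = {f"r{i}": ("hap1" if i < 10 else "hap2") for i in range(16)}
        counts, stats = demultiplex(assignments, flnc)
        by_hap = counts.set_index("haplotype")["count"]
        assert by_hap["hap1"] == 10 and by_hap["hap2"] == 6
        assert stats["n_hap1"] + stats["n_hap2"] + stats["n_ambiguous"] == stats["n_reads"]

    def test_all_ambiguous_reads_conserve_counts(self):
        flnc = _flnc_frame(["ACG"] * 4)
        counts, stats = demultiplex({f"r{i}": "ambiguous" for i in range(4)}, flnc)
        assert len(counts) == 0
        assert stats["n_ambiguous"] == stats["n_reads"] == 4

    def test_tpm_examples(self):
        df = pd.DataFrame(
            {"gene_id": "g", "isoform_id": ["i1", "i2"], "haplotype": "hap1",
             "tissue": "brain", "count": [5, 5]}
        )
        out = tpm_normalize(df)
        assert out["tpm"].tolist() == [500_000.0, 500_000.0]

    def test_tpm_single_row_is_a_million(self):
        df = pd.DataFrame(
            {"gene_id": ["g"], "isoform_id": ["i"], "haplotype": ["hap1"],
             "tissue": ["brain"], "count": [7]}
        )
        assert tpm_normalize(df)["tpm"].tolist() == [1_000_000.0]

    def test_zero_total_tissue_gets_zero_tpm_with_warning(self, caplog):
        df = pd.DataFrame(
            {"gene_id": ["g"], "isoform_id": ["i"], "haplotype": ["hap1"],
             "tissue": ["brain"], "count": [0]}
        )
        with caplog.at_level("WARNING"):
            out = tpm_normalize(df)
        assert out["tpm"].tolist() == [0.0]
        assert any("zero total" in r.message for r in caplog.records)

    def test_per_tissue_sums_are_exactly_one_million_in_exact_arithmetic(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "gene_id": "g",
                "isoform_id": [f"i{k}" for k in range(12)],
                "haplotype": "hap1",
                "tissue": ["brain"] * 6 + ["liver"] * 6,
                "count": rng.integers(1, 500, 12),
            }
        )
        out = tpm_normalize(df)
        for _, grp in out.groupby("tissue"):
            total = int(grp["count"].sum())
            exact = sum(Fraction(int(c) * 10**6, total) for c in grp["count"])
            assert exact == 10**6
            assert abs(grp["tpm"].sum() - 1e6) < 1e-6


class TestAllelicProportion:
    def test_eight_to_one_ratio(self):
        assert allelic_proportion(1.0, 8.0) == pytest.approx(1 / 9)

    def test_balanced_expression(self):
        assert allelic_proportion(3.0, 3.0) == 0.5

    def test_silent_paternal_allele(self):
        assert allelic_proportion(2.0, 0.0) == 1.0

    def test_both_silent_is_undefined(self):
        assert math.isnan(allelic_proportion(0.0, 0.0))

    def test_label_swap_maps_p_to_one_minus_p(self):
        rng = np.random.default_rng(10)
        for m, p in rng.random((50, 2)) + 0.01:
            assert allelic_proportion(m, p) + allelic_proportion(p, m) == pytest.approx(1.0)


class TestTissueImbalance:
    def test_normal_proportions_are_rarely_flagged(self):
        rng = np.random.default_rng(11)
        flags = 0
        for _ in range(20):
            props = rng.normal(0.5, 0.05, 200)
            _, _, flagged = tissue_imbalance_test(props)
            flags += flagged
        assert flags / 20 <= 0.10

    def test_bimodal_proportions_are_flagged(self):
        rng = np.random.default_rng(12)
        flags = 0
        for _ in range(20):
            props = np.concatenate(
                [rng.normal(0.05, 0.02, 100), rng.normal(0.95, 0.02, 100)]
            )
            _, _, flagged = tissue_imbalance_test(props)
            flags += flagged
        assert flags / 20 >= 0.95

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            tissue_imbalance_test([0.4, 0.6])


class TestSnpConcordance:
    def test_venn_regions(self):
        cov = {p: 100 for p in (1, 2, 3)}
        out = snp_concordance({1, 2, 3}, {2, 3}, {3}, cov)
        assert out["triple"] == 1 and out["iso_wgs"] == 1 and out["iso_only"] == 1
        assert out["concordance"] == pytest.approx(1 / 3)

    def test_identical_sets_are_fully_concordant(self):
        cov = {p: 50 for p in range(10)}
        out = snp_concordance(set(range(10)), set(range(10)), set(range(10)), cov)
        assert out["concordance"] == 1.0 and out["triple"] == 10

    def test_coverage_filter_drops_shared_positions(self):
        cov = {1: 100, 2: 39}
        out = snp_concordance({1, 2}, {1, 2}, {1, 2}, cov, min_cov=40)
        assert out["triple"] == 1 and out["n_iso"] == 1
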