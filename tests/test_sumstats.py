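"""I/O and allele-harmonization behavior of the summary-statistics layer."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mrcoloc import (
    ConfigurationError,
    EmptySetError,
    ExclusionReason,
    GwasRecord,
    HarmonizedSet,
    SimConfig,
    harmonize,
    read_sumstats,
    simulate_gwas_pair,
)
from conftest import make_record


class TestReadSumstats:
    def test_well_formed_table_round_trips(self, sumstats_tsv):
        path, df = sumstats_tsv
        result = read_sumstats(str(path))
        assert len(result) == 3
        assert result.n_skipped == 0
        by_id = {r.variant_id: r for r in result}
        for _, row in df.iterrows():
            rec = by_id[row["SNP"]]
            assert rec.beta == pytest.approx(row["BETA"])
            assert rec.effect_allele == row["A1"]
        # sorted by (chrom, pos): rs3 is on chr2 so it comes last
        assert [r.variant_id for r in result] == ["rs1", "rs2", "rs3"]

    def test_invalid_rows_skipped_and_counted(self, tmp_path):
        df = pd.DataFrame(
            {
                "SNP": ["rs1", "rs_bad_se", "rs_bad_eaf", "rs_indel"],
                "CHR": ["1"] * 4,
                "BP": [100, 200, 300, 400],
                "A1": ["A", "A", "A", "AT"],
                "A2": ["G", "G", "G", "A"],
                "EAF": [0.3, 0.3, 1.4, 0.3],
                "BETA": [0.1] * 4,
                "SE": [0.02, 0.0, 0.02, 0.02],
                "P": [1e-8] * 4,
                "N": [1000] * 4,
            }
        )
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        result = read_sumstats(str(path))
        assert len(result) == 1
        assert result.n_skipped == 3
        lines = sorted(line for line, _ in result.skipped)
        assert lines == [3, 4, 5]  # 1-based line numbers after the header

    def test_shuffled_columns_with_map_give_identical_records(self, tmp_path, sumstats_tsv):
        _, df = sumstats_tsv
        renamed = df.rename(columns={"SNP": "rsid", "BETA": "effect", "P": "pval"})
        shuffled = renamed[list(reversed(renamed.columns))]
        path = tmp_path / "shuffled.tsv"
        shuffled.to_csv(path, sep="\t", index=False)
        result = read_sumstats(
            str(path), column_map={"variant_id": "rsid", "beta": "effect", "pvalue": "pval"}
        )
        expected = [
            make_record("rs1", "1", 1000, "A", "G", 0.3, 0.10, 0.02, 1e-8, 20000),
            make_record("rs2", "1", 2000, "C", "T", 0.45, -0.05, 0.01, 5e-7, 20000),
            make_record("rs3", "2", 500, "G", "A", 0.12, 0.02, 0.005, 2e-4, 20000),
        ]
        assert list(result) == expected

    def test_gzip_input(self, tmp_path, sumstats_tsv):
        _, df = sumstats_tsv
        path = tmp_path / "sumstats.tsv.gz"
        df.to_csv(path, sep="\t", index=False, compression="gzip")
        assert len(read_sumstats(str(path))) == 3

    def test_missing_column_is_configuration_error(self, tmp_path, sumstats_tsv):
        _, df = sumstats_tsv
        path = tmp_path / "noeaf.tsv"
        df.drop(columns=["EAF"]).to_csv(path, sep="\t", index=False)
        with pytest.raises(ConfigurationError):
            read_sumstats(str(path))


class TestHarmonize:
    def test_identical_orientation_passes_through(self):
        ex = [make_record("rs1", beta=0.10)]
        out = [make_record("rs1", beta=-0.05, eaf=0.3)]
        hs = harmonize(ex, out)
        assert hs.n_snps == 1
        p = hs.pairs[0]
        assert p.beta_outcome == pytest.approx(-0.05)
        assert p.eaf_outcome == pytest.approx(0.3)

    def test_swapped_alleles_flip_beta_and_eaf(self):
        ex = [make_record("rs1", effect_allele="A", other_allele="G", beta=0.10)]
        out = [make_record("rs1", effect_allele="G", other_allele="A", beta=-0.05, eaf=0.30)]
        hs = harmonize(ex, out)
        p = hs.pairs[0]
        assert p.beta_outcome == pytest.approx(0.05)
        assert p.eaf_outcome == pytest.approx(0.70)

    def test_palindromic_excluded(self):
        ex = [make_record("rs1", effect_allele="A", other_allele="T", beta=0.10),
              make_record("rs2", pos=5000, beta=0.2)]
        out = [make_record("rs1", effect_allele="A", other_allele="T", beta=0.02),
               make_record("rs2", pos=5000, beta=0.1)]
        hs = harmonize(ex, out)
        assert hs.variant_ids == ["rs2"]
        assert ("rs1", ExclusionReason.PALINDROMIC) in hs.exclusions

    def test_incompatible_and_missing_reasons(self):
        ex = [make_record("rs1", effect_allele="A", other_allele="G"),
              make_record("rs2", pos=2000), make_record("rs3", pos=3000)]
        out = [make_record("rs1", effect_allele="A", other_allele="C"),
               make_record("rs2", pos=2000)]
        hs = harmonize(ex, out)
        reasons = dict(hs.exclusions)
        assert reasons["rs1"] == ExclusionReason.INCOMPATIBLE_ALLELES
        assert reasons["rs3"] == ExclusionReason.MISSING_IN_OUTCOME

    def test_empty_intersection_raises(self):
        with pytest.raises(EmptySetError, match="brainX.*disease"):
            harmonize(
                [make_record("rs1")],
                [make_record("rs2", pos=2000)],
                "brainX", "disease",
            )

    def test_orientation_invariance(self):
        """Flipping every outcome record's alleles (and negating beta,
        complementing eaf) must leave the harmonized pairs unchanged."""
        ex, out, _ = simulate_gwas_pair(SimConfig(n_snps=30, pi_causal=1.0, seed=11))
        flipped = [
            dataclasses.replace(
                r,
                effect_allele=r.other_allele,
                other_allele=r.effect_allele,
                beta=-r.beta,
                eaf=1.0 - r.eaf,
            )
            for r in out
        ]
        hs_a = harmonize(ex, out)
        hs_b = harmonize(ex, flipped)
        np.testing.assert_allclose(hs_a.beta_outcome, hs_b.beta_outcome)
        np.testing.assert_allclose(
            [p.eaf_outcome for p in hs_a.pairs], [p.eaf_outcome for p in hs_b.pairs]
        )

    def test_harmonization_idempotence(self):
        """Re-harmonizing records reconstructed from an already-harmonized
        set returns identical pairs."""
        ex, out, _ = simulate_gwas_pair(SimConfig(n_snps=20, pi_causal=1.0, seed=3))
        hs = harmonize(ex, out)
        ex_by_id = {r.variant_id: r for r in ex}
        rebuilt_outcome = [
            dataclasses.replace(
                ex_by_id[p.variant_id],
                beta=p.beta_outcome, se=p.se_outcome, eaf=p.eaf_outcome,
                pvalue=p.pval_outcome, n=p.n_outcome,
            )
            for p in hs.pairs
        ]
        hs2 = harmonize([ex_by_id[v] for v in hs.variant_ids], rebuilt_outcome)
        assert hs2.variant_ids == hs.variant_ids
        np.testing.assert_array_equal(hs2.beta_outcome, hs.beta_outcome)

    def test_partition_accounting(self):
        """Every exposure variant lands in exactly one of pairs/exclusions."""
        ex = [
            make_record("rs1"),
            make_record("rs2", pos=2000, effect_allele="C", other_allele="G"),
            make_record("rs3", pos=3000),
            make_record("rs4", pos=4000),
        ]
        out = [
            make_record("rs1"),
            make_record("rs2", pos=2000, effect_allele="C", other_allele="G"),
            make_record("rs4", pos=4000, effect_allele="C", other_allele="T"),
        ]
        hs = harmonize(ex, out)
        assert hs.n_snps + len(hs.exclusions) == len(ex)
        assert {v for v, _ in hs.exclusions} | set(hs.variant_ids) == {
            r.variant_id for r in ex
        }

    def test_no_variant_in_both_pairs_and_exclusions(self):
        hs = HarmonizedSet.from_arrays([0.1], [0.01], [0.05], [0.02], ["rs1"])
        with pytest.raises(ValueError):
            HarmonizedSet("x", "y", hs.pairs, [("rs1", ExclusionReason.CONFOUNDER)])
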