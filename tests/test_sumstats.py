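"""Summary-statistic records, conversions and file round-trips."""

import math

import numpy as np
import pytest
from scipy import stats

from locusfine import (
    LocusTable,
    VariantRecord,
    neglog10p_from_z,
    p_from_z,
    read_sumstats,
    write_sumstats,
    z_from_beta_se,
    z_from_p,
)
from locusfine.sumstats import (
    ConfigurationError,
    EmptyInputError,
    SumstatsError,
    fold_maf,
    harmonize_alleles,
)

from conftest import make_record


class TestConversions:
    @pytest.mark.parametrize(
        "beta,se,expected",
        [(0.05, 0.01, 5.0), (0.0, 0.1, 0.0), (-0.02, 0.004, -5.0)],
    )
    def test_wald_z(self, beta, se, expected):
        assert z_from_beta_se(beta, se) == pytest.approx(expected)

    def test_wald_z_rejects_nonpositive_se(self):
        with pytest.raises(SumstatsError):
            z_from_beta_se(0.1, 0.0)

    @pytest.mark.parametrize(
        "p,sign,expected",
        [(1.0, 1, 0.0), (0.05, 1, 1.959964), (0.05, -1, -1.959964)],
    )
    def test_z_from_p(self, p, sign, expected):
        assert z_from_p(p, sign) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_z_from_p_domain(self, p):
        with pytest.raises(SumstatsError):
            z_from_p(p)

    def test_z_p_roundtrip(self):
        for z in np.concatenate([np.linspace(0.1, 37, 50), [-5.0, -20.0]]):
            back = z_from_p(p_from_z(z), 1 if z > 0 else -1)
            assert back == pytest.approx(z, rel=1e-8)

    @pytest.mark.parametrize(
        "z,expected", [(0.0, 0.0), (1.959964, 1.30103)]
    )
    def test_neglog10p_small_z(self, z, expected):
        assert neglog10p_from_z(z) == pytest.approx(expected, abs=1e-5)

    def test_neglog10p_beyond_underflow(self):
        # at z = 40 the p-value (~1e-350) is below the double-precision
        # floor; the log-survival route must stay finite and accurate.
        # Oracle: -log10(erfc(40/sqrt(2))) evaluated in arbitrary
        # precision with sympy gives 349.13597646368186.
        val = neglog10p_from_z(40.0)
        assert math.isfinite(val) and val > 300
        assert val == pytest.approx(349.13597646368186, rel=1e-6)

    def test_neglog10p_matches_direct_log_in_representable_range(self):
        for z in np.linspace(0.5, 35, 40):
            direct = -math.log10(2 * stats.norm.sf(z))
            assert neglog10p_from_z(z) == pytest.approx(direct, rel=1e-10)

    def test_neglog10p_rejects_nonfinite(self):
        with pytest.raises(SumstatsError):
            neglog10p_from_z(float("inf"))


class TestRecordInvariants:
    def test_maf_folding(self):
        rec = make_record(maf=0.7)
        assert rec.maf == pytest.approx(0.3)

    def test_maf_folding_idempotent(self):
        assert fold_maf(fold_maf(0.9)) == fold_maf(0.9)

    @pytest.mark.parametrize("kw", [{"se": 0.0}, {"p": 0.0}, {"p": 1.5}, {"pos": 0}])
    def test_invalid_records_rejected(self, kw):
        base = dict(rsid="rs1", chrom="2", pos=10, beta=0.1, se=0.01, p=0.5)
        base.update(kw)
        with pytest.raises(SumstatsError):
            VariantRecord(**base)

    def test_table_sorts_and_rejects_duplicates(self):
        a, b = make_record("rs1", 500), make_record("rs2", 100)
        t = LocusTable((a, b))
        assert t.rsids == ["rs2", "rs1"]
        with pytest.raises(SumstatsError):
            LocusTable((a, a))

    def test_table_single_chromosome(self):
        a = make_record("rs1", 100)
        b = VariantRecord(rsid="rs2", chrom="3", pos=200)
        with pytest.raises(SumstatsError):
            LocusTable((a, b))


class TestFileIO:
    def _write(self, tmp_path, text):
        path = tmp_path / "ss.tsv"
        path.write_text(text)
        return path

    def test_three_row_ingestion(self, tmp_path):
        path = self._write(
            tmp_path,
            "SNP\tCHR\tPOS\tBETA\tSE\tP\tMAF\tN\n"
            "rs3\t2\t300\t0.01\t0.005\t0.045\t0.2\t1000\n"
            "rs1\t2\t100\t0.02\t0.005\t6e-5\t0.3\t1000\n"
            "rs2\t2\t200\t0.03\t0.005\t2e-9\t0.4\t1000\n",
        )
        table, failures = read_sumstats(path)
        assert len(table) == 3 and not failures
        assert table.rsids == ["rs1", "rs2", "rs3"]

    def test_bad_rows_rejected_with_reason(self, tmp_path):
        path = self._write(
            tmp_path,
            "SNP\tCHR\tPOS\tBETA\tSE\tP\n"
            "rs1\t2\t100\t0.02\t0.005\t1e-5\n"
            "rs2\t2\t200\t0.03\t0\t1e-9\n",
        )
        table, failures = read_sumstats(path)
        assert len(table) == 1
        assert failures[0].rsid == "rs2"
        assert failures[0].reason == "nonpositive SE"

    def test_maf_folded_on_read(self, tmp_path):
        path = self._write(
            tmp_path,
            "SNP\tCHR\tPOS\tMAF\nrs1\t2\t100\t0.7\n",
        )
        table, _ = read_sumstats(path)
        assert table.records[0].maf == pytest.approx(0.3)

    def test_missing_mapped_column_is_configuration_error(self, tmp_path):
        path = self._write(tmp_path, "SNP\tCHR\nrs1\t2\n")
        with pytest.raises(ConfigurationError):
            read_sumstats(path, column_map={"rsid": "SNP", "chrom": "CHR", "pos": "BP"})

    def test_all_rows_invalid_is_empty_input(self, tmp_path):
        path = self._write(
            tmp_path, "SNP\tCHR\tPOS\tSE\nrs1\t2\t100\t0\n"
        )
        with pytest.raises(EmptyInputError):
            read_sumstats(path)

    def test_roundtrip_identity(self, tmp_path):
        recs = tuple(
            make_record(f"rs{i}", 100 + i, beta=0.01 * i + 0.001,
                        functional_rank="1b" if i == 2 else None)
            for i in range(5)
        )
        table = LocusTable(recs)
        out = tmp_path / "out.tsv"
        write_sumstats(table, out)
        back, failures = read_sumstats(out)
        assert not failures
        for a, b in zip(table.records, back.records):
            assert a.rsid == b.rsid and a.pos == b.pos
            assert a.beta == pytest.approx(b.beta, rel=1e-12)
            assert a.se == pytest.approx(b.se, rel=1e-12)
            assert a.functional_rank == b.functional_rank

    def test_empty_table_roundtrip(self, tmp_path):
        out = tmp_path / "empty.tsv"
        write_sumstats(LocusTable(()), out)
        with pytest.raises(EmptyInputError):
            read_sumstats(out)


class TestHarmonization:
    def test_exact_match_passthrough(self):
        rec = make_record(effect_allele="A", other_allele="G")
        assert harmonize_alleles(rec, "A", "G") is rec

    def test_swap_flips_sign(self):
        rec = make_record(beta=0.05, effect_allele="A", other_allele="G")
        out = harmonize_alleles(rec, "G", "A")
        assert out.beta == pytest.approx(-0.05)

    def test_mismatch_rejected(self):
        rec = make_record(effect_allele="A", other_allele="G")
        with pytest.raises(SumstatsError):
            harmonize_alleles(rec, "A", "C")
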