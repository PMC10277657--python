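"""Reading, validation, instrument selection and allele harmonisation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mrbias.gwas_io import (NoInstrumentsError, SummaryStats,
                            SummaryStatsError, harmonise, read_summary_stats,
                            select_instruments, write_summary_stats)

from conftest import make_sumstats

HEADER = ("variant_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta"
          "\tse\tpvalue\tn\n")


def _write(tmp_path, body, name="stats.tsv", header=HEADER):
    path = tmp_path / name
    path.write_text(header + body)
    return path


class TestReadSummaryStats:
    def test_direct_parse(self, tmp_path):
        path = _write(tmp_path, "rs1\t1\t100\tA\tG\t0.3\t0.10\t0.02\t5e-7\t10000\n")
        stats = read_summary_stats(path)
        row = stats.data.iloc[0]
        assert row["beta"] == 0.10 and row["se"] == 0.02
        assert row["effect_allele"] == "A" and row["pos"] == 100

    def test_zero_se_row_dropped(self, tmp_path):
        body = ("rs1\t1\t100\tA\tG\t0.3\t0.10\t0.02\t5e-7\t10000\n"
                "rs2\t1\t200\tC\tT\t0.3\t0.10\t0\t5e-7\t10000\n")
        stats = read_summary_stats(_write(tmp_path, body))
        assert stats.n_variants == 1
        assert "1 rows dropped" in stats.provenance

    def test_missing_p_recomputed_from_normal_tail(self, tmp_path):
        header = "variant_id\tchrom\tpos\teffect_allele\tother_allele\tbeta\tse\n"
        path = _write(tmp_path, "rs1\t1\t100\tA\tG\t0.10\t0.02\n", header=header)
        stats = read_summary_stats(path)
        expected = 2.0 * sps.norm.sf(0.10 / 0.02)  # independent oracle
        assert stats.data["pvalue"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(5.733e-7, rel=1e-3)

    def test_missing_required_column_errors(self, tmp_path):
        header = "variant_id\tchrom\tpos\teffect_allele\tother_allele\tbeta\n"
        path = _write(tmp_path, "rs1\t1\t100\tA\tG\t0.10\n", header=header)
        with pytest.raises(SummaryStatsError, match="se"):
            read_summary_stats(path)

    def test_zero_valid_rows_errors(self, tmp_path):
        path = _write(tmp_path, "rs1\t1\t100\tA\tA\t0.3\t0.1\t0.02\t0.5\t100\n")
        with pytest.raises(SummaryStatsError, match="no valid rows"):
            read_summary_stats(path)

    def test_column_map_and_csv(self, tmp_path):
        path = tmp_path / "dialect.csv"
        path.write_text("SNP,CHR,BP,A1,A2,b,SE,P\nrs9,2,500,G,A,0.05,0.01,0.2\n")
        stats = read_summary_stats(path, column_map={
            "variant_id": "SNP", "chrom": "CHR", "pos": "BP",
            "effect_allele": "A1", "other_allele": "A2", "beta": "b",
            "se": "SE", "pvalue": "P"})
        assert stats.data["beta"].iloc[0] == 0.05

    def test_roundtrip_via_writer(self, tmp_path):
        stats = make_sumstats([
            dict(variant_id="rs1", chrom="1", pos=100, effect_allele="A",
                 other_allele="G", eaf=0.3, beta=0.1, se=0.02,
                 pvalue=5e-7, n=1000)])
        write_summary_stats(stats, tmp_path / "out.tsv")
        back = read_summary_stats(tmp_path / "out.tsv")
        pd.testing.assert_frame_equal(back.data[["variant_id", "beta", "se"]],
                                      stats.data[["variant_id", "beta", "se"]])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(SummaryStatsError, match="duplicate"):
            make_sumstats([
                dict(variant_id="rs1", effect_allele="A", other_allele="G",
                     beta=0.1, se=0.01),
                dict(variant_id="rs1", effect_allele="C", other_allele="T",
                     beta=0.2, se=0.01)])


def _variants(ps, positions=None, chrom="1"):
    rows = []
    for i, p in enumerate(ps):
        rows.append(dict(variant_id=f"rs{i+1}", chrom=chrom,
                         pos=positions[i] if positions else (i + 1) * 10**6,
                         effect_allele="A", other_allele="G", eaf=0.3,
                         beta=0.1, se=0.02, pvalue=p, n=1000))
    return make_sumstats(rows)


class TestSelectInstruments:
    def test_threshold_filter(self):
        stats = _variants([1e-9, 1e-4, 1e-10])
        out = select_instruments(stats, 5e-8, 0)
        assert out.n_variants == 2

    def test_greedy_window_keeps_smallest_p(self):
        stats = _variants([1e-9, 1e-12], positions=[100_000, 150_000])
        out = select_instruments(stats, 5e-8, 250_000)
        assert list(out.data["variant_id"]) == ["rs2"]

    def test_relaxed_threshold_rescues_subthreshold_hits(self):
        stats = _variants([1e-6, 2e-6, 4e-6])
        with pytest.raises(NoInstrumentsError):
            select_instruments(stats, 5e-8, 0)
        assert select_instruments(stats, 5e-6, 0).n_variants == 3

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(ps=st.lists(st.floats(1e-12, 0.99), min_size=1, max_size=20),
           thr1=st.floats(1e-10, 0.5), thr2=st.floats(1e-10, 0.5))
    def test_subset_and_monotone_in_threshold(self, ps, thr1, thr2):
        stats = _variants(ps)
        lo, hi = sorted([thr1, thr2])

        def ids(th):
            try:
                return set(select_instruments(stats, th, 0).data["variant_id"])
            except NoInstrumentsError:
                return set()

        assert ids(lo) <= ids(hi) <= set(stats.data["variant_id"])


def _pair(exp_row, out_row):
    e = make_sumstats([dict(variant_id="rs1", chrom="1", pos=1, **exp_row)])
    o = make_sumstats([dict(variant_id="rs1", chrom="1", pos=1, **out_row)],
                      trait_name="outcome", trait_type="binary")
    return e, o


class TestHarmonise:
    def test_allele_swap_flips_outcome_beta(self):
        e, o = _pair(dict(effect_allele="A", other_allele="G", eaf=0.3,
                          beta=0.10, se=0.02),
                     dict(effect_allele="G", other_allele="A", eaf=0.7,
                          beta=0.05, se=0.01))
        h = harmonise(e, o)
        assert h.beta_outcome[0] == pytest.approx(-0.05)
        assert h.flags["action"].iloc[0] == "flipped"

    def test_palindrome_near_half_freq_dropped(self):
        e, o = _pair(dict(effect_allele="A", other_allele="T", eaf=0.50,
                          beta=0.10, se=0.02),
                     dict(effect_allele="A", other_allele="T", eaf=0.52,
                          beta=0.05, se=0.01))
        with pytest.raises(SummaryStatsError):
            harmonise(e, o)  # only variant dropped -> empty intersection

    def test_palindrome_strand_flip_resolved_by_eaf(self):
        # outcome eaf 0.88 matches 1-0.10 better than 0.10 -> strand flip
        e, o = _pair(dict(effect_allele="A", other_allele="T", eaf=0.10,
                          beta=0.10, se=0.02),
                     dict(effect_allele="A", other_allele="T", eaf=0.88,
                          beta=0.05, se=0.01))
        h = harmonise(e, o)
        assert h.beta_outcome[0] == pytest.approx(-0.05)
        assert h.flags["action"].iloc[0] == "flipped"

    def test_palindrome_missing_eaf_dropped(self):
        e, o = _pair(dict(effect_allele="C", other_allele="G", eaf=np.nan,
                          beta=0.10, se=0.02),
                     dict(effect_allele="C", other_allele="G", eaf=0.2,
                          beta=0.05, se=0.01))
        with pytest.raises(SummaryStatsError):
            harmonise(e, o)

    def test_complement_strand_match(self):
        e, o = _pair(dict(effect_allele="A", other_allele="G", eaf=0.3,
                          beta=0.10, se=0.02),
                     dict(effect_allele="T", other_allele="C", eaf=0.3,
                          beta=0.05, se=0.01))
        h = harmonise(e, o)
        assert h.beta_outcome[0] == pytest.approx(0.05)
        assert h.flags["action"].iloc[0] == "kept"

    def test_mismatched_alleles_dropped(self):
        e, o = _pair(dict(effect_allele="A", other_allele="G", eaf=0.3,
                          beta=0.10, se=0.02),
                     dict(effect_allele="A", other_allele="C", eaf=0.3,
                          beta=0.05, se=0.01))
        with pytest.raises(SummaryStatsError):
            harmonise(e, o)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(beta=st.floats(-0.5, 0.5), eaf=st.floats(0.05, 0.95),
           swap=st.booleans())
    def test_idempotent_and_involution(self, beta, eaf, swap):
        exp = dict(effect_allele="A", other_allele="G", eaf=0.3,
                   beta=0.10, se=0.02)
        out = (dict(effect_allele="G", other_allele="A", eaf=1 - eaf,
                    beta=-beta, se=0.01) if swap else
               dict(effect_allele="A", other_allele="G", eaf=eaf,
                    beta=beta, se=0.01))
        e, o = _pair(exp, out)
        h = harmonise(e, o)
        # involution: flipping both alleles and negating beta is a no-op
        assert h.beta_outcome[0] == pytest.approx(beta)
        # idempotence: re-harmonising the already-aligned pair changes nothing
        o2 = make_sumstats([dict(variant_id="rs1", chrom="1", pos=1,
                                 effect_allele="A", other_allele="G",
                                 eaf=float(h.flags.shape[0]) * 0 + eaf,
                                 beta=float(h.beta_outcome[0]), se=0.01)],
                           trait_type="binary")
        h2 = harmonise(e, o2)
        assert h2.beta_outcome[0] == pytest.approx(h.beta_outcome[0])
        assert h2.flags["action"].iloc[0] == "kept"

    def test_multi_outcome_intersection(self):
        e = make_sumstats([
            dict(variant_id=f"rs{i}", chrom="1", pos=i, effect_allele="A",
                 other_allele="G", eaf=0.3, beta=0.1, se=0.02)
            for i in (1, 2, 3)])
        o1 = make_sumstats([
            dict(variant_id=f"rs{i}", chrom="1", pos=i, effect_allele="A",
                 other_allele="G", eaf=0.3, beta=0.05, se=0.01)
            for i in (1, 2)], trait_name="o1", trait_type="binary")
        o2 = make_sumstats([
            dict(variant_id=f"rs{i}", chrom="1", pos=i, effect_allele="A",
                 other_allele="G", eaf=0.3, beta=0.02, se=0.01)
            for i in (2, 3)], trait_name="o2", trait_type="binary")
        sets = harmonise(e, [o1, o2])
        assert [list(h.variant_ids) for h in sets] == [["rs2"], ["rs2"]]
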