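"""Summary-statistics I/O, validation and allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from statemr.core_io import (
    ConfigurationError,
    EmptyOverlapError,
    GenomicInterval,
    SumstatTable,
    align_to_reference,
    harmonize,
    kept_pairs,
    make_sumstats,
    read_ld_reference,
    read_sumstats,
    write_sumstats,
)

from helpers import quick_table, sumstat_frame


class TestReadValidate:
    def test_well_formed_round_trip(self, tmp_path):
        """Read -> write -> read reproduces every field for exact-decimal input."""
        path = tmp_path / "sumstats.tsv"
        path.write_text(
            "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"
            "rs1\t1\t100\tA\tG\t0.25\t0.5\t0.1\t5.733031e-07\t500\n"
            "rs2\t1\t200\tT\tC\t0.5\t-0.25\t0.25\t0.3173105\t500\n"
            "rs3\t1\t300\tG\tC\t0.125\t0.0625\t0.5\t0.9004989\t500\n")
        table = read_sumstats(path, trait_id="t")
        assert len(table) == 3 and table.audit == []
        out = tmp_path / "again.tsv"
        write_sumstats(table, out)
        again = read_sumstats(out, trait_id="t")
        pd.testing.assert_frame_equal(table.frame, again.frame)

    def test_zero_se_row_dropped_and_audited(self):
        frame = sumstat_frame(["rs1", "rs2"], [0.5, 0.3], [0.1, 0.0])
        table = make_sumstats(frame, "t", "quantitative")
        assert len(table) == 1
        assert [a for a in table.audit if a["reason"] == "nonpositive_se"]

    def test_pval_recomputed_from_z_when_absent(self):
        """beta=0.5, se=0.1 gives the two-sided normal p of |z|=5."""
        table = quick_table(["rs1"], [0.5], [0.1])
        expected = 2 * stats.norm.sf(5.0)
        assert table.frame["pval"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(5.733e-7, rel=1e-3)

    def test_inconsistent_pval_dropped(self):
        frame = sumstat_frame(["rs1"], [0.5], [0.1], pvals=[0.5])
        with pytest.raises(Exception):
            make_sumstats(frame, "t", "quantitative")  # only row dropped -> empty

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("SNP\tCHR\tPOS\tEA\tOA\tBETA\nrs1\t1\t1\tA\tG\t0.1\n")
        with pytest.raises(ConfigurationError, match="se"):
            read_sumstats(path)

    def test_dialect_mapping(self, tmp_path):
        path = tmp_path / "alt.tsv"
        path.write_text("rsid\tchr\tbp\ta1\ta2\tb\tstderr\n"
                        "rs1\t2\t50\tA\tG\t0.2\t0.05\n")
        dialect = {"snp_id": "rsid", "chrom": "chr", "pos": "bp", "effect_allele": "a1",
                   "other_allele": "a2", "beta": "b", "se": "stderr"}
        table = read_sumstats(path, dialect, trait_id="t")
        assert table.frame["snp_id"].tolist() == ["rs1"]

    def test_binary_trait_requires_consistent_counts(self):
        frame = sumstat_frame(["rs1"], [0.1], [0.02], n=150, n_case=50, n_control=100)
        table = make_sumstats(frame, "t", "binary")
        assert table.frame["n"].iloc[0] == 150
        bad = sumstat_frame(["rs1"], [0.1], [0.02], n=999, n_case=50, n_control=100)
        with pytest.raises(Exception):
            make_sumstats(bad, "t", "binary")


class TestLDReference:
    def test_duplicate_snp_has_unit_correlation(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, size=200).astype(float)
        dosages = np.column_stack([a, a, rng.integers(0, 3, 200)])
        meta = pd.DataFrame({"snp_id": ["a", "b", "c"], "chrom": "1",
                             "pos": [1, 2, 3], "ref_effect_allele": "A",
                             "ref_other_allele": "G", "freq": 0.5})
        from statemr.core_io import LDReference
        ld = LDReference.from_dosages(dosages, meta)
        assert ld.corr[0, 1] == pytest.approx(1.0)

    def test_permuted_columns_near_zero_correlation(self):
        """Independently permuted columns: null sampling distribution of r."""
        rng = np.random.default_rng(1)
        base = rng.integers(0, 3, size=(500, 40)).astype(float)
        for j in range(40):
            rng.shuffle(base[:, j])
        meta = pd.DataFrame({"snp_id": [f"s{j}" for j in range(40)], "chrom": "1",
                             "pos": np.arange(40) + 1, "ref_effect_allele": "A",
                             "ref_other_allele": "G", "freq": 0.5})
        from statemr.core_io import LDReference
        ld = LDReference.from_dosages(base, meta)
        off = np.abs(ld.corr[np.triu_indices(40, 1)])
        assert np.mean(off) < 0.06
        assert np.quantile(off, 0.95) < 0.12

    def test_monomorphic_snp_excluded_and_logged(self):
        dosages = np.column_stack([np.full(100, 2.0),
                                   np.random.default_rng(2).integers(0, 3, 100)])
        meta = pd.DataFrame({"snp_id": ["mono", "poly"], "chrom": "1", "pos": [1, 2],
                             "ref_effect_allele": "A", "ref_other_allele": "G",
                             "freq": [1.0, 0.5]})
        from statemr.core_io import LDReference
        ld = LDReference.from_dosages(dosages, meta)
        assert ld.snp_ids.tolist() == ["poly"]
        assert ld.audit[0]["snp_id"] == "mono"

    def test_read_ld_reference_dimension_mismatch(self, tmp_path, panel_small):
        panel_small.write(tmp_path / "p")
        bad = pd.read_csv(tmp_path / "p.snps.tsv", sep="\t").iloc[:-1]
        bad.to_csv(tmp_path / "p.snps.tsv", sep="\t", index=False)
        from statemr.core_io import FormatError
        with pytest.raises(FormatError):
            read_ld_reference(tmp_path / "p.dosages.tsv", tmp_path / "p.snps.tsv")

    def test_panel_round_trip(self, tmp_path, panel_small):
        panel_small.write(tmp_path / "p")
        again = read_ld_reference(tmp_path / "p.dosages.tsv", tmp_path / "p.snps.tsv")
        np.testing.assert_allclose(again.corr, panel_small.corr, atol=1e-12)
        assert again.snp_ids.tolist() == panel_small.snp_ids.tolist()


def _pair_tables(exp_rows, out_rows):
    e = make_sumstats(pd.DataFrame(exp_rows), "exp", "quantitative")
    o = make_sumstats(pd.DataFrame(out_rows), "out", "quantitative")
    return e, o


def _row(sid, ea, oa, beta, eaf, pos=100):
    return {"snp_id": sid, "chrom": "1", "pos": pos, "effect_allele": ea,
            "other_allele": oa, "eaf": eaf, "beta": beta, "se": 0.1, "n": 500}


class TestHarmonize:
    @pytest.mark.parametrize(
        "out_alleles,beta_out,expected_action,expected_beta",
        [
            (("A", "G"), -0.2, "kept", -0.2),
            (("G", "A"), -0.2, "sign_flipped", 0.2),  # allele swap symmetry
            (("T", "C"), -0.2, "kept", -0.2),  # strand flip, same orientation
            (("C", "T"), -0.2, "sign_flipped", 0.2),  # strand flip + swap
            (("A", "C"), -0.2, "dropped_incompatible", None),
        ])
    def test_orientations(self, out_alleles, beta_out, expected_action, expected_beta):
        e, o = _pair_tables([_row("rs1", "A", "G", 0.3, 0.2)],
                            [_row("rs1", out_alleles[0], out_alleles[1], beta_out, 0.2)])
        pairs = harmonize(e, o)
        assert pairs["action"].iloc[0] == expected_action
        if expected_beta is not None:
            assert pairs["beta_out"].iloc[0] == pytest.approx(expected_beta)

    def test_palindromic_high_maf_dropped(self):
        e, o = _pair_tables([_row("rs1", "A", "T", 0.3, 0.50)],
                            [_row("rs1", "A", "T", 0.1, 0.50)])
        pairs = harmonize(e, o, palindromic_maf_cut=0.42)
        assert pairs["action"].iloc[0] == "dropped_palindromic"

    def test_palindromic_frequency_alignment(self):
        """Low-MAF palindromic SNP with opposing frequencies implies a strand
        flip of the effect allele, so the sign is flipped."""
        e, o = _pair_tables([_row("rs1", "A", "T", 0.3, 0.10)],
                            [_row("rs1", "A", "T", 0.1, 0.90)])
        pairs = harmonize(e, o, palindromic_maf_cut=0.42)
        assert pairs["action"].iloc[0] == "sign_flipped"
        assert pairs["beta_out"].iloc[0] == pytest.approx(-0.1)

    def test_no_overlap_raises(self):
        e, o = _pair_tables([_row("rs1", "A", "G", 0.3, 0.2)],
                            [_row("rs2", "A", "G", 0.1, 0.2)])
        with pytest.raises(EmptyOverlapError):
            harmonize(e, o)

    def test_idempotence(self, rng):
        """Harmonizing an already-harmonized pair changes nothing."""
        n = 30
        alleles = [("A", "G"), ("T", "C"), ("G", "T")]
        exp_rows, out_rows = [], []
        for i in range(n):
            ea, oa = alleles[i % 3]
            eaf = float(rng.uniform(0.05, 0.95))
            exp_rows.append(_row(f"rs{i}", ea, oa, float(rng.normal()), eaf, pos=100 + i))
            swap = rng.random() < 0.5
            out_rows.append(_row(f"rs{i}", oa if swap else ea, ea if swap else oa,
                                 float(rng.normal()), 1 - eaf if swap else eaf, pos=100 + i))
        e, o = _pair_tables(exp_rows, out_rows)
        pairs = kept_pairs(harmonize(e, o))
        # rebuild tables from the harmonized pair and harmonize again
        o2_rows = [_row(r.snp_id, r.effect_allele, r.other_allele, r.beta_out,
                        r.eaf_out, pos=r.pos) for r in pairs.itertuples(index=False)]
        for row, se in zip(o2_rows, pairs["se_out"]):
            row["se"] = se
        e2, o2 = _pair_tables(
            [_row(r.snp_id, r.effect_allele, r.other_allele, r.beta_exp, r.eaf_exp,
                  pos=r.pos) for r in pairs.itertuples(index=False)], o2_rows)
        pairs2 = harmonize(e2, o2)
        assert (pairs2["action"] == "kept").all()
        merged = pairs.merge(pairs2, on="snp_id", suffixes=("_1", "_2"))
        np.testing.assert_allclose(merged["beta_out_1"], merged["beta_out_2"])


def test_align_to_reference_flips_signs(panel_small):
    """Swapping a record's alleles and negating beta is a no-op after alignment."""
    from helpers import table_from_z
    rng = np.random.default_rng(3)
    z = rng.normal(size=panel_small.n_snps)
    table = table_from_z(panel_small, z, n=500)
    flipped = table.frame.copy()
    sel = flipped.index[::3]
    flipped.loc[sel, ["effect_allele", "other_allele"]] = (
        flipped.loc[sel, ["other_allele", "effect_allele"]].to_numpy())
    flipped.loc[sel, "beta"] *= -1
    flipped.loc[sel, "eaf"] = 1 - flipped.loc[sel, "eaf"]
    t2 = SumstatTable("t", "quantitative", flipped)
    a1 = align_to_reference(table, panel_small)
    a2 = align_to_reference(t2, panel_small)
    np.testing.assert_allclose(a1.frame["beta"], a2.frame["beta"])


def test_interval_membership_is_half_open():
    iv = GenomicInterval("1", 100, 200)
    assert iv.contains_pos1(101) and iv.contains_pos1(200)
    assert not iv.contains_pos1(100) and not iv.contains_pos1(201)
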