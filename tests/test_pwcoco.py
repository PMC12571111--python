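"""Colocalisation posteriors, conditional analysis and region decomposition."""

import numpy as np
import pytest

from statemr.core_io import DomainError, align_to_reference
from statemr.pwcoco import (
    ColocPriors,
    PairwiseConditionalColoc,
    cojo_condition,
    cojo_select,
    coloc_abf,
    prior_expectations,
    pwcoco_region,
    wakefield_abf,
)
from statemr.synthetic import Scenario, simulate_ld_panel, simulate_region_sumstats

from helpers import joint_ols_z, marginal_ols_stats, oracle_coloc_enumeration, \
    quick_table, table_from_z


class TestWakefieldABF:
    def test_null_z_shrinks_toward_h0(self):
        labf = wakefield_abf(0.0, 0.1, 0.2)
        r = 0.04 / (0.01 + 0.04)
        assert labf == pytest.approx(0.5 * np.log(1 - r))
        assert labf < 0

    def test_vanishing_prior_sd_limit(self):
        assert wakefield_abf(0.3, 0.1, 1e-8) == pytest.approx(0.0, abs=1e-10)

    def test_strong_association_value(self):
        """beta=0.1, se=0.01, prior_sd=0.2: log ABF ~ 46.88."""
        labf = wakefield_abf(0.1, 0.01, 0.2)
        r = 0.04 / (0.0001 + 0.04)
        expected = 0.5 * np.log(1 - r) + 0.5 * r * 100
        assert labf == pytest.approx(expected, rel=1e-12)
        assert labf == pytest.approx(46.88, abs=0.01)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            wakefield_abf(0.1, 0.0, 0.2)
        with pytest.raises(DomainError):
            wakefield_abf(0.1, 0.1, 0.0)


class TestColocABF:
    def _null_tables(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"rs{i}" for i in range(n)]
        d1 = quick_table(ids, rng.normal(0, 0.01, n), np.full(n, 0.05))
        d2 = quick_table(ids, rng.normal(0, 0.01, n), np.full(n, 0.05))
        return d1, d2

    def test_null_region_favors_h0(self):
        res = coloc_abf(*self._null_tables())
        assert np.argmax(res.pp) == 0

    def test_single_snp_shared_signal_is_h4(self):
        """With one SNP, H3 is impossible; strong shared signal gives H4 > 0.99."""
        d1 = quick_table(["rs1"], [0.5], [0.05])
        d2 = quick_table(["rs1"], [0.4], [0.04])
        res = coloc_abf(d1, d2)
        assert res.pp_h3 == 0.0
        assert res.pp_h4 > 0.99

    def test_zero_p12_kills_h4(self):
        d1 = quick_table(["rs1", "rs2"], [0.5, 0.1], [0.05, 0.05])
        d2 = quick_table(["rs1", "rs2"], [0.4, 0.1], [0.04, 0.05])
        priors = ColocPriors.__new__(ColocPriors)  # bypass validation for the limit case
        object.__setattr__(priors, "p1", 1e-4)
        object.__setattr__(priors, "p2", 1e-4)
        object.__setattr__(priors, "p12", 0.0)
        res = coloc_abf(d1, d2, priors)
        assert res.pp_h4 == 0.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(1, 21))
            ids = [f"rs{i}" for i in range(n)]
            d1 = quick_table(ids, rng.normal(0, 0.2, n), rng.uniform(0.02, 0.1, n))
            d2 = quick_table(ids, rng.normal(0, 0.2, n), rng.uniform(0.02, 0.1, n))
            res = coloc_abf(d1, d2)
            l1 = wakefield_abf(d1.frame["beta"].to_numpy(), d1.frame["se"].to_numpy(), 0.15)
            l2 = wakefield_abf(d2.frame["beta"].to_numpy(), d2.frame["se"].to_numpy(), 0.15)
            want = oracle_coloc_enumeration(l1, l2, 1e-5, 1e-5, 1e-7)
            np.testing.assert_allclose(res.pp, want, atol=1e-12)

    def test_posteriors_sum_to_one_and_order_invariant(self):
        d1, d2 = self._null_tables(seed=4)
        res = coloc_abf(d1, d2)
        assert res.pp.sum() == pytest.approx(1.0, abs=1e-10)
        perm = d1.frame.sample(frac=1, random_state=1).reset_index(drop=True)
        from statemr.core_io import SumstatTable
        res2 = coloc_abf(SumstatTable("t", "quantitative", perm), d2)
        np.testing.assert_allclose(res.pp, res2.pp, atol=1e-10)

    def test_h4_monotone_in_p12(self):
        rng = np.random.default_rng(10)
        ids = [f"rs{i}" for i in range(30)]
        betas = rng.normal(0, 0.1, 30)
        d1 = quick_table(ids, betas, np.full(30, 0.04))
        d2 = quick_table(ids, betas * 0.8 + rng.normal(0, 0.02, 30), np.full(30, 0.04))
        last = -1.0
        for p12 in (1e-8, 1e-7, 1e-6, 1e-5):
            pp_h4 = coloc_abf(d1, d2, ColocPriors(1e-5, 1e-5, p12)).pp_h4
            assert pp_h4 >= last
            last = pp_h4


class TestPriorExpectations:
    def test_window_scale_values(self):
        """~1,621 SNPs with p1=p2=1e-5, p12=1e-7: P(H4)~1.6e-4, P(H1)~1.6e-2."""
        pri = prior_expectations(ColocPriors(), 1621)
        assert pri["H4"] == pytest.approx(1621 * 1e-7, rel=0.05)
        assert pri["H1"] == pytest.approx(1621 * 1e-5, rel=0.05)
        assert sum(pri.values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_snp_no_h3(self):
        assert prior_expectations(ColocPriors(), 1)["H3"] == 0.0

    def test_tiny_priors_h0_limit(self):
        pri = prior_expectations(ColocPriors(1e-12, 1e-12, 1e-13), 100)
        assert pri["H0"] > 0.999999


class TestCojoCondition:
    def _identity_panel(self, n=10, seed=3):
        # near-identity LD: zero decay panel at large n
        return simulate_ld_panel(n, 4000, 0.0, (0.2, 0.4), seed=seed)

    def test_identity_ld_leaves_z_unchanged(self):
        ld = self._identity_panel()
        rng = np.random.default_rng(1)
        z = rng.normal(0, 2, ld.n_snps)
        table = table_from_z(ld, z, n=500)
        cond = cojo_condition(table, ld, [ld.snp_ids[0]])
        kept = cond.frame
        orig = dict(zip(table.frame["snp_id"], z))
        for sid, zc in zip(kept["snp_id"], kept["beta"] / kept["se"]):
            assert zc == pytest.approx(orig[sid], abs=0.15)

    def test_conditioning_snp_dropped_as_collinear(self):
        ld = self._identity_panel()
        table = table_from_z(ld, np.ones(ld.n_snps), n=500)
        audit = []
        cond = cojo_condition(table, ld, [ld.snp_ids[0]], audit=audit)
        assert ld.snp_ids[0] not in set(cond.frame["snp_id"])
        assert audit and audit[0]["snp_id"] == ld.snp_ids[0]

    def test_matches_individual_level_joint_ols(self):
        """Summary-space conditioning tracks the full-data joint regression."""
        rng = np.random.default_rng(12)
        worst = 0.0
        for rep in range(8):
            panel = simulate_ld_panel(20, 2000, 0.9, (0.1, 0.5), seed=700 + rep)
            Xc = panel.dosages - panel.dosages.mean(0)
            b = np.zeros(20)
            b[4], b[15] = 0.15, -0.12
            y = Xc @ b + rng.standard_normal(Xc.shape[0])
            betas, ses = marginal_ols_stats(Xc, y)
            table = table_from_z(panel, betas / ses, n=2000)
            table.frame["beta"], table.frame["se"] = betas, ses
            cond = cojo_condition(table, panel, [panel.snp_ids[4]])
            zc = dict(zip(cond.frame["snp_id"], cond.frame["beta"] / cond.frame["se"]))
            for j in range(20):
                sid = panel.snp_ids[j]
                if sid in zc:
                    worst = max(worst, abs(zc[sid] - joint_ols_z(Xc, y, [4], j)))
        assert worst < 0.05

    def test_conditioning_on_causal_nulls_region(self, panel_medium):
        """Single-causal region: conditioning on the causal SNP leaves only noise."""
        rng = np.random.default_rng(13)
        sc = Scenario(architecture="exposure_only", exposure_h2=0.4, n_exp=2000,
                      n_snps=panel_medium.n_snps)
        p95 = []
        for _ in range(20):
            exp, _, truth = simulate_region_sumstats(sc, panel_medium, rng)
            cond = cojo_condition(align_to_reference(exp, panel_medium), panel_medium,
                                  [truth.causal_snp_exposure])
            p95.append(np.quantile(np.abs(cond.frame["beta"] / cond.frame["se"]), 0.95))
        assert np.quantile(p95, 0.95) < 3.0


class TestCojoSelect:
    def test_single_causal_selects_sentinel(self, panel_medium):
        rng = np.random.default_rng(14)
        sc = Scenario(architecture="exposure_only", exposure_h2=0.5, n_exp=2000,
                      n_snps=panel_medium.n_snps)
        hits = 0
        for _ in range(20):
            exp, _, truth = simulate_region_sumstats(sc, panel_medium, rng)
            sel = cojo_select(align_to_reference(exp, panel_medium), panel_medium)
            assert len(sel) >= 1
            if panel_medium.r2(sel[0], truth.causal_snp_exposure) > 0.8:
                hits += 1
        assert hits >= 19

    def test_no_signal_empty_selection(self, panel_small, rng):
        z = rng.normal(0, 1, panel_small.n_snps)
        table = table_from_z(panel_small, z, n=500)
        assert cojo_select(table, panel_small) == []

    def test_two_independent_signals_both_selected(self, panel_medium):
        ids = panel_medium.snp_ids
        i, j = 20, 180  # far apart -> r2 ~ 0 (sampling noise only at n=400)
        assert panel_medium.r2(ids[i], ids[j]) < 0.05
        lam = np.zeros(panel_medium.n_snps)
        lam[i], lam[j] = 12.0, 11.0
        rng = np.random.default_rng(15)
        z = panel_medium.corr @ lam + panel_medium.cholesky() @ rng.standard_normal(len(lam))
        table = table_from_z(panel_medium, z, n=2000)
        sel = cojo_select(table, panel_medium)
        assert len(sel) == 2
        assert panel_medium.r2(sel[0], ids[i]) > 0.8 or panel_medium.r2(sel[0], ids[j]) > 0.8
        # reported in marginal-significance order
        pmap = dict(zip(table.frame["snp_id"], table.frame["pval"]))
        assert pmap[sel[0]] <= pmap[sel[1]]


class TestPwcocoRegion:
    def test_shared_variant_evidence(self, panel_medium):
        rng = np.random.default_rng(16)
        sc = Scenario(architecture="shared_variant", exposure_h2=0.35,
                      n_snps=panel_medium.n_snps)
        flags = []
        for _ in range(20):
            e, o, _ = simulate_region_sumstats(sc, panel_medium, rng)
            rep = pwcoco_region(align_to_reference(e, panel_medium),
                                align_to_reference(o, panel_medium), panel_medium)
            flags.append(rep.evidence)
        assert np.mean(flags) >= 0.9

    def test_distinct_variants_h3(self, panel_medium):
        rng = np.random.default_rng(17)
        sc = Scenario(architecture="distinct_variants", exposure_h2=0.35,
                      n_snps=panel_medium.n_snps)
        h3_modal, flags = [], []
        for _ in range(20):
            e, o, _ = simulate_region_sumstats(sc, panel_medium, rng)
            rep = pwcoco_region(align_to_reference(e, panel_medium),
                                align_to_reference(o, panel_medium), panel_medium)
            h3_modal.append(int(np.argmax(rep.results[0].pp)) == 3)
            flags.append(rep.evidence)
        assert np.mean(h3_modal) >= 0.8
        assert np.mean(flags) <= 0.2

    def test_multi_signal_conditioning_recovers_shared_pair(self, panel_medium):
        """Two shared signals plus a trait-1-only signal: some conditioned
        pair colocalises even where the marginal pair is ambiguous."""
        ids = panel_medium.snp_ids
        s1, s2, s3 = 15, 110, 185
        assert max(panel_medium.r2(ids[s1], ids[s2]),
                   panel_medium.r2(ids[s2], ids[s3]),
                   panel_medium.r2(ids[s1], ids[s3])) < 0.05
        rng = np.random.default_rng(18)
        found = 0
        for _ in range(10):
            lam1 = np.zeros(panel_medium.n_snps)
            lam2 = np.zeros(panel_medium.n_snps)
            lam1[s1], lam1[s2], lam1[s3] = 12.0, 11.0, 10.0  # two shared + one own
            lam2[s1], lam2[s2] = 11.0, 12.0
            L = panel_medium.cholesky()
            z1 = panel_medium.corr @ lam1 + L @ rng.standard_normal(len(lam1))
            z2 = panel_medium.corr @ lam2 + L @ rng.standard_normal(len(lam2))
            d1 = table_from_z(panel_medium, z1, n=5000)
            d2 = table_from_z(panel_medium, z2, n=100000, trait_id="out")
            rep = pwcoco_region(d1, d2, panel_medium)
            conditioned_pairs = [r for r in rep.results if "cond" in r.pair_label]
            if rep.max_h4 > 0.8 and any(r.pp_h4 > 0.8 for r in conditioned_pairs):
                found += 1
        assert found >= 8

    def test_model_interface_matches_function(self, panel_medium):
        rng = np.random.default_rng(19)
        sc = Scenario(architecture="shared_variant", n_snps=panel_medium.n_snps)
        e, o, _ = simulate_region_sumstats(sc, panel_medium, rng)
        d1 = align_to_reference(e, panel_medium)
        d2 = align_to_reference(o, panel_medium)
        a = PairwiseConditionalColoc(d1, d2, panel_medium).fit()
        b = pwcoco_region(d1, d2, panel_medium)
        assert a.max_h4 == pytest.approx(b.max_h4, abs=1e-12)
        assert "max H4" in a.summary()
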