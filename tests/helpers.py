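"""Shared builders and independent oracles for the test suite.

The oracles here are deliberately naive (exhaustive enumeration, explicit
greedy loops, literal step-up definitions, full-data least squares) and stay
independent of the implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from statemr.core_io import LDReference, SumstatTable, make_sumstats, zscore_pvalue


def sumstat_frame(snp_ids, betas, ses, *, chrom="1", positions=None, ea="A", oa="G",
                  eaf=0.3, pvals=None, n=1000, n_case=None, n_control=None):
    """Quick internal-column frame for constructing SumstatTables."""
    m = len(snp_ids)
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    frame = pd.DataFrame({
        "snp_id": snp_ids, "chrom": chrom, "pos": positions,
        "effect_allele": [ea] * m if isinstance(ea, str) else ea,
        "other_allele": [oa] * m if isinstance(oa, str) else oa,
        "eaf": eaf, "beta": betas, "se": ses, "n": n,
    })
    if pvals is not None:
        frame["pval"] = pvals
    if n_case is not None:
        frame["n_case"] = n_case
        frame["n_control"] = n_control
    return frame


def quick_table(snp_ids, betas, ses, trait_id="t", trait_type="quantitative", **kw):
    return make_sumstats(sumstat_frame(snp_ids, betas, ses, **kw), trait_id, trait_type)


def table_from_z(panel: LDReference, z, n, trait_id="t", trait_type="quantitative",
                 n_case=None, n_control=None) -> SumstatTable:
    """Summary statistics on a panel's SNPs with the given z-scores."""
    meta = panel.snp_meta
    f = meta["freq"].to_numpy()
    n_eff = n if trait_type == "quantitative" else 4.0 / (1.0 / n_case + 1.0 / n_control)
    se = 1.0 / np.sqrt(n_eff * 2 * f * (1 - f))
    frame = pd.DataFrame({
        "snp_id": meta["snp_id"], "chrom": meta["chrom"], "pos": meta["pos"],
        "effect_allele": meta["ref_effect_allele"], "other_allele": meta["ref_other_allele"],
        "eaf": f, "beta": np.asarray(z) * se, "se": se, "pval": zscore_pvalue(np.asarray(z)),
        "n": n,
    })
    if trait_type == "binary":
        frame["n_case"], frame["n_control"] = n_case, n_control
        frame["n"] = n_case + n_control
    return make_sumstats(frame, trait_id, trait_type)


# ---------------------------------------------------------------------------
# Oracles


def oracle_coloc_enumeration(labf1, labf2, p1, p2, p12):
    """Posterior over H0..H4 by explicit enumeration of all (n+1)^2 causal
    configuration pairs (None or one causal SNP per trait)."""
    labf1 = np.asarray(labf1)
    labf2 = np.asarray(labf2)
    n = len(labf1)
    logs = {h: [] for h in range(5)}
    logs[0].append(0.0)
    for i in range(n):
        logs[1].append(np.log(p1) + labf1[i])
        logs[2].append(np.log(p2) + labf2[i])
        if p12 > 0:
            logs[4].append(np.log(p12) + labf1[i] + labf2[i])
        for j in range(n):
            if i != j:
                logs[3].append(np.log(p1) + np.log(p2) + labf1[i] + labf2[j])
    lse = np.array([logsumexp(v) if v else -np.inf for v in logs.values()])
    pp = np.exp(lse - logsumexp(lse))
    return pp / pp.sum()


def oracle_greedy_clump(frame: pd.DataFrame, corr: np.ndarray, snp_index: dict,
                        p_thresh: float, r2_thresh: float, window_bp: int) -> list[str]:
    """Literal restatement of the greedy clumping rule with explicit loops."""
    cand = [r for r in frame.itertuples(index=False)
            if r.pval < p_thresh and r.snp_id in snp_index]
    cand.sort(key=lambda r: (r.pval, r.pos))
    selected = []
    while cand:
        index_snp = cand.pop(0)
        selected.append(index_snp.snp_id)
        kept = []
        for r in cand:
            r2 = corr[snp_index[index_snp.snp_id], snp_index[r.snp_id]] ** 2
            near = abs(r.pos - index_snp.pos) < window_bp
            if not (r2 >= r2_thresh or near):
                kept.append(r)
        cand = kept
    return selected


def oracle_bh_stepup(pvals) -> np.ndarray:
    """Literal step-up definition with an explicit double loop (small m only)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def marginal_ols_stats(Xc: np.ndarray, y: np.ndarray):
    """Per-SNP simple-regression betas and SEs on centred genotypes."""
    n, m = Xc.shape
    betas, ses = np.empty(m), np.empty(m)
    for j in range(m):
        xj = Xc[:, j]
        b = xj @ y / (xj @ xj)
        resid = y - xj * b
        ses[j] = np.sqrt(resid @ resid / (n - 2) / (xj @ xj))
        betas[j] = b
    return betas, ses


def joint_ols_z(Xc: np.ndarray, y: np.ndarray, cond_idx: list[int], j: int) -> float:
    """t-statistic of SNP j in the joint model y ~ 1 + X[cond] + X[j]."""
    n = len(y)
    W = np.column_stack([np.ones(n)] + [Xc[:, c] for c in cond_idx] + [Xc[:, j]])
    coef, *_ = np.linalg.lstsq(W, y, rcond=None)
    resid = y - W @ coef
    s2 = resid @ resid / (n - W.shape[1])
    cov = s2 * np.linalg.inv(W.T @ W)
    return float(coef[-1] / np.sqrt(cov[-1, -1]))
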