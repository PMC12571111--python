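"""Bayesian colocalisation with pairwise conditional decomposition.

Per-SNP evidence uses the Wakefield approximate Bayes factor: with V = se^2,
W = prior_sd^2, z = beta/se and r = W/(V+W),

    log ABF = 0.5 * log(1 - r) + 0.5 * r * z^2 .

Hypothesis sums (one causal variant per trait at most) are combined with the
per-SNP priors p1, p2 (trait-specific causality) and p12 (shared causality)
into posteriors over H0..H4. Regions that may hold several independent
signals are decomposed first by stepwise conditional selection from summary
statistics plus an LD reference (conditional/joint analysis in standardized
z-space), and colocalisation is run on every cross-pair of conditioned
datasets; the region-level evidence is the maximum H4 over pairs.

All ABF accumulation is in log space (log-sum-exp); regions with |z| ~ 30
overflow in raw space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core_io import (
    DomainError,
    EmptyOverlapError,
    LDReference,
    SumstatTable,
    zscore_pvalue,
)


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities of trait-specific (p1, p2) and shared (p12)
    causality. Defaults follow the ~1,621-SNP cis-window calibration."""

    p1: float = 1e-5
    p2: float = 1e-5
    p12: float = 1e-7

    def __post_init__(self):
        if not (0 < self.p12 <= min(self.p1, self.p2) < 1):
            raise DomainError("require 0 < p12 <= min(p1, p2) < 1")

    def check_region(self, n_snps: int) -> None:
        if n_snps * (self.p1 + self.p2 + self.p12) >= 1:
            warnings.warn(
                f"n_snps * (p1+p2+p12) = {n_snps * (self.p1 + self.p2 + self.p12):.3g} >= 1; "
                "priors are outside their intended regime", stacklevel=2)


@dataclass
class ColocResult:
    """Posterior probabilities of H0..H4 for one (possibly conditioned) pair."""

    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    n_snps_used: int
    pair_label: str = "marginal|marginal"
    log_sums: dict = field(default_factory=dict)

    @property
    def pp(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4])


@dataclass
class PwcocoConfig:
    p_cut: float = 5e-8
    collinearity_r2: float = 0.9
    prior_sd_quant: float = 0.15  # per-SD expression scale
    prior_sd_cc: float = 0.2  # log-odds scale
    h4_threshold: float = 0.8
    max_signals: int = 10
    ridge: float = 1e-8
    eps: float = 1e-6

    def prior_sd_for(self, table: SumstatTable) -> float:
        return self.prior_sd_cc if table.trait_type == "binary" else self.prior_sd_quant


def wakefield_abf(beta, se, prior_sd: float):
    """Log approximate Bayes factor for a single SNP association."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise DomainError("se must be positive")
    if prior_sd <= 0:
        raise DomainError("prior_sd must be positive")
    V = se ** 2
    W = prior_sd ** 2
    r = W / (V + W)
    z = beta / se
    return 0.5 * np.log1p(-r) + 0.5 * r * z ** 2


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf when the difference underflows."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(d1: SumstatTable, d2: SumstatTable, priors: ColocPriors | None = None,
              prior_sd1: float | None = None, prior_sd2: float | None = None,
              pair_label: str = "marginal|marginal") -> ColocResult:
    """Posterior probabilities of H0..H4 for a pair of datasets in one region.

    The SNP intersection is taken internally; effect-size prior SDs default
    to 0.15 (quantitative) and 0.2 (binary log-odds).
    """
    priors = priors or ColocPriors()
    if prior_sd1 is None:
        prior_sd1 = 0.2 if d1.trait_type == "binary" else 0.15
    if prior_sd2 is None:
        prior_sd2 = 0.2 if d2.trait_type == "binary" else 0.15

    f1 = d1.frame.set_index("snp_id")
    f2 = d2.frame.set_index("snp_id")
    shared = f1.index.intersection(f2.index)
    n = len(shared)
    if n == 0:
        raise EmptyOverlapError("no shared SNPs between the two datasets")
    priors.check_region(n)

    l1 = wakefield_abf(f1.loc[shared, "beta"].to_numpy(), f1.loc[shared, "se"].to_numpy(), prior_sd1)
    l2 = wakefield_abf(f2.loc[shared, "beta"].to_numpy(), f2.loc[shared, "se"].to_numpy(), prior_sd2)

    lS1 = float(logsumexp(l1))
    lS2 = float(logsumexp(l2))
    lS12 = float(logsumexp(l1 + l2))
    lS3 = _logdiffexp(lS1 + lS2, lS12)

    with np.errstate(divide="ignore"):
        log_post = np.array([
            0.0,
            np.log(priors.p1) + lS1,
            np.log(priors.p2) + lS2,
            np.log(priors.p1) + np.log(priors.p2) + lS3,
            (np.log(priors.p12) + lS12) if priors.p12 > 0 else -np.inf,
        ])
    pp = np.exp(log_post - logsumexp(log_post))
    pp /= pp.sum()
    return ColocResult(*pp, n_snps_used=n, pair_label=pair_label,
                       log_sums={"log_S1": lS1, "log_S2": lS2,
                                 "log_S12": lS12, "log_S3": lS3})


def prior_expectations(priors: ColocPriors, n_snps: int) -> dict[str, float]:
    """Exact per-hypothesis prior probabilities for an n-SNP region.

    Enumerates the one-causal-per-trait configurations under independent
    per-SNP states {none, trait1, trait2, both} and normalizes over the five
    hypotheses (the single-causal world in which the posteriors live).
    """
    if n_snps < 1:
        raise DomainError("n_snps must be >= 1")
    p1, p2, p12 = priors.p1, priors.p2, priors.p12
    q0 = 1.0 - p1 - p2 - p12
    if q0 <= 0:
        raise DomainError("per-SNP prior mass exceeds 1")
    n = n_snps
    h0 = q0 ** n
    h1 = n * p1 * q0 ** (n - 1)
    h2 = n * p2 * q0 ** (n - 1)
    h3 = n * (n - 1) * p1 * p2 * q0 ** (n - 2)
    h4 = n * p12 * q0 ** (n - 1)
    total = h0 + h1 + h2 + h3 + h4
    return {"H0": h0 / total, "H1": h1 / total, "H2": h2 / total,
            "H3": h3 / total, "H4": h4 / total}


# ---------------------------------------------------------------------------
# Conditional/joint analysis from summary statistics


def _aligned_arrays(table: SumstatTable, ld: LDReference):
    """Subset the panel to the table's SNPs (table order) and return (ids, z, R, frame)."""
    f = table.frame
    in_ld = f["snp_id"].map(ld.contains)
    f = f[in_ld].reset_index(drop=True)
    if f.empty:
        raise EmptyOverlapError(f"{table.trait_id}: no SNPs shared with the LD reference")
    idx = ld.index_of(f["snp_id"])
    R = ld.corr[np.ix_(idx, idx)]
    z = (f["beta"] / f["se"]).to_numpy()
    return f, z, R


def cojo_condition(table: SumstatTable, ld: LDReference, cond_set,
                   ridge: float = 1e-8, eps: float = 1e-6,
                   audit: list | None = None) -> SumstatTable:
    """Associations of all region SNPs conditioned on ``cond_set``.

    In standardized z-space, with C the conditioning set and R the panel
    correlations,

        z_{j|C} = (z_j - R_jC R_CC^-1 z_C) / sqrt(max(eps, 1 - R_jC R_CC^-1 R_Cj)),

    the conditioned SE is the marginal SE inflated by the same factor, and the
    conditioned p comes from the normal. SNPs collinear with C (including the
    conditioning SNPs themselves) are dropped and recorded in ``audit``.
    Effect signs must already be oriented to the panel's reference alleles.
    """
    cond_set = list(cond_set)
    f, z, R = _aligned_arrays(table, ld)
    if not cond_set:
        return SumstatTable(table.trait_id, table.trait_type, f, table.region)
    id_to_row = {s: i for i, s in enumerate(f["snp_id"])}
    try:
        c_idx = np.array([id_to_row[s] for s in cond_set], dtype=int)
    except KeyError as e:
        raise KeyError(f"conditioning SNP {e.args[0]!r} not in table/LD overlap") from None

    Rcc = R[np.ix_(c_idx, c_idx)] + ridge * np.eye(len(c_idx))
    try:
        Rcc_inv_zc = np.linalg.solve(Rcc, z[c_idx])
        Rcc_inv_A = np.linalg.solve(Rcc, R[c_idx, :])
    except np.linalg.LinAlgError:
        raise DomainError("conditioning correlation submatrix is singular")
    A = R[:, c_idx]  # n x k
    num = z - A @ Rcc_inv_zc
    q = np.einsum("ij,ji->i", A, Rcc_inv_A)
    resid_var = 1.0 - q

    keep = resid_var > eps
    if audit is not None:
        for s in f.loc[~keep, "snp_id"]:
            audit.append({"snp_id": s, "reason": "collinear_with_conditioning_set",
                          "action": "dropped"})
    denom = np.sqrt(np.maximum(resid_var, eps))
    z_c = num / denom
    out = f.copy()
    out["se"] = out["se"] / denom
    out["beta"] = z_c * out["se"]
    out["pval"] = zscore_pvalue(z_c)
    out = out[keep].reset_index(drop=True)
    return SumstatTable(table.trait_id, table.trait_type, out, table.region)


def cojo_select(table: SumstatTable, ld: LDReference, p_cut: float = 5e-8,
                collinearity_r2: float = 0.9, max_signals: int = 10,
                ridge: float = 1e-8, eps: float = 1e-6,
                audit: list | None = None) -> list[str]:
    """Stepwise forward selection of conditionally independent signals.

    Starts from the sentinel (smallest marginal p, ties broken by position),
    then repeatedly adds the SNP with the smallest conditional p below
    ``p_cut`` whose r-squared with every selected SNP stays below
    ``collinearity_r2``. Deterministic.
    """
    f, z, _ = _aligned_arrays(table, ld)
    if f.empty:
        return []
    cand = f.sort_values(["pval", "pos"], kind="mergesort")
    if cand["pval"].iloc[0] >= p_cut:
        return []
    selected = [str(cand["snp_id"].iloc[0])]

    while len(selected) < max_signals:
        cond = cojo_condition(table, ld, selected, ridge, eps, audit)
        cf = cond.frame
        cf = cf[~cf["snp_id"].isin(selected)]
        if cf.empty:
            break
        ok = np.ones(len(cf), dtype=bool)
        for s in selected:
            i = ld.index_of([s])[0]
            r2 = ld.corr[i, ld.index_of(cf["snp_id"])] ** 2
            ok &= r2 < collinearity_r2
        cf = cf[ok]
        if cf.empty:
            break
        cf = cf.sort_values(["pval", "pos"], kind="mergesort")
        if cf["pval"].iloc[0] >= p_cut:
            break
        selected.append(str(cf["snp_id"].iloc[0]))
    # report in marginal-significance order
    marg_p = {s: p for s, p in zip(f["snp_id"], f["pval"])}
    selected.sort(key=lambda s: (marg_p[s],))
    return selected


# ---------------------------------------------------------------------------
# Region-level pairwise conditional colocalisation


@dataclass
class RegionColocReport:
    """All conditioned-pair colocalisations for one region, with the
    region-level evidence (max H4 over pairs)."""

    results: list[ColocResult]
    selected_1: list[str]
    selected_2: list[str]
    h4_threshold: float

    @property
    def max_h4(self) -> float:
        return max(r.pp_h4 for r in self.results)

    @property
    def evidence(self) -> bool:
        """The binary colocalisation evidence flag, max H4 > threshold."""
        return self.max_h4 > self.h4_threshold

    @property
    def best_pair(self) -> ColocResult:
        return max(self.results, key=lambda r: r.pp_h4)

    def frame(self) -> pd.DataFrame:
        rows = [{"pair_label": r.pair_label, "n_snps": r.n_snps_used,
                 "pp_h0": r.pp_h0, "pp_h1": r.pp_h1, "pp_h2": r.pp_h2,
                 "pp_h3": r.pp_h3, "pp_h4": r.pp_h4} for r in self.results]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Pairwise conditional colocalisation",
            "===================================",
            f"signals: trait1 {self.selected_1 or ['(marginal only)']}, "
            f"trait2 {self.selected_2 or ['(marginal only)']}",
            f"max H4 = {self.max_h4:.4f}  "
            f"(evidence {'YES' if self.evidence else 'no'} at > {self.h4_threshold})",
            "",
            self.frame().to_string(index=False, float_format=lambda x: f"{x:.4f}"),
        ]
        return "\n".join(lines)


def _conditioned_datasets(table: SumstatTable, ld: LDReference, selected: list[str],
                          cfg: PwcocoConfig, audit: list | None):
    """Marginal dataset plus, for k >= 2 signals, each signal's dataset
    conditioned on the other selected signals."""
    datasets = [("marginal", table)]
    if len(selected) >= 2:
        for s in selected:
            others = [t for t in selected if t != s]
            cond = cojo_condition(table, ld, others, cfg.ridge, cfg.eps, audit)
            datasets.append((f"cond({s}|{'+'.join(others)})", cond))
    return datasets


def pwcoco_region(d1: SumstatTable, d2: SumstatTable, ld: LDReference,
                  priors: ColocPriors | None = None,
                  config: PwcocoConfig | None = None) -> RegionColocReport:
    """Pairwise conditional colocalisation of two traits in one region.

    Both tables must be oriented to the panel's reference alleles (see
    :func:`statemr.core_io.align_to_reference`).
    """
    priors = priors or ColocPriors()
    cfg = config or PwcocoConfig()
    audit: list = []
    sel1 = cojo_select(d1, ld, cfg.p_cut, cfg.collinearity_r2, cfg.max_signals,
                       cfg.ridge, cfg.eps, audit)
    sel2 = cojo_select(d2, ld, cfg.p_cut, cfg.collinearity_r2, cfg.max_signals,
                       cfg.ridge, cfg.eps, audit)
    sets1 = _conditioned_datasets(d1, ld, sel1, cfg, audit)
    sets2 = _conditioned_datasets(d2, ld, sel2, cfg, audit)
    results = []
    for lab1, t1 in sets1:
        for lab2, t2 in sets2:
            res = coloc_abf(t1, t2, priors,
                            prior_sd1=cfg.prior_sd_for(d1),
                            prior_sd2=cfg.prior_sd_for(d2),
                            pair_label=f"{lab1}|{lab2}")
            results.append(res)
    return RegionColocReport(results, sel1, sel2, cfg.h4_threshold)


class PairwiseConditionalColoc:
    """Model-style interface: configure on construction, ``fit()`` to run."""

    def __init__(self, d1: SumstatTable, d2: SumstatTable, ld: LDReference,
                 priors: ColocPriors | None = None, config: PwcocoConfig | None = None):
        self.d1, self.d2, self.ld = d1, d2, ld
        self.priors = priors or ColocPriors()
        self.config = config or PwcocoConfig()

    def fit(self) -> RegionColocReport:
        return pwcoco_region(self.d1, self.d2, self.ld, self.priors, self.config)
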