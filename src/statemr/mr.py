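"""Wald-ratio Mendelian randomization with delta-method standard errors.

For a single instrument with exposure effect beta_x (per SD of expression)
and outcome effect beta_y (log-odds), the causal estimate is the Wald ratio

    beta_MR = beta_y / beta_x

with either the first-order SE, se_y / |beta_x|, or the second-order delta
approximation sqrt(se_y^2/beta_x^2 + beta_y^2 se_x^2 / beta_x^4). Estimates
are reported as odds ratios per SD higher expression with 95% CIs, and the
transcriptome-wide scan applies Benjamini-Hochberg FDR within each outcome
stratum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import DomainError, zscore_pvalue

Z_95 = 1.959964  # two-sided 95% normal quantile

SE_METHODS = ("first_order", "delta_second_order")


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float,
               method: str = "delta_second_order") -> tuple[float, float]:
    """Wald-ratio estimate and its delta-method standard error."""
    if beta_exp == 0:
        raise DomainError("Wald ratio undefined for beta_exp = 0")
    if method not in SE_METHODS:
        raise DomainError(f"unknown SE method {method!r}")
    beta_mr = beta_out / beta_exp
    if method == "first_order":
        se_mr = se_out / abs(beta_exp)
    else:
        se_mr = np.sqrt(se_out ** 2 / beta_exp ** 2
                        + beta_out ** 2 * se_exp ** 2 / beta_exp ** 4)
    return float(beta_mr), float(se_mr)


def to_or_ci(beta_mr: float, se_mr: float) -> tuple[float, float, float, float]:
    """Odds ratio, 95% CI and two-sided normal p for a log-odds estimate."""
    if se_mr <= 0:
        raise DomainError("se_mr must be positive")
    or_ = np.exp(beta_mr)
    lo = np.exp(beta_mr - Z_95 * se_mr)
    hi = np.exp(beta_mr + Z_95 * se_mr)
    p = float(zscore_pvalue(beta_mr / se_mr))
    return float(or_), float(lo), float(hi), p


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q(i) = min_{j >= i} p(j) * m / j over the ascending-sorted p's, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise DomainError("pvals must be a non-empty 1-d sequence")
    if np.any(~(p > 0) | (p > 1)):
        raise DomainError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


REQUIRED_SCAN_COLUMNS = ("gene_id", "cell_state", "outcome_id", "snp_id",
                         "beta_exp", "se_exp", "beta_out", "se_out")


class WaldRatioScan:
    """Transcriptome-wide per-instrument Wald-ratio scan.

    Parameters
    ----------
    instruments : DataFrame
        One row per (gene, cell_state, outcome, instrument SNP) with
        harmonized effects: columns ``gene_id, cell_state, outcome_id,
        snp_id, beta_exp, se_exp, beta_out, se_out``.
    se_method : {"delta_second_order", "first_order"}
        Delta-method order for the ratio SE.
    fdr_alpha : float
        BH threshold used to flag discoveries.
    fdr_universe : {"per_outcome", "joint"}
        Whether BH is applied within each outcome stratum (default,
        matching per-outcome reporting) or across all strata jointly.
    """

    def __init__(self, instruments: pd.DataFrame, se_method: str = "delta_second_order",
                 fdr_alpha: float = 0.05, fdr_universe: str = "per_outcome"):
        missing = [c for c in REQUIRED_SCAN_COLUMNS if c not in instruments.columns]
        if missing:
            raise DomainError(f"instrument frame missing columns: {missing}")
        if fdr_universe not in ("per_outcome", "joint"):
            raise DomainError(f"unknown fdr_universe {fdr_universe!r}")
        self.instruments = instruments.reset_index(drop=True)
        self.se_method = se_method
        self.fdr_alpha = fdr_alpha
        self.fdr_universe = fdr_universe

    def fit(self) -> "MRScanResults":
        rows = []
        for rec in self.instruments.itertuples(index=False):
            beta_mr, se_mr = wald_ratio(rec.beta_exp, rec.se_exp,
                                        rec.beta_out, rec.se_out, self.se_method)
            or_, lo, hi, p = to_or_ci(beta_mr, se_mr)
            rows.append({
                "gene_id": rec.gene_id, "cell_state": rec.cell_state,
                "outcome_id": rec.outcome_id, "snp_id": rec.snp_id,
                "beta_mr": beta_mr, "se_mr": se_mr, "pval": p,
                "or_": or_, "ci_low": lo, "ci_high": hi,
            })
        frame = pd.DataFrame(rows)
        if frame.empty:
            frame = pd.DataFrame(columns=["gene_id", "cell_state", "outcome_id", "snp_id",
                                          "beta_mr", "se_mr", "pval", "or_", "ci_low",
                                          "ci_high", "fdr_p", "fdr_flag", "multi_instrument"])
            return MRScanResults(self, frame)
        if self.fdr_universe == "per_outcome":
            frame["fdr_p"] = np.nan
            for _, idx in frame.groupby("outcome_id").groups.items():
                frame.loc[idx, "fdr_p"] = bh_adjust(frame.loc[idx, "pval"].to_numpy())
        else:
            frame["fdr_p"] = bh_adjust(frame["pval"].to_numpy())
        frame["fdr_flag"] = frame["fdr_p"] < self.fdr_alpha
        sizes = frame.groupby(["gene_id", "cell_state", "outcome_id"])["snp_id"].transform("size")
        frame["multi_instrument"] = sizes > 1
        return MRScanResults(self, frame)


class MRScanResults:
    """Results of a :class:`WaldRatioScan` fit."""

    def __init__(self, model: WaldRatioScan, frame: pd.DataFrame):
        self.model = model
        self.frame = frame

    @property
    def n_tests(self) -> int:
        return len(self.frame)

    @property
    def flagged(self) -> pd.DataFrame:
        """Rows passing the FDR threshold."""
        return self.frame[self.frame["fdr_flag"]].reset_index(drop=True)

    @property
    def flagged_genes(self) -> list[str]:
        return sorted(self.flagged["gene_id"].unique())

    def summary(self, top: int = 10) -> str:
        f = self.frame
        lines = [
            "Wald-ratio MR scan",
            "==================",
            f"tests: {self.n_tests}   SE method: {self.model.se_method}   "
            f"FDR: BH {self.model.fdr_universe} @ {self.model.fdr_alpha}",
            f"FDR-significant rows: {int(f['fdr_flag'].sum())} "
            f"({len(self.flagged_genes)} genes)",
            "",
        ]
        if not f.empty:
            show = f.sort_values("pval").head(top)
            with pd.option_context("display.width", 120):
                lines.append(show[["gene_id", "cell_state", "outcome_id", "snp_id",
                                   "or_", "ci_low", "ci_high", "pval", "fdr_p"]]
                             .to_string(index=False,
                                        float_format=lambda x: f"{x:.3g}"))
        return "\n".join(lines)


def mr_scan(instruments: pd.DataFrame, se_method: str = "delta_second_order",
            fdr_alpha: float = 0.05, fdr_universe: str = "per_outcome") -> pd.DataFrame:
    """Functional wrapper around :class:`WaldRatioScan`; returns the results frame."""
    return WaldRatioScan(instruments, se_method, fdr_alpha, fdr_universe).fit().frame
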