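"""Selection and filtering of cis-eQTL instruments per gene x cell state.

The chain is: cis window (+-500 kb of the gene body) -> genome-wide
significance and LD clumping -> allele harmonization against the outcome ->
instrument-strength (F >= 10) filter -> Steiger directionality filter.
Each step's exclusions are counted in an audit dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (
    DomainError,
    GeneRecord,
    GenomicInterval,
    LDReference,
    SumstatTable,
    effective_n,
    harmonize,
    kept_pairs,
    sample_size_for,
)


@dataclass
class InstrumentConfig:
    p_instr: float = 5e-8
    r2_clump: float = 0.001
    clump_window: int = 10_000
    f_min: float = 10.0
    cis_flank: int = 500_000
    palindromic_maf_cut: float = 0.42


@dataclass
class Instrument:
    """A clumped, filtered cis-eQTL SNP with its harmonized outcome effect."""

    snp_id: str
    gene_id: str
    cell_state: str
    beta_exp: float
    se_exp: float
    eaf: float
    beta_out: float
    se_out: float
    F: float
    r2_exp: float
    r2_out: float
    steiger_kept: bool


def cis_window(gene: GeneRecord, flank: int = 500_000) -> GenomicInterval:
    """The +-flank cis region around the gene body, clamped at the chromosome start."""
    return GenomicInterval(gene.chrom, max(0, gene.start - flank), gene.end + flank)


def ld_clump(table: SumstatTable, ld: LDReference, p_thresh: float = 5e-8,
             r2_thresh: float = 0.001, window_bp: int = 10_000,
             audit: dict | None = None) -> list[str]:
    """Greedy p-value-ranked LD clumping; returns index SNPs in selection order.

    A remaining SNP is discarded against an index SNP when its r-squared with
    the index reaches ``r2_thresh`` OR it lies within ``window_bp`` of it.
    Ties on p are broken by smaller genomic position. SNPs absent from the
    LD panel are dropped first (counted in ``audit``).
    """
    f = table.frame
    in_ld = f["snp_id"].map(ld.contains)
    if audit is not None:
        audit["clump_missing_from_ld"] = int((~in_ld).sum())
    f = f[in_ld]
    cand = f[f["pval"] < p_thresh]
    if cand.empty:
        return []
    cand = cand.sort_values(["pval", "pos"], kind="mergesort")
    ids = cand["snp_id"].to_numpy()
    pos = cand["pos"].to_numpy()
    idx = ld.index_of(ids)
    alive = np.ones(len(cand), dtype=bool)
    selected: list[str] = []
    for i in range(len(cand)):
        if not alive[i]:
            continue
        selected.append(str(ids[i]))
        r2 = ld.corr[idx[i], idx] ** 2
        near = np.abs(pos - pos[i]) < window_bp
        alive &= ~((r2 >= r2_thresh) | near)
    return selected


def f_statistic(beta_exp: float, se_exp: float) -> float:
    """Single-instrument approximation F = (beta/se)^2."""
    if se_exp <= 0:
        raise DomainError("se_exp must be positive")
    return (beta_exp / se_exp) ** 2


def variance_explained(beta: float, se: float, n: float, trait_type: str = "quantitative",
                       n_case: float | None = None, n_control: float | None = None) -> float:
    """Variance explained r^2 = z^2 / (z^2 + n* - 2).

    ``n*`` is the sample size for quantitative traits and the case-control
    effective sample size for binary traits.
    """
    if se <= 0:
        raise DomainError("se must be positive")
    if trait_type == "binary":
        if n_case is None or n_control is None:
            raise DomainError("binary trait requires n_case and n_control")
        n_star = effective_n(n_case, n_control)
    else:
        n_star = n
    if n_star < 3:
        raise DomainError("need n >= 3")
    z2 = (beta / se) ** 2
    return z2 / (z2 + n_star - 2.0)


def steiger_filter(pairs: pd.DataFrame, n_exp: float, outcome_meta: dict) -> pd.DataFrame:
    """Directionality filter: keep pairs explaining strictly more variance in
    the exposure than in the outcome (guards against reverse causation).

    ``outcome_meta`` needs ``trait_type`` and either ``n`` or
    ``n_case``/``n_control``. Adds ``r2_exp``, ``r2_out`` and
    ``steiger_kept`` columns; the returned frame contains all input rows.
    """
    out = pairs.copy()
    r2e, r2o = [], []
    for row in out.itertuples(index=False):
        r2e.append(variance_explained(row.beta_exp, row.se_exp, n_exp, "quantitative"))
        r2o.append(variance_explained(
            row.beta_out, row.se_out, outcome_meta.get("n", np.nan),
            outcome_meta["trait_type"], outcome_meta.get("n_case"),
            outcome_meta.get("n_control")))
    out["r2_exp"] = r2e
    out["r2_out"] = r2o
    out["steiger_kept"] = out["r2_exp"] > out["r2_out"]  # strict: ties dropped
    return out


def build_instruments(gene: GeneRecord, exposure: SumstatTable, outcome: SumstatTable,
                      ld: LDReference, config: InstrumentConfig | None = None,
                      ) -> tuple[list[Instrument], dict]:
    """Full instrument-selection chain for one gene x cell state x outcome.

    Returns the retained instruments and an audit dict of per-step counts.
    An empty result is a valid outcome.
    """
    cfg = config or InstrumentConfig()
    audit: dict = {"n_region": len(exposure)}
    window = cis_window(gene, cfg.cis_flank)
    cis = exposure.restrict(window)
    audit["n_cis"] = len(cis)
    if len(cis) == 0:
        return [], audit

    selected = ld_clump(cis, ld, cfg.p_instr, cfg.r2_clump, cfg.clump_window, audit)
    audit["n_clumped"] = len(selected)
    if not selected:
        return [], audit

    try:
        pairs = harmonize(cis.subset(selected), outcome, cfg.palindromic_maf_cut)
    except Exception:
        audit["n_harmonized"] = 0
        return [], audit
    pairs = kept_pairs(pairs)
    audit["n_harmonized"] = len(pairs)
    if pairs.empty:
        return [], audit

    pairs = pairs.assign(F=[f_statistic(b, s) for b, s in zip(pairs["beta_exp"], pairs["se_exp"])])
    pairs = pairs[pairs["F"] >= cfg.f_min]
    audit["n_f_pass"] = len(pairs)
    if pairs.empty:
        return [], audit

    out_meta = {"trait_type": outcome.trait_type, "n": sample_size_for(outcome)}
    if outcome.trait_type == "binary":
        out_meta["n_case"] = float(outcome.frame["n_case"].iloc[0])
        out_meta["n_control"] = float(outcome.frame["n_control"].iloc[0])
    n_exp = sample_size_for(exposure)
    pairs = steiger_filter(pairs, n_exp, out_meta)
    kept = pairs[pairs["steiger_kept"]]
    audit["n_steiger_pass"] = len(kept)

    cell_state = gene.cell_state or ""
    instruments = [
        Instrument(
            snp_id=row.snp_id, gene_id=gene.gene_id, cell_state=cell_state,
            beta_exp=row.beta_exp, se_exp=row.se_exp, eaf=row.eaf_exp,
            beta_out=row.beta_out, se_out=row.se_out, F=row.F,
            r2_exp=row.r2_exp, r2_out=row.r2_out, steiger_kept=True)
        for row in kept.itertuples(index=False)
    ]
    return instruments, audit


def instruments_frame(instruments: list[Instrument]) -> pd.DataFrame:
    cols = ["gene_id", "cell_state", "snp_id", "beta_exp", "se_exp", "eaf",
            "beta_out", "se_out", "F", "r2_exp", "r2_out", "steiger_kept"]
    rows = [{c: getattr(i, c) for c in cols} for i in instruments]
    return pd.DataFrame(rows, columns=cols)
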