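"""Cross-tissue specificity lookup for prioritized genes.

For each prioritized gene's lead instrument, test whether the same variant
(or, when the lead is missing from the tissue resource, its best LD proxy
with r^2 >= 0.8) is associated with that gene's expression across a
multi-tissue eQTL table at genome-wide significance (P < 5e-8). Designated
local tissues (by default the two colon labels) are reported as named flags
alongside the overall proportion of significant tissues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import LDReference


@dataclass
class TissueConfig:
    p_thresh: float = 5e-8
    proxy_r2_min: float = 0.8
    local_tissues: tuple[str, ...] = ("Colon_Sigmoid", "Colon_Transverse")
    strict_missing: bool = False  # exclude missing (gene,tissue) pairs from the denominator


@dataclass
class TissueOverlap:
    """Per-gene cross-tissue lookup result."""

    gene_id: str
    lead_snp: str
    proxy_snp: str | None
    proxy_r2: float | None
    per_tissue: dict[str, bool]
    local_flags: dict[str, bool]
    proportion: float | None  # fraction of tissues significant, None when not_available
    status: str  # "evaluated" | "not_available"
    missing_tissues: list[str] = field(default_factory=list)


def best_proxy(lead_snp: str, ld: LDReference, available_snps,
               r2_min: float = 0.8) -> tuple[str, float] | None:
    """The lead SNP itself when available, else the available SNP in highest
    LD with it (requiring r^2 >= ``r2_min``), else None."""
    if not ld.contains(lead_snp):
        raise KeyError(f"lead SNP {lead_snp!r} absent from LD reference")
    available = [s for s in set(available_snps) if ld.contains(s)]
    if lead_snp in available:
        return lead_snp, 1.0
    if not available:
        return None
    i = ld.index_of([lead_snp])[0]
    idx = ld.index_of(available)
    r2 = ld.corr[i, idx] ** 2
    best = int(np.argmax(r2))
    if r2[best] >= r2_min:
        return available[best], float(r2[best])
    return None


def tissue_lookup(snp_id: str, gene_id: str, tissue_table: pd.DataFrame,
                  p_thresh: float = 5e-8) -> tuple[dict[str, bool], list[str]]:
    """Per-tissue genome-wide-significance flags for one (gene, SNP).

    Missing (gene, tissue, snp) entries flag False and are returned in the
    missingness list. Tissues are taken from the whole table so every gene is
    scored against the same tissue set.
    """
    tissues = list(pd.unique(tissue_table["tissue"]))
    sub = tissue_table[(tissue_table["gene_id"] == gene_id)
                       & (tissue_table["snp_id"] == snp_id)]
    pmap = dict(zip(sub["tissue"], sub["pval"]))
    flags = {}
    missing = []
    for t in tissues:
        if t in pmap:
            flags[t] = bool(pmap[t] < p_thresh)
        else:
            flags[t] = False
            missing.append(t)
    return flags, missing


def evaluate_gene(gene_id: str, lead_snp: str, ld: LDReference,
                  tissue_table: pd.DataFrame, config: TissueConfig | None = None,
                  ) -> TissueOverlap:
    cfg = config or TissueConfig()
    gene_snps = tissue_table.loc[tissue_table["gene_id"] == gene_id, "snp_id"]
    proxy = best_proxy(lead_snp, ld, gene_snps.unique(), cfg.proxy_r2_min)
    if proxy is None:
        return TissueOverlap(gene_id, lead_snp, None, None, {}, {}, None, "not_available")
    snp, r2 = proxy
    flags, missing = tissue_lookup(snp, gene_id, tissue_table, cfg.p_thresh)
    local = {t: flags.get(t, False) for t in cfg.local_tissues}
    if cfg.strict_missing:
        counted = {t: v for t, v in flags.items() if t not in missing}
    else:
        counted = flags
    proportion = float(np.mean(list(counted.values()))) if counted else None
    return TissueOverlap(gene_id, lead_snp, snp, r2, flags, local, proportion,
                         "evaluated", missing)


def overlap_summary(leads: pd.DataFrame, ld_map: dict[str, LDReference],
                    tissue_table: pd.DataFrame,
                    config: TissueConfig | None = None) -> pd.DataFrame:
    """One row per prioritized gene, mirroring the lead/proxy/local-tissue/
    all-tissues-percentage report shape.

    ``leads`` needs columns gene_id, snp_id (the lead instrument per gene).
    """
    cfg = config or TissueConfig()
    rows = []
    for rec in leads.itertuples(index=False):
        ov = evaluate_gene(rec.gene_id, rec.snp_id, ld_map[rec.gene_id],
                           tissue_table, cfg)
        row = {
            "gene_id": ov.gene_id,
            "lead_snp": ov.lead_snp,
            "proxy_snp": ov.proxy_snp if ov.proxy_snp not in (None, ov.lead_snp) else "-",
            "proxy_r2": (round(ov.proxy_r2, 3)
                         if ov.proxy_snp not in (None, ov.lead_snp) else np.nan),
            "status": ov.status,
        }
        for t in cfg.local_tissues:
            row[t] = ("NA" if ov.status == "not_available"
                      else ("Y" if ov.local_flags.get(t, False) else "N"))
        row["all_tissues_pct"] = (np.nan if ov.proportion is None
                                  else round(100.0 * ov.proportion, 1))
        if ov.status == "not_available":
            row["proxy_snp"] = "NA"
        rows.append(row)
    cols = (["gene_id", "lead_snp", "proxy_snp", "proxy_r2", "status"]
            + list(cfg.local_tissues) + ["all_tissues_pct"])
    return pd.DataFrame(rows, columns=cols)
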