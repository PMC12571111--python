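"""End-to-end orchestration: instruments -> MR scan -> conditional
colocalisation (on FDR hits) -> cross-tissue lookup (on prioritized genes).

A gene x cell-state x outcome tuple is *prioritized* exactly when it passes
the MR FDR threshold (BH < 0.05) and its region shows colocalisation
evidence (max H4 > 0.8). Every run header records the clumping rule, FDR
universe, SE method and priors, because these are the analysis's
under-specified choices.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core_io import align_to_reference
from .instruments import InstrumentConfig, build_instruments, instruments_frame
from .mr import WaldRatioScan
from .pwcoco import ColocPriors, PwcocoConfig, pwcoco_region
from .synthetic import StudyBundle, load_study
from .tissue import TissueConfig, overlap_summary

STAGE_FILES = {
    "instruments": "instruments.tsv",
    "instrument_audit": "instrument_audit.tsv",
    "mr": "mr_results.tsv",
    "coloc": "coloc_results.tsv",
    "prioritized": "prioritized.tsv",
    "tissue": "tissue_overlap.tsv",
}


@dataclass
class PipelineConfig:
    """All analysis thresholds, with the study's published defaults."""

    p_instr: float = 5e-8
    r2_clump: float = 0.001
    clump_window: int = 10_000
    f_min: float = 10.0
    fdr: float = 0.05
    h4: float = 0.8
    proxy_r2: float = 0.8
    tissue_p: float = 5e-8
    cis_flank: int = 500_000
    palindromic_maf_cut: float = 0.42
    se_method: str = "delta_second_order"
    fdr_universe: str = "per_outcome"
    prior_p1: float = 1e-5
    prior_p2: float = 1e-5
    prior_p12: float = 1e-7
    prior_sd_quant: float = 0.15
    prior_sd_cc: float = 0.2
    cojo_p_cut: float = 5e-8
    cojo_collinearity_r2: float = 0.9
    coloc_exhaustive: bool = False  # run coloc on all tuples, not just FDR hits
    local_tissues: tuple[str, ...] = ("Colon_Sigmoid", "Colon_Transverse")
    tissue_strict_missing: bool = False
    seed: int = 0

    def instrument_config(self) -> InstrumentConfig:
        return InstrumentConfig(self.p_instr, self.r2_clump, self.clump_window,
                                self.f_min, self.cis_flank, self.palindromic_maf_cut)

    def priors(self) -> ColocPriors:
        return ColocPriors(self.prior_p1, self.prior_p2, self.prior_p12)

    def pwcoco_config(self) -> PwcocoConfig:
        return PwcocoConfig(p_cut=self.cojo_p_cut,
                            collinearity_r2=self.cojo_collinearity_r2,
                            prior_sd_quant=self.prior_sd_quant,
                            prior_sd_cc=self.prior_sd_cc,
                            h4_threshold=self.h4)

    def tissue_config(self) -> TissueConfig:
        return TissueConfig(self.tissue_p, self.proxy_r2,
                            tuple(self.local_tissues), self.tissue_strict_missing)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["local_tissues"] = list(self.local_tissues)
        return d

    @classmethod
    def from_dict(cls, d) -> "PipelineConfig":
        d = dict(d)
        if "local_tissues" in d:
            d["local_tissues"] = tuple(d["local_tissues"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def header_lines(self) -> list[str]:
        return [
            f"statemr {__version__}  config {self.hash()}",
            f"clumping rule: discard candidates with r2 >= {self.r2_clump} against an "
            f"index SNP OR within {self.clump_window} bp of it; index order by ascending p "
            f"(ties: smaller position); candidate threshold p < {self.p_instr}",
            f"instrument filters: F >= {self.f_min}; Steiger strict r2_exp > r2_out",
            f"MR: Wald ratio, SE method {self.se_method}; "
            f"FDR universe {self.fdr_universe}, BH alpha {self.fdr}",
            f"coloc priors: p1={self.prior_p1} p2={self.prior_p2} p12={self.prior_p12}; "
            f"prior SDs {self.prior_sd_quant} (quant) / {self.prior_sd_cc} (binary); "
            f"evidence at max H4 > {self.h4}",
        ]


@dataclass
class StudyReport:
    """Per-stage counts, result tables and run metadata for one pipeline run."""

    counts: dict
    frames: dict[str, pd.DataFrame]
    config: PipelineConfig
    metadata: dict = field(default_factory=dict)

    @property
    def prioritized_genes(self) -> list[str]:
        f = self.frames["prioritized"]
        return sorted(f["gene_id"].unique()) if len(f) else []

    def summary(self) -> str:
        lines = ["Pipeline report", "===============", *self.config.header_lines(), ""]
        for k, v in self.counts.items():
            lines.append(f"{k}: {v}")
        if self.prioritized_genes:
            lines.append("prioritized genes: " + ", ".join(self.prioritized_genes))
        return "\n".join(lines)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key, fname in STAGE_FILES.items():
            if key in self.frames:
                self.frames[key].to_csv(out / fname, sep="\t", index=False, na_rep="NA")
        meta = {"counts": self.counts, "config": self.config.to_dict(),
                "metadata": self.metadata}
        with open(out / "report.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        with open(out / "run.log", "w") as fh:
            fh.write(self.summary() + "\n")


# ---------------------------------------------------------------------------
# Stages


def _split_state(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    parts = out["cell_state"].str.rsplit("_", n=1, expand=True)
    out.insert(out.columns.get_loc("cell_state") + 1, "cell_subtype", parts[0])
    out.insert(out.columns.get_loc("cell_state") + 2, "activation_timepoint", parts[1])
    return out


def stage_instruments(bundle: StudyBundle, config: PipelineConfig,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Instrument selection for every gene x cell state x outcome stratum."""
    icfg = config.instrument_config()
    gene_by_id = {g.gene_id: g for g in bundle.genes}
    instr_rows, audit_rows = [], []
    for rec in bundle.profiles.itertuples(index=False):
        gene = gene_by_id[rec.gene_id].with_cell_state(rec.cell_state)
        exposure = bundle.exposures[(rec.gene_id, rec.cell_state)]
        ld = bundle.ld[rec.gene_id]
        for stratum in bundle.outcome_strata:
            outcome = bundle.outcomes[(stratum, rec.gene_id)]
            if len(outcome) == 0:
                continue
            instrs, audit = build_instruments(gene, exposure, outcome, ld, icfg)
            frame = instruments_frame(instrs)
            frame.insert(2, "outcome_id", stratum)
            instr_rows.append(frame)
            audit_rows.append({"gene_id": rec.gene_id, "cell_state": rec.cell_state,
                               "outcome_id": stratum, **audit})
    instr_rows = [f for f in instr_rows if len(f)]
    if instr_rows:
        instr = pd.concat(instr_rows, ignore_index=True)
    else:
        instr = instruments_frame([])
        instr.insert(2, "outcome_id", pd.Series(dtype=str))
    return instr, pd.DataFrame(audit_rows)


def stage_mr(instr: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    if instr.empty:
        instr = pd.DataFrame(columns=["gene_id", "cell_state", "outcome_id", "snp_id",
                                      "beta_exp", "se_exp", "beta_out", "se_out"])
    return WaldRatioScan(instr, config.se_method, config.fdr,
                         config.fdr_universe).fit().frame


def stage_coloc(bundle: StudyBundle, mr_frame: pd.DataFrame, config: PipelineConfig,
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Conditional colocalisation for FDR-passing tuples (or all, in
    exhaustive mode). Returns (pair-level frame, prioritized frame)."""
    priors = config.priors()
    pcfg = config.pwcoco_config()
    gene_by_id = {g.gene_id: g for g in bundle.genes}
    if mr_frame.empty:
        hits = mr_frame
    elif config.coloc_exhaustive:
        hits = mr_frame
    else:
        hits = mr_frame[mr_frame["fdr_flag"]]
    tuples = (hits[["gene_id", "cell_state", "outcome_id"]].drop_duplicates()
              .itertuples(index=False))
    pair_rows = []
    region_rows = []
    from .instruments import cis_window
    for tup in tuples:
        gene = gene_by_id[tup.gene_id]
        ld = bundle.ld[tup.gene_id]
        window = cis_window(gene, config.cis_flank)
        d1 = align_to_reference(
            bundle.exposures[(tup.gene_id, tup.cell_state)].restrict(window), ld)
        d2 = align_to_reference(
            bundle.outcomes[(tup.outcome_id, tup.gene_id)].restrict(window), ld)
        report = pwcoco_region(d1, d2, ld, priors, pcfg)
        for r in report.results:
            pair_rows.append({
                "gene_id": tup.gene_id, "cell_state": tup.cell_state,
                "outcome_id": tup.outcome_id, "pair_label": r.pair_label,
                "n_snps": r.n_snps_used, "pp_h0": r.pp_h0, "pp_h1": r.pp_h1,
                "pp_h2": r.pp_h2, "pp_h3": r.pp_h3, "pp_h4": r.pp_h4,
            })
        region_rows.append({
            "gene_id": tup.gene_id, "cell_state": tup.cell_state,
            "outcome_id": tup.outcome_id, "max_h4": report.max_h4,
            "coloc_evidence": report.evidence,
        })
    pair_cols = ["gene_id", "cell_state", "outcome_id", "pair_label", "n_snps",
                 "pp_h0", "pp_h1", "pp_h2", "pp_h3", "pp_h4"]
    coloc = pd.DataFrame(pair_rows, columns=pair_cols)
    regions = pd.DataFrame(region_rows, columns=["gene_id", "cell_state", "outcome_id",
                                                 "max_h4", "coloc_evidence"])
    if regions.empty or mr_frame.empty:
        prioritized = pd.DataFrame(columns=["gene_id", "cell_state", "outcome_id",
                                            "snp_id", "beta_mr", "or_", "ci_low",
                                            "ci_high", "pval", "fdr_p", "max_h4"])
        return coloc, prioritized
    merged = mr_frame.merge(regions, on=["gene_id", "cell_state", "outcome_id"], how="inner")
    prioritized = merged[(merged["fdr_p"] < config.fdr) & (merged["max_h4"] > config.h4)]
    prioritized = prioritized[["gene_id", "cell_state", "outcome_id", "snp_id",
                               "beta_mr", "or_", "ci_low", "ci_high", "pval",
                               "fdr_p", "max_h4"]].reset_index(drop=True)
    return coloc, prioritized


def stage_tissue(bundle: StudyBundle, prioritized: pd.DataFrame,
                 instr: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Cross-tissue lookup for prioritized genes; lead = strongest instrument."""
    tcfg = config.tissue_config()
    if prioritized.empty:
        return pd.DataFrame(columns=["gene_id", "lead_snp", "proxy_snp", "proxy_r2",
                                     "status", *tcfg.local_tissues, "all_tissues_pct"])
    leads = []
    for gene_id in sorted(prioritized["gene_id"].unique()):
        sub = instr[instr["gene_id"] == gene_id]
        best = sub.loc[sub["F"].idxmax()]
        leads.append({"gene_id": gene_id, "snp_id": best["snp_id"]})
    return overlap_summary(pd.DataFrame(leads), bundle.ld, bundle.tissue_table, tcfg)


def run_pipeline(study, config: PipelineConfig | None = None,
                 out_dir=None) -> StudyReport:
    """Run the full workflow on a study bundle (object or on-disk path)."""
    config = config or PipelineConfig()
    bundle = study if isinstance(study, StudyBundle) else load_study(study)

    instr, audit = stage_instruments(bundle, config)
    mr_frame = stage_mr(instr, config)
    coloc, prioritized = stage_coloc(bundle, mr_frame, config)
    tissue = stage_tissue(bundle, prioritized, instr, config)

    mr_out = _split_state(mr_frame) if len(mr_frame) else mr_frame
    counts = {
        "genes": len(bundle.genes),
        "profiles": len(bundle.profiles),
        "outcome_strata": len(bundle.outcome_strata),
        "instruments": len(instr),
        "mr_tests": len(mr_frame),
        "fdr_hits": int(mr_frame["fdr_flag"].sum()) if len(mr_frame) else 0,
        "coloc_regions_tested": int(coloc[["gene_id", "cell_state", "outcome_id"]]
                                    .drop_duplicates().shape[0]) if len(coloc) else 0,
        "coloc_evidence": int((prioritized["max_h4"] > config.h4).sum())
        if len(prioritized) else 0,
        "prioritized_rows": len(prioritized),
        "prioritized_genes": int(prioritized["gene_id"].nunique()) if len(prioritized) else 0,
    }
    report = StudyReport(
        counts=counts,
        frames={"instruments": instr, "instrument_audit": audit, "mr": mr_out,
                "coloc": coloc, "prioritized": prioritized, "tissue": tissue},
        config=config,
        metadata={"seed": config.seed, "version": __version__,
                  "config_hash": config.hash()},
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
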