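"""Synthetic LD panels and exposure/outcome summary statistics under known truth.

The generator works directly in z-score space: marginal association z-vectors
for a region are drawn from MVN(R @ lambda, R), where R is the panel
correlation matrix and lambda the vector of true joint noncentralities. This
is the model under which summary-statistic conditioning and colocalisation
operate, so every downstream stage has an exact parameter-recovery surface.

Noncentrality conventions (standardized genotypes and phenotypes):

* exposure (quantitative, per-SD expression):
  ``lambda = sqrt(n_exp * h2 / (1 - h2))`` at the causal SNP;
* binary outcome (log-odds): ``lambda = b_std * sqrt(n_eff)`` with
  ``n_eff = 4 / (1/n_case + 1/n_control)``; for a causal gene the
  standardized outcome effect is ``b_std = theta * sqrt(h2)``.

Betas and standard errors are back-computed on the reported scales as
``se = 1 / sqrt(n * 2 f (1 - f))`` and ``beta = z * se``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_io import (
    DomainError,
    GeneRecord,
    LDReference,
    SumstatTable,
    effective_n,
    make_sumstats,
    read_gene_bed,
    read_ld_reference,
    read_profile_manifest,
    read_sumstats,
    write_gene_bed,
    write_sumstats,
    zscore_pvalue,
)


class ScenarioError(ValueError):
    """A requested simulation architecture is infeasible for the given panel."""


ARCHITECTURES = ("null", "exposure_only", "outcome_only", "distinct_variants",
                 "shared_variant", "causal_gene")

#: CD4+ T cell activation timepoints: resting, lowly active, pre-division,
#: post first division, effector.
ALL_TIMEPOINTS = ("0h", "LA", "16h", "40h", "5d")

#: CRC GWAS strata (overall plus anatomical-subsite and sex strata) with
#: their case/control sample sizes.
CRC_OUTCOME_STRATA: dict[str, tuple[int, int]] = {
    "overall": (78473, 107143),
    "proximal": (14416, 43099),
    "distal": (12879, 43099),
    "rectal": (14150, 43099),
    "left_sided": (27004, 43099),
    "colon": (28736, 43099),
    "female": (24594, 23936),
    "male": (28271, 22351),
}

#: multi-tissue eQTL resource emulation: 54 tissues including the two colon labels
DEFAULT_TISSUES: tuple[str, ...] = ("Colon_Sigmoid", "Colon_Transverse") + tuple(
    f"Tissue_{i:02d}" for i in range(1, 53))

_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
                 ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T")]


@dataclass
class Scenario:
    """Ground-truth description of one simulated gene region.

    ``theta`` is the causal effect of one SD of expression on outcome
    log-odds (only used by the ``causal_gene`` architecture); ``gamma_out``
    is the standardized outcome effect used by architectures whose outcome
    signal is unrelated to expression.
    """

    architecture: str = "null"
    theta: float = 0.0
    exposure_h2: float = 0.3
    gamma_out: float = 0.02
    n_exp: int = 119
    n_case: int = 78473
    n_control: int = 107143
    n_snps: int = 1600
    ld_decay: float = 0.95
    maf_range: tuple[float, float] = (0.05, 0.5)
    distinct_max_r2: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ScenarioError(f"unknown architecture {self.architecture!r}")
        if not 0.0 <= self.exposure_h2 < 1.0:
            raise DomainError("exposure_h2 must be in [0, 1)")
        if min(self.n_exp, self.n_case, self.n_control) < 2:
            raise DomainError("all sample sizes must be >= 2")
        if self.n_snps < 1:
            raise DomainError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.51):
            raise DomainError("maf_range must lie within (0, 0.5]")

    @property
    def n_eff_outcome(self) -> float:
        return effective_n(self.n_case, self.n_control)


@dataclass
class RegionTruth:
    """Simulation bookkeeping sufficient to score every downstream stage."""

    architecture: str
    theta: float
    causal_snp_exposure: str | None
    causal_snp_outcome: str | None
    lambda_exp: np.ndarray
    lambda_out: np.ndarray
    exposure_h2: float


def simulate_ld_panel(n_snps: int, n_individuals: int, ld_decay: float,
                      maf_range: tuple[float, float], seed: int, *,
                      chrom: str = "1", id_prefix: str = "rs") -> LDReference:
    """Simulate a diploid LD reference panel spanning ~1 Mb.

    Haplotype alleles follow a heterogeneous-margin two-state Markov chain
    along the region; two-state chain correlations compose multiplicatively,
    so the allele correlation between SNPs at distance d bp is
    ``ld_decay ** (d / 1000)`` (clipped to the Frechet bound where dissimilar
    MAFs make that target infeasible, as in real data). Dosages are sums of
    two independent haplotypes, hence Hardy-Weinberg genotype frequencies.
    Deterministic given ``seed``.
    """
    if n_snps < 1 or n_individuals < 2:
        raise DomainError("need n_snps >= 1 and n_individuals >= 2")
    if not 0.0 <= ld_decay < 1.0:
        raise DomainError("ld_decay must be in [0, 1)")
    rng = np.random.default_rng(seed)
    spacing = max(1, round(1_000_000 / n_snps))
    pos = spacing * (np.arange(n_snps, dtype=np.int64) + 1)
    mafs = rng.uniform(maf_range[0], maf_range[1], n_snps)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), n_snps)

    n_hap = 2 * n_individuals
    hap = np.empty((n_hap, n_snps), dtype=np.int8)
    hap[:, 0] = rng.random(n_hap) < mafs[0]
    r_adj = ld_decay ** (spacing / 1000.0) if ld_decay > 0 else 0.0
    for j in range(1, n_snps):
        p0, p1 = mafs[j - 1], mafs[j]
        sd01 = np.sqrt(p0 * (1 - p0) * p1 * (1 - p1))
        r_max = (min(p0, p1) - p0 * p1) / sd01
        r = min(r_adj, 0.995 * r_max)
        cov = r * sd01
        p_11 = np.clip(p1 + cov / p0, 0.0, 1.0)
        p_10 = np.clip(p1 - cov / (1 - p0), 0.0, 1.0)
        u = rng.random(n_hap)
        hap[:, j] = np.where(hap[:, j - 1] == 1, u < p_11, u < p_10)

    dosages = (hap[:n_individuals] + hap[n_individuals:]).astype(float)
    meta = pd.DataFrame({
        "snp_id": [f"{id_prefix}{i + 1}" for i in range(n_snps)],
        "chrom": chrom,
        "pos": pos,
        "ref_effect_allele": [_ALLELE_PAIRS[k][0] for k in pair_idx],
        "ref_other_allele": [_ALLELE_PAIRS[k][1] for k in pair_idx],
        "freq": mafs,
    })
    return LDReference.from_dosages(dosages, meta)


def _pick_causal(rng: np.random.Generator, ld: LDReference) -> int:
    """Prefer causal SNPs away from the frequency extremes, for stable SEs."""
    freq = ld.snp_meta["freq"].to_numpy()
    ok = np.flatnonzero((freq >= 0.05) & (freq <= 0.95))
    pool = ok if len(ok) else np.arange(ld.n_snps)
    return int(rng.choice(pool))


def simulate_region_sumstats(scenario: Scenario, ld: LDReference,
                             rng: np.random.Generator | None = None, *,
                             exposure_id: str = "exposure",
                             outcome_id: str = "outcome",
                             ) -> tuple[SumstatTable, SumstatTable, RegionTruth]:
    """Draw one exposure and one outcome summary-statistics table for a region.

    Marginal z-vectors are MVN(R @ lambda, R); the two traits are drawn
    independently (no sample overlap). Effects are reported per effect-allele
    copy on the per-SD-expression (exposure) and log-odds (outcome) scales,
    with EAFs equal to panel frequencies.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    n = ld.n_snps
    R = ld.corr
    arch = scenario.architecture

    lam_e = np.zeros(n)
    lam_o = np.zeros(n)
    ce = co = None
    if arch in ("exposure_only", "distinct_variants", "shared_variant", "causal_gene"):
        ce = _pick_causal(rng, ld)
        h2 = scenario.exposure_h2
        lam_e[ce] = np.sqrt(scenario.n_exp * h2 / (1.0 - h2))
    if arch == "outcome_only":
        co = _pick_causal(rng, ld)
    elif arch == "distinct_variants":
        if n < 2:
            raise ScenarioError("distinct_variants requires at least 2 SNPs")
        eligible = np.flatnonzero(R[ce] ** 2 < scenario.distinct_max_r2)
        if len(eligible) == 0:
            raise ScenarioError(
                f"no SNP with r2 < {scenario.distinct_max_r2} against the exposure causal SNP")
        co = int(rng.choice(eligible))
    elif arch in ("shared_variant", "causal_gene"):
        co = ce
    if co is not None:
        if arch == "causal_gene":
            b_std = scenario.theta * np.sqrt(scenario.exposure_h2)
        else:
            b_std = scenario.gamma_out
        lam_o[co] = b_std * np.sqrt(scenario.n_eff_outcome)

    L = ld.cholesky()
    z_e = R @ lam_e + L @ rng.standard_normal(n)
    z_o = R @ lam_o + L @ rng.standard_normal(n)

    meta = ld.snp_meta
    f = meta["freq"].to_numpy()
    het = 2.0 * f * (1.0 - f)

    # OLS-consistent exposure SE: residual sd is sqrt(1 - h2) when the region
    # carries a causal cis variant, so beta at the causal SNP back-computes to
    # the true per-allele effect sqrt(h2 / (2f(1-f)))
    resid_sd = np.sqrt(1.0 - scenario.exposure_h2) if lam_e.any() else 1.0
    se_e = resid_sd / np.sqrt(scenario.n_exp * het)
    exp_frame = pd.DataFrame({
        "snp_id": meta["snp_id"], "chrom": meta["chrom"], "pos": meta["pos"],
        "effect_allele": meta["ref_effect_allele"], "other_allele": meta["ref_other_allele"],
        "eaf": f, "beta": z_e * se_e, "se": se_e, "pval": zscore_pvalue(z_e),
        "n": scenario.n_exp,
    })
    exposure = make_sumstats(exp_frame, exposure_id, "quantitative")

    se_o = 1.0 / np.sqrt(scenario.n_eff_outcome * het)
    out_frame = pd.DataFrame({
        "snp_id": meta["snp_id"], "chrom": meta["chrom"], "pos": meta["pos"],
        "effect_allele": meta["ref_effect_allele"], "other_allele": meta["ref_other_allele"],
        "eaf": f, "beta": z_o * se_o, "se": se_o, "pval": zscore_pvalue(z_o),
        "n": scenario.n_case + scenario.n_control,
        "n_case": scenario.n_case, "n_control": scenario.n_control,
    })
    outcome = make_sumstats(out_frame, outcome_id, "binary")

    ids = meta["snp_id"].to_numpy()
    truth = RegionTruth(
        architecture=arch, theta=scenario.theta if arch == "causal_gene" else 0.0,
        causal_snp_exposure=None if ce is None else str(ids[ce]),
        causal_snp_outcome=None if co is None else str(ids[co]),
        lambda_exp=lam_e, lambda_out=lam_o, exposure_h2=scenario.exposure_h2)
    return exposure, outcome, truth


# ---------------------------------------------------------------------------
# Whole-study simulation


@dataclass
class StudyConfig:
    """Configuration for a synthetic cell-state-resolved eQTL x GWAS study.

    Defaults emulate the study conditions at donor scale: 119 eQTL donors,
    the overall CRC-GWAS case/control sizes, ~1 Mb cis regions. The gene,
    SNP and profile counts are configurable so tests can run at reduced
    scale; architecture fractions assign exactly round(fraction * n_genes)
    genes per class.
    """

    n_genes: int = 50
    profiles_per_gene: int = 1
    cell_subtypes: tuple[str, ...] = ("CD4_naive", "CD4_memory", "nTreg")
    timepoints: tuple[str, ...] = ("0h", "16h", "40h")
    fraction_causal: float = 0.1
    fraction_exposure_only: float = 0.5
    theta: float = -0.15
    h2_range: tuple[float, float] = (0.3, 0.45)
    gamma_out: float = 0.02
    n_exp: int = 119
    outcomes: dict = field(default_factory=lambda: {"overall": (78473, 107143)})
    n_snps: int = 1600
    n_individuals: int = 400
    ld_decay: float = 0.95
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_tissues: int = 54
    tissue_fraction_shared: float = 0.6
    tissue_availability: float = 1.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outcomes"] = {k: list(v) for k, v in self.outcomes.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        d = dict(d)
        for key in ("cell_subtypes", "timepoints", "h2_range", "maf_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "outcomes" in d:
            d["outcomes"] = {k: tuple(v) for k, v in d["outcomes"].items()}
        return cls(**d)


@dataclass
class StudyBundle:
    """In-memory synthetic study: all five pipeline inputs plus ground truth."""

    config: StudyConfig
    genes: list[GeneRecord]
    profiles: pd.DataFrame  # gene_id, cell_subtype, activation_timepoint, cell_state
    ld: dict[str, LDReference]  # gene_id -> panel
    exposures: dict[tuple[str, str], SumstatTable]  # (gene_id, cell_state) ->
    outcomes: dict[tuple[str, str], SumstatTable]  # (stratum, gene_id) ->
    truth: pd.DataFrame
    tissue_table: pd.DataFrame

    @property
    def outcome_strata(self) -> list[str]:
        return list(self.config.outcomes)


def _assign_architectures(cfg: StudyConfig, rng: np.random.Generator) -> list[str]:
    n_causal = round(cfg.fraction_causal * cfg.n_genes)
    n_expo = round(cfg.fraction_exposure_only * cfg.n_genes)
    if n_causal + n_expo > cfg.n_genes:
        raise DomainError("architecture fractions exceed 1")
    arch = (["causal_gene"] * n_causal + ["exposure_only"] * n_expo
            + ["null"] * (cfg.n_genes - n_causal - n_expo))
    order = rng.permutation(cfg.n_genes)
    return [arch[i] for i in np.argsort(order)]


def simulate_transcriptome_study(config: StudyConfig,
                                 out_dir: str | Path | None = None) -> StudyBundle:
    """Simulate a full study bundle; optionally write it to disk.

    One exposure table per (gene, cell-state profile), one outcome table per
    configured stratum, an LD panel, BED annotation and profile manifest per
    gene, a cross-tissue eQTL table, and a truth table. Fully reproducible
    from ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    states = [f"{s}_{t}" for s in cfg.cell_subtypes for t in cfg.timepoints]
    if cfg.profiles_per_gene > len(states):
        raise DomainError("profiles_per_gene exceeds the profile catalogue")
    archs = _assign_architectures(cfg, rng)

    genes: list[GeneRecord] = []
    profiles_rows = []
    ld_map: dict[str, LDReference] = {}
    exposures: dict[tuple[str, str], SumstatTable] = {}
    outcomes: dict[tuple[str, str], SumstatTable] = {}
    truth_rows = []
    tissue_instr_rows = []

    for g in range(cfg.n_genes):
        gene_id = f"GENE{g + 1:04d}"
        chrom = str(g + 1)
        panel = simulate_ld_panel(cfg.n_snps, cfg.n_individuals, cfg.ld_decay,
                                  cfg.maf_range,
                                  seed=int(rng.integers(2 ** 31)),
                                  chrom=chrom, id_prefix=f"rs{g + 1}_")
        ld_map[gene_id] = panel
        center = int(panel.snp_meta["pos"].iloc[len(panel.snp_meta) // 2])
        genes.append(GeneRecord(gene_id, chrom, max(0, center - 5000), center + 5000, "+"))

        arch = archs[g]
        h2 = float(rng.uniform(*cfg.h2_range))
        gene_states = [states[(g * cfg.profiles_per_gene + k) % len(states)]
                       for k in range(cfg.profiles_per_gene)]
        first_stratum = next(iter(cfg.outcomes))
        n_case0, n_control0 = cfg.outcomes[first_stratum]
        scen = Scenario(architecture=arch, theta=cfg.theta, exposure_h2=h2,
                        gamma_out=cfg.gamma_out, n_exp=cfg.n_exp,
                        n_case=n_case0, n_control=n_control0,
                        n_snps=cfg.n_snps, ld_decay=cfg.ld_decay,
                        maf_range=cfg.maf_range)

        # exposures: independent draw per profile, same causal architecture
        truth0 = None
        for state in gene_states:
            sub, tp = state.rsplit("_", 1)
            profiles_rows.append({"gene_id": gene_id, "cell_subtype": sub,
                                  "activation_timepoint": tp, "cell_state": state})
            if truth0 is None:
                expo, outc, truth0 = simulate_region_sumstats(
                    scen, panel, rng, exposure_id=f"{gene_id}|{state}",
                    outcome_id=f"{first_stratum}")
                outcomes[(first_stratum, gene_id)] = outc
            else:
                expo, _, _ = _redraw_exposure(scen, panel, truth0, rng,
                                              exposure_id=f"{gene_id}|{state}")
            exposures[(gene_id, state)] = expo
            truth_rows.append({
                "gene_id": gene_id, "cell_state": state, "architecture": arch,
                "theta": truth0.theta, "exposure_h2": round(h2, 6),
                "causal_snp_exposure": truth0.causal_snp_exposure or "NA",
                "causal_snp_outcome": truth0.causal_snp_outcome or "NA",
            })

        # remaining outcome strata: redraw outcome z at each stratum's n
        for stratum, (n_case, n_control) in cfg.outcomes.items():
            if stratum == first_stratum:
                continue
            scen_s = dataclasses.replace(scen, n_case=n_case, n_control=n_control)
            outcomes[(stratum, gene_id)] = _redraw_outcome(
                scen_s, panel, truth0, rng, outcome_id=stratum,
                base_neff=scen.n_eff_outcome)

        if truth0.causal_snp_exposure is not None:
            tissue_instr_rows.append({
                "gene_id": gene_id, "snp_id": truth0.causal_snp_exposure,
                "ncp": float(truth0.lambda_exp.max())})

    tissues = list(DEFAULT_TISSUES[:cfg.n_tissues])
    tissue_table = simulate_tissue_eqtl_table(
        pd.DataFrame(tissue_instr_rows, columns=["gene_id", "snp_id", "ncp"]),
        tissues, cfg.tissue_fraction_shared, seed=int(rng.integers(2 ** 31)),
        availability=cfg.tissue_availability)

    bundle = StudyBundle(
        config=cfg, genes=genes, profiles=pd.DataFrame(profiles_rows),
        ld=ld_map, exposures=exposures, outcomes=outcomes,
        truth=pd.DataFrame(truth_rows), tissue_table=tissue_table)
    if out_dir is not None:
        write_study(bundle, out_dir)
    return bundle


def _redraw_exposure(scen: Scenario, ld: LDReference, truth: RegionTruth,
                     rng: np.random.Generator, exposure_id: str):
    """New exposure noise draw with the region's fixed true noncentralities."""
    n = ld.n_snps
    z = ld.corr @ truth.lambda_exp + ld.cholesky() @ rng.standard_normal(n)
    meta = ld.snp_meta
    f = meta["freq"].to_numpy()
    resid_sd = np.sqrt(1.0 - truth.exposure_h2) if truth.lambda_exp.any() else 1.0
    se = resid_sd / np.sqrt(scen.n_exp * 2.0 * f * (1.0 - f))
    frame = pd.DataFrame({
        "snp_id": meta["snp_id"], "chrom": meta["chrom"], "pos": meta["pos"],
        "effect_allele": meta["ref_effect_allele"], "other_allele": meta["ref_other_allele"],
        "eaf": f, "beta": z * se, "se": se, "pval": zscore_pvalue(z), "n": scen.n_exp,
    })
    return make_sumstats(frame, exposure_id, "quantitative"), None, truth


def _redraw_outcome(scen: Scenario, ld: LDReference, truth: RegionTruth,
                    rng: np.random.Generator, outcome_id: str, *,
                    base_neff: float) -> SumstatTable:
    """New outcome draw at this stratum's sample size, same causal variant.

    The joint standardized effect is preserved, so the noncentrality (stored
    at ``base_neff``) rescales with sqrt(n_eff).
    """
    n = ld.n_snps
    lam = truth.lambda_out * np.sqrt(scen.n_eff_outcome / base_neff)
    z = ld.corr @ lam + ld.cholesky() @ rng.standard_normal(n)
    meta = ld.snp_meta
    f = meta["freq"].to_numpy()
    se = 1.0 / np.sqrt(scen.n_eff_outcome * 2.0 * f * (1.0 - f))
    frame = pd.DataFrame({
        "snp_id": meta["snp_id"], "chrom": meta["chrom"], "pos": meta["pos"],
        "effect_allele": meta["ref_effect_allele"], "other_allele": meta["ref_other_allele"],
        "eaf": f, "beta": z * se, "se": se, "pval": zscore_pvalue(z),
        "n": scen.n_case + scen.n_control,
        "n_case": scen.n_case, "n_control": scen.n_control,
    })
    return make_sumstats(frame, outcome_id, "binary")


def simulate_tissue_eqtl_table(instruments: pd.DataFrame, tissues: Sequence[str],
                               fraction_shared: float, seed: int, *,
                               availability: float = 1.0,
                               tissue_se: float = 0.1) -> pd.DataFrame:
    """Cross-tissue eQTL association table for the specificity lookup.

    ``instruments`` needs columns gene_id, snp_id, ncp (the instrument's eQTL
    noncentrality). A deterministic (seeded) subset of round(fraction_shared
    * n_tissues) tissues shares each instrument's signal; the rest draw from
    the null. Genes are omitted entirely with probability 1 - availability,
    emulating resource coverage gaps.
    """
    if not 0.0 <= fraction_shared <= 1.0:
        raise DomainError("fraction_shared must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tissues = list(tissues)
    n_shared = round(fraction_shared * len(tissues))
    rows = []
    for rec in instruments.itertuples(index=False):
        if rng.random() >= availability:
            continue
        shared = set(rng.choice(len(tissues), size=n_shared, replace=False))
        for t_idx, tissue in enumerate(tissues):
            z = (rec.ncp if t_idx in shared else 0.0) + rng.standard_normal()
            rows.append({
                "gene_id": rec.gene_id, "tissue": tissue, "snp_id": rec.snp_id,
                "beta": z * tissue_se, "se": tissue_se,
                "pval": float(zscore_pvalue(z)),
            })
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "snp_id", "beta", "se", "pval"])


# ---------------------------------------------------------------------------
# On-disk study bundle


def write_study(bundle: StudyBundle, out_dir: str | Path) -> Path:
    """Write a study bundle in core_io dialects; layout is self-describing."""
    out = Path(out_dir)
    (out / "exposures").mkdir(parents=True, exist_ok=True)
    (out / "outcomes").mkdir(exist_ok=True)
    (out / "ld").mkdir(exist_ok=True)

    write_gene_bed(bundle.genes, out / "genes.bed")
    manifest = bundle.profiles.copy()
    manifest["sumstats"] = [
        f"exposures/{g}__{s}.tsv" for g, s in zip(manifest["gene_id"], manifest["cell_state"])]
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)

    regions = []
    for gene in bundle.genes:
        prefix = out / "ld" / gene.gene_id
        bundle.ld[gene.gene_id].write(prefix)
        regions.append({"gene_id": gene.gene_id, "chrom": gene.chrom,
                        "ld_prefix": f"ld/{gene.gene_id}"})
    pd.DataFrame(regions).to_csv(out / "regions.tsv", sep="\t", index=False)

    for (gene_id, state), table in bundle.exposures.items():
        write_sumstats(table, out / "exposures" / f"{gene_id}__{state}.tsv")
    for stratum in bundle.outcome_strata:
        parts = [bundle.outcomes[(stratum, g.gene_id)].frame for g in bundle.genes]
        merged = pd.concat(parts, ignore_index=True)
        tab = SumstatTable(stratum, "binary", merged)
        write_sumstats(tab, out / "outcomes" / f"{stratum}.tsv")

    bundle.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    bundle.tissue_table.to_csv(out / "tissue_eqtl.tsv", sep="\t", index=False)
    with open(out / "study_config.yaml", "w") as fh:
        # keep insertion order: the outcomes dict's order defines the strata order
        yaml.safe_dump(bundle.config.to_dict(), fh, sort_keys=False)
    return out


def load_study(path: str | Path) -> StudyBundle:
    """Load a study bundle written by :func:`write_study`."""
    root = Path(path)
    with open(root / "study_config.yaml") as fh:
        cfg = StudyConfig.from_dict(yaml.safe_load(fh))
    genes = read_gene_bed(root / "genes.bed")
    profiles = read_profile_manifest(root / "manifest.tsv")
    regions = pd.read_csv(root / "regions.tsv", sep="\t", dtype=str)
    ld_map = {}
    for rec in regions.itertuples(index=False):
        prefix = root / rec.ld_prefix
        ld_map[rec.gene_id] = read_ld_reference(
            str(prefix) + ".dosages.tsv", str(prefix) + ".snps.tsv")
    exposures = {}
    for rec in profiles.itertuples(index=False):
        table = read_sumstats(root / rec.sumstats, trait_id=f"{rec.gene_id}|{rec.cell_state}",
                              trait_type="quantitative")
        exposures[(rec.gene_id, rec.cell_state)] = table
    gene_chrom = {g.gene_id: g.chrom for g in genes}
    outcomes = {}
    for stratum in cfg.outcomes:
        full = read_sumstats(root / "outcomes" / f"{stratum}.tsv",
                             trait_id=stratum, trait_type="binary")
        by_chrom = dict(tuple(full.frame.groupby("chrom", sort=False)))
        for gene_id, chrom in gene_chrom.items():
            sub = by_chrom.get(chrom, full.frame.iloc[0:0]).reset_index(drop=True)
            outcomes[(stratum, gene_id)] = SumstatTable(stratum, "binary", sub)
    truth = pd.read_csv(root / "truth.tsv", sep="\t", dtype={"gene_id": str},
                        float_precision="round_trip")
    tissue = pd.read_csv(root / "tissue_eqtl.tsv", sep="\t", dtype={"gene_id": str},
                         float_precision="round_trip")
    return StudyBundle(cfg, genes, profiles, ld_map, exposures, outcomes, truth, tissue)
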