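"""Reading, validation, writing and harmonization of GWAS/eQTL summary statistics,
LD reference panels and gene annotation.

All coordinate conventions are resolved here and nowhere else: summary
statistics carry 1-based positions (GWAS convention), gene annotation is BED
0-based half-open. Downstream modules consume only the containers defined in
this module.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class ConfigurationError(ValueError):
    """A column mapping or config value is unusable."""


class FormatError(ValueError):
    """An input file violates its declared dialect."""


class EmptyInputError(ValueError):
    """No records survive validation."""


class EmptyOverlapError(ValueError):
    """Two tables share no SNPs."""


class DomainError(ValueError):
    """An argument is outside the mathematical domain of an operation."""


#: canonical on-disk column names for summary statistics (TSV with header)
CANONICAL_COLUMNS: dict[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
    "n_case": "N_CASE",
    "n_control": "N_CONTROL",
}

MANDATORY_FIELDS = ("snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# smallest representable two-sided normal p before underflow; p-values are
# clipped here rather than reported as an (invalid) exact zero
_P_FLOOR = 1e-320


def zscore_pvalue(z: np.ndarray | float) -> np.ndarray | float:
    """Two-sided standard-normal p-value for a z-score, clipped away from zero."""
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.maximum(p, _P_FLOOR)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise DomainError(f"invalid interval [{self.start}, {self.end})")

    def contains_pos1(self, pos: int | np.ndarray) -> bool | np.ndarray:
        """Membership test for a 1-based position."""
        return (pos - 1 >= self.start) & (pos - 1 < self.end)

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene, optionally bound to a cell-state expression profile.

    ``cell_state`` labels follow the subtype_timepoint convention
    (e.g. ``CD4_naive_0h``).
    """

    gene_id: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str = "."
    cell_state: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise DomainError(f"{self.gene_id}: start must precede end")
        if self.strand not in ("+", "-", "."):
            raise DomainError(f"{self.gene_id}: bad strand {self.strand!r}")

    def with_cell_state(self, cell_state: str) -> "GeneRecord":
        return dataclasses.replace(self, cell_state=cell_state)


@dataclass
class SumstatTable:
    """One trait's marginal per-SNP associations in a region.

    ``frame`` holds internal (lower-case) column names; positions are 1-based.
    ``audit`` records rows dropped or flagged during validation.
    """

    trait_id: str
    trait_type: str  # "quantitative" | "binary"
    frame: pd.DataFrame
    region: GenomicInterval | None = None
    audit: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if self.trait_type not in ("quantitative", "binary"):
            raise ConfigurationError(f"unknown trait_type {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.frame["snp_id"].to_numpy()

    def subset(self, snp_ids: Sequence[str]) -> "SumstatTable":
        keep = self.frame[self.frame["snp_id"].isin(set(snp_ids))]
        return SumstatTable(self.trait_id, self.trait_type, keep.reset_index(drop=True), self.region)

    def restrict(self, interval: GenomicInterval) -> "SumstatTable":
        f = self.frame
        mask = (f["chrom"].astype(str) == interval.chrom) & interval.contains_pos1(f["pos"].to_numpy())
        return SumstatTable(self.trait_id, self.trait_type, f[mask].reset_index(drop=True), interval)

    def zscores(self) -> np.ndarray:
        return (self.frame["beta"] / self.frame["se"]).to_numpy()


def _validate_frame(df: pd.DataFrame, trait_type: str) -> tuple[pd.DataFrame, list[dict]]:
    audit: list[dict] = []

    def drop(mask: pd.Series, reason: str):
        nonlocal df
        for sid in df.loc[mask, "snp_id"]:
            audit.append({"snp_id": sid, "reason": reason, "action": "dropped"})
        df = df[~mask]

    df = df.copy()
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    bad_allele = pd.Series(False, index=df.index)
    for col in ("effect_allele", "other_allele"):
        valid = df[col].str.fullmatch(r"[ACGT]+")
        bad_allele |= ~valid.fillna(False)
    drop(bad_allele, "invalid_alleles")

    indel = (df["effect_allele"].str.len() > 1) | (df["other_allele"].str.len() > 1)
    for sid in df.loc[indel, "snp_id"]:
        audit.append({"snp_id": sid, "reason": "indel_allele", "action": "flagged"})

    drop(~(df["se"] > 0), "nonpositive_se")
    drop(df["beta"].isna(), "missing_beta")
    drop(df["pos"].isna() | (df["pos"] < 1), "invalid_position")
    df["pos"] = df["pos"].astype(np.int64)

    if "eaf" in df:
        bad_eaf = df["eaf"].notna() & ~((df["eaf"] > 0) & (df["eaf"] < 1))
        for sid in df.loc[bad_eaf, "snp_id"]:
            audit.append({"snp_id": sid, "reason": "eaf_out_of_range", "action": "set_missing"})
        df.loc[bad_eaf, "eaf"] = np.nan
    else:
        df["eaf"] = np.nan

    z = (df["beta"] / df["se"]).to_numpy()
    p_from_z = zscore_pvalue(z)
    if "pval" not in df:
        df["pval"] = p_from_z
    else:
        invalid_p = df["pval"].isna() | ~((df["pval"] > 0) & (df["pval"] <= 1))
        for sid in df.loc[invalid_p, "snp_id"]:
            audit.append({"snp_id": sid, "reason": "pval_recomputed", "action": "flagged"})
        df.loc[invalid_p, "pval"] = p_from_z[invalid_p.to_numpy()]
        # consistency with |beta/se| under a two-sided normal (10% relative),
        # skipped near the underflow floor where relative error is meaningless
        comparable = (~invalid_p).to_numpy() & (p_from_z > 1e-300) & (df["pval"].to_numpy() > 1e-300)
        rel = np.ones(len(df))
        with np.errstate(divide="ignore", invalid="ignore"):
            rel[comparable] = np.abs(df["pval"].to_numpy()[comparable] - p_from_z[comparable]) / p_from_z[comparable]
        drop(pd.Series(comparable & (rel > 0.10), index=df.index), "pval_inconsistent_with_z")

    if trait_type == "binary":
        if "n_case" not in df or "n_control" not in df:
            raise ConfigurationError("binary trait requires N_CASE and N_CONTROL columns")
        drop(df["n_case"].isna() | df["n_control"].isna(), "missing_case_control_n")
        if "n" not in df or df["n"].isna().all():
            df["n"] = df["n_case"] + df["n_control"]
        df["n"] = df["n"].fillna(df["n_case"] + df["n_control"])
        drop(df["n"] != df["n_case"] + df["n_control"], "case_control_n_mismatch")
        df["n_case"] = df["n_case"].astype(np.int64)
        df["n_control"] = df["n_control"].astype(np.int64)
    else:
        if "n" not in df:
            df["n"] = np.nan
        df["n_case"] = np.nan
        df["n_control"] = np.nan

    dup = df["snp_id"].duplicated(keep="first")
    drop(dup, "duplicate_snp_id")

    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    cols = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "eaf",
            "beta", "se", "pval", "n", "n_case", "n_control"]
    return df[cols], audit


def make_sumstats(frame: pd.DataFrame, trait_id: str, trait_type: str,
                  region: GenomicInterval | None = None) -> SumstatTable:
    """Validate an in-memory frame (internal column names) into a SumstatTable."""
    clean, audit = _validate_frame(frame, trait_type)
    if len(clean) == 0:
        raise EmptyInputError(f"{trait_id}: no records survive validation")
    return SumstatTable(trait_id, trait_type, clean, region, audit)


def read_sumstats(path, dialect: Mapping[str, str] | None = None, *,
                  trait_id: str | None = None, trait_type: str | None = None) -> SumstatTable:
    """Read a summary-statistics TSV into a validated :class:`SumstatTable`.

    Parameters
    ----------
    path : str or Path
        Tab-delimited file with a header row.
    dialect : mapping, optional
        Maps internal field names (``snp_id`` ...) to the file's column
        headers. Defaults to the canonical ``SNP/CHR/POS/EA/OA/...`` headers.
    trait_type : {"quantitative", "binary"}, optional
        Inferred from the presence of case/control columns when omitted.
    """
    raw = pd.read_csv(path, sep="\t", na_values=["NA", ""], dtype={0: str},
                      float_precision="round_trip")
    mapping = dict(CANONICAL_COLUMNS)
    if dialect:
        mapping.update(dialect)
    rename = {}
    for internal, external in mapping.items():
        if external in raw.columns:
            rename[external] = internal
    missing = [f for f in MANDATORY_FIELDS if mapping[f] not in raw.columns]
    if missing:
        raise ConfigurationError(
            "missing mandatory column(s): "
            + ", ".join(f"{f} (expected header {mapping[f]!r})" for f in missing))
    df = raw.rename(columns=rename)
    if trait_type is None:
        trait_type = "binary" if ("n_case" in df and df["n_case"].notna().any()) else "quantitative"
    if trait_id is None:
        trait_id = str(path)
    return make_sumstats(df, trait_id, trait_type)


def write_sumstats(table: SumstatTable, path) -> None:
    """Write a table in the canonical TSV dialect (lossless for float fields)."""
    out = table.frame.rename(columns=CANONICAL_COLUMNS)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# LD reference


@dataclass
class LDReference:
    """Aligned genotype panel and derived SNP-SNP correlation matrix.

    ``snp_meta`` columns: snp_id, chrom, pos, ref_effect_allele,
    ref_other_allele, freq (effect-allele frequency). ``corr`` is the Pearson
    correlation of effect-allele dosages; its row/column order matches
    ``snp_meta``. ``dosages`` (individuals x SNPs, in [0, 2]) may be absent
    when the panel was loaded from a precomputed correlation matrix.
    """

    snp_meta: pd.DataFrame
    corr: np.ndarray
    dosages: np.ndarray | None = None
    audit: list[dict] = field(default_factory=list)
    _chol: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        n = len(self.snp_meta)
        if self.corr.shape != (n, n):
            raise FormatError(f"corr shape {self.corr.shape} does not match {n} SNPs")
        if not np.allclose(self.corr, self.corr.T, atol=1e-10):
            raise FormatError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-8):
            raise FormatError("correlation matrix diagonal is not 1")
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        self._index = {s: i for i, s in enumerate(self.snp_meta["snp_id"])}

    @classmethod
    def from_dosages(cls, dosages: np.ndarray, snp_meta: pd.DataFrame) -> "LDReference":
        """Build a panel from a dosage matrix; monomorphic SNPs are removed and logged."""
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape[1] != len(snp_meta):
            raise FormatError(
                f"dosage matrix has {dosages.shape[1]} columns for {len(snp_meta)} SNPs")
        sd = dosages.std(axis=0)
        mono = sd == 0
        audit = [{"snp_id": s, "reason": "monomorphic", "action": "dropped"}
                 for s in snp_meta.loc[mono, "snp_id"]]
        dosages = dosages[:, ~mono]
        snp_meta = snp_meta.loc[~mono].reset_index(drop=True).copy()
        snp_meta["freq"] = dosages.mean(axis=0) / 2.0
        corr = np.corrcoef(dosages, rowvar=False)
        corr = np.atleast_2d(corr)
        np.fill_diagonal(corr, 1.0)
        return cls(snp_meta, corr, dosages, audit)

    @property
    def n_snps(self) -> int:
        return len(self.snp_meta)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_meta["snp_id"].to_numpy()

    def index_of(self, snp_ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._index[s] for s in snp_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"SNP {e.args[0]!r} absent from LD reference") from None

    def contains(self, snp_id: str) -> bool:
        return snp_id in self._index

    def subset(self, snp_ids: Sequence[str]) -> "LDReference":
        idx = self.index_of(snp_ids)
        meta = self.snp_meta.iloc[idx].reset_index(drop=True)
        dos = self.dosages[:, idx] if self.dosages is not None else None
        return LDReference(meta, self.corr[np.ix_(idx, idx)], dos)

    def r2(self, a: str, b: str) -> float:
        i, j = self._index[a], self._index[b]
        return float(self.corr[i, j] ** 2)

    def cholesky(self) -> np.ndarray:
        """Lower Cholesky factor of corr (cached), with escalating jitter."""
        if self._chol is None:
            jitter = 1e-10
            for _ in range(8):
                try:
                    self._chol = np.linalg.cholesky(
                        self.corr + jitter * np.eye(self.n_snps))
                    break
                except np.linalg.LinAlgError:
                    jitter *= 100
            else:
                raise np.linalg.LinAlgError("correlation matrix not factorizable")
        return self._chol

    def relabel(self, chrom: str | None = None, id_map: Mapping[str, str] | None = None) -> "LDReference":
        meta = self.snp_meta.copy()
        if chrom is not None:
            meta["chrom"] = chrom
        if id_map is not None:
            meta["snp_id"] = meta["snp_id"].map(lambda s: id_map.get(s, s))
        return LDReference(meta, self.corr, self.dosages)

    def write(self, prefix) -> None:
        prefix = str(prefix)
        self.snp_meta.to_csv(prefix + ".snps.tsv", sep="\t", index=False)
        if self.dosages is None:
            raise FormatError("panel has no dosages to write")
        pd.DataFrame(self.dosages, columns=self.snp_meta["snp_id"]).to_csv(
            prefix + ".dosages.tsv", sep="\t", index=False)


def read_ld_reference(genotype_path, snplist_path) -> LDReference:
    """Read a dosage-matrix TSV (individuals x SNPs) plus SNP metadata TSV."""
    meta = pd.read_csv(snplist_path, sep="\t", dtype={"snp_id": str, "chrom": str},
                       float_precision="round_trip")
    dos = pd.read_csv(genotype_path, sep="\t")
    if dos.shape[1] != len(meta):
        raise FormatError(
            f"dosage matrix has {dos.shape[1]} columns but SNP list has {len(meta)} rows")
    return LDReference.from_dosages(dos.to_numpy(dtype=float), meta)


def read_ld_corr(corr_path, snplist_path) -> LDReference:
    """Read a precomputed correlation matrix TSV plus SNP metadata TSV."""
    meta = pd.read_csv(snplist_path, sep="\t", dtype={"snp_id": str, "chrom": str},
                       float_precision="round_trip")
    corr = pd.read_csv(corr_path, sep="\t", header=None).to_numpy(dtype=float)
    return LDReference(meta, corr)


# ---------------------------------------------------------------------------
# Gene annotation


def read_gene_bed(path) -> list[GeneRecord]:
    """Read BED6 gene annotation (0-based half-open, gene_id in the name field)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     dtype={"chrom": str})
    return [GeneRecord(r.name, r.chrom, int(r.start), int(r.end), str(r.strand))
            for r in df.itertuples(index=False)]


def write_gene_bed(genes: Sequence[GeneRecord], path) -> None:
    rows = [(g.chrom, g.start, g.end, g.gene_id, 0, g.strand) for g in genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_profile_manifest(path) -> pd.DataFrame:
    """Read the profile manifest TSV: gene_id, cell_subtype, activation_timepoint, sumstats path.

    Adds a ``cell_state`` column in the subtype_timepoint convention.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "cell_subtype", "activation_timepoint"):
        if col not in df.columns:
            raise ConfigurationError(f"profile manifest missing column {col!r}")
    df["cell_state"] = df["cell_subtype"] + "_" + df["activation_timepoint"]
    return df


# ---------------------------------------------------------------------------
# Harmonization

HARMONIZE_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
                     "beta_exp", "se_exp", "eaf_exp", "beta_out", "se_out",
                     "eaf_out", "action"]


def _is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


def _complement(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[b] for b in allele)
    except KeyError:
        return None


def harmonize(exposure: SumstatTable, outcome: SumstatTable,
              palindromic_maf_cut: float = 0.42) -> pd.DataFrame:
    """Align outcome records to the exposure's effect-allele orientation.

    Returns one row per overlapping SNP with an ``action`` column in
    {kept, sign_flipped, dropped_palindromic, dropped_incompatible}.
    Palindromic (A/T, C/G) SNPs are frequency-aligned when informative and
    dropped when min(eaf, 1-eaf) exceeds ``palindromic_maf_cut`` in either
    trait (or when a frequency is missing).
    """
    e = exposure.frame.set_index("snp_id")
    o = outcome.frame.set_index("snp_id")
    shared = e.index.intersection(o.index)
    if len(shared) == 0:
        raise EmptyOverlapError(
            f"no overlapping SNPs between {exposure.trait_id} and {outcome.trait_id}")

    rows = []
    for sid in shared:
        ex, ou = e.loc[sid], o.loc[sid]
        ea_e, oa_e = ex["effect_allele"], ex["other_allele"]
        ea_o, oa_o = ou["effect_allele"], ou["other_allele"]
        beta_o, eaf_o = ou["beta"], ou["eaf"]
        action = None

        if _is_palindromic(ea_e, oa_e):
            if {ea_o, oa_o} != {ea_e, oa_e}:
                action = "dropped_incompatible"
            else:
                eaf_o_adj = eaf_o if ea_o == ea_e else (1.0 - eaf_o if pd.notna(eaf_o) else np.nan)
                mafs = [ex["eaf"], eaf_o_adj]
                if any(pd.isna(m) for m in mafs) or any(min(m, 1 - m) > palindromic_maf_cut for m in mafs):
                    action = "dropped_palindromic"
                else:
                    flipped = ea_o != ea_e
                    if flipped:
                        beta_o, eaf_o = -beta_o, 1.0 - eaf_o
                    # frequency-based strand resolution: minor alleles must agree
                    if (ex["eaf"] < 0.5) != (eaf_o < 0.5):
                        beta_o, eaf_o = -beta_o, 1.0 - eaf_o
                        flipped = not flipped
                    action = "sign_flipped" if flipped else "kept"
        else:
            cea, coa = _complement(ea_o), _complement(oa_o)
            if (ea_o, oa_o) == (ea_e, oa_e):
                action = "kept"
            elif (ea_o, oa_o) == (oa_e, ea_e):
                beta_o = -beta_o
                eaf_o = 1.0 - eaf_o if pd.notna(eaf_o) else np.nan
                action = "sign_flipped"
            elif (cea, coa) == (ea_e, oa_e):
                action = "kept"  # pure strand flip, same orientation
            elif (cea, coa) == (oa_e, ea_e):
                beta_o = -beta_o
                eaf_o = 1.0 - eaf_o if pd.notna(eaf_o) else np.nan
                action = "sign_flipped"
            else:
                action = "dropped_incompatible"

        rows.append({
            "snp_id": sid, "chrom": ex["chrom"], "pos": ex["pos"],
            "effect_allele": ea_e, "other_allele": oa_e,
            "beta_exp": ex["beta"], "se_exp": ex["se"], "eaf_exp": ex["eaf"],
            "beta_out": beta_o if action in ("kept", "sign_flipped") else np.nan,
            "se_out": ou["se"] if action in ("kept", "sign_flipped") else np.nan,
            "eaf_out": eaf_o if action in ("kept", "sign_flipped") else np.nan,
            "action": action,
        })
    out = pd.DataFrame(rows, columns=HARMONIZE_COLUMNS)
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def kept_pairs(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Rows of a harmonization frame whose outcome effect is usable."""
    return harmonized[harmonized["action"].isin(["kept", "sign_flipped"])].reset_index(drop=True)


def align_to_reference(table: SumstatTable, ld: LDReference) -> SumstatTable:
    """Orient a table's effects to the LD panel's reference effect alleles.

    SNPs absent from the panel, or with irreconcilable alleles, are dropped
    (recorded in the returned table's audit). The sign convention of z-scores
    then matches the dosage correlations in ``ld.corr``.
    """
    meta = ld.snp_meta.set_index("snp_id")
    f = table.frame
    audit = []
    keep_rows = []
    for row in f.itertuples(index=False):
        if row.snp_id not in meta.index:
            audit.append({"snp_id": row.snp_id, "reason": "absent_from_ld", "action": "dropped"})
            continue
        m = meta.loc[row.snp_id]
        rec = row._asdict()
        if (row.effect_allele, row.other_allele) == (m["ref_effect_allele"], m["ref_other_allele"]):
            pass
        elif (row.effect_allele, row.other_allele) == (m["ref_other_allele"], m["ref_effect_allele"]):
            rec["beta"] = -rec["beta"]
            rec["eaf"] = 1.0 - rec["eaf"] if pd.notna(rec["eaf"]) else np.nan
            rec["effect_allele"], rec["other_allele"] = m["ref_effect_allele"], m["ref_other_allele"]
        else:
            audit.append({"snp_id": row.snp_id, "reason": "allele_mismatch_with_ld", "action": "dropped"})
            continue
        keep_rows.append(rec)
    if not keep_rows:
        raise EmptyOverlapError(f"{table.trait_id}: no SNPs align to the LD reference")
    out = SumstatTable(table.trait_id, table.trait_type,
                       pd.DataFrame(keep_rows).reset_index(drop=True), table.region)
    out.audit = list(table.audit) + audit
    return out


def effective_n(n_case: float, n_control: float) -> float:
    """Case-control effective sample size, 4 / (1/n_case + 1/n_control)."""
    if n_case <= 0 or n_control <= 0:
        raise DomainError("case/control counts must be positive")
    return 4.0 / (1.0 / n_case + 1.0 / n_control)


def sample_size_for(table: SumstatTable) -> float:
    """The n relevant to summary-statistic approximations for this trait.

    Quantitative traits use N; binary traits the case-control effective n.
    """
    f = table.frame
    if table.trait_type == "binary":
        return effective_n(float(f["n_case"].iloc[0]), float(f["n_control"].iloc[0]))
    n = f["n"].dropna()
    if n.empty:
        raise DomainError(f"{table.trait_id}: sample size missing")
    return float(n.iloc[0])
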