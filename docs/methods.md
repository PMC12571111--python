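# Methods

`statemr` estimates causal effects of cell-state-resolved gene expression on
a binary disease outcome from two-sample summary statistics, and provides a
matched synthetic-data generator so that every stage of the analysis can be
verified against known ground truth. This note documents the statistical
model, the defaults and why they were chosen, the numerical decisions, and
what the simulations do and do not establish about real data.

## The analysis model

**Instruments.** For each gene × cell-state expression profile, candidate
instruments are cis-eQTL SNPs inside the gene body ± 500 kb with
P < 5×10⁻⁸. Candidates are thinned by greedy p-value-ranked clumping: the
most significant remaining SNP becomes an index SNP and every remaining
candidate with r² ≥ 0.001 against it *or* within 10 kb of it is discarded.
The r² criterion applies regardless of distance; the 10 kb window is an
additional proximity discard. (The two criteria could also be read as a
conjunction; the rule actually applied is printed in every run header so the
choice is auditable.) Ties on p are broken by smaller genomic position, for
determinism. Surviving SNPs are harmonized to the outcome (see below),
weak instruments are removed with the single-SNP approximation
F = (β/se)² < 10, and Steiger filtering removes SNPs whose variance
explained in the *outcome*, r² = z²/(z² + n* − 2), is greater than or equal
to their variance explained in the exposure (n* is N for quantitative traits
and the effective sample size 4/(1/N_case + 1/N_control) for case-control
traits). The Steiger comparison is strict — exact ties are excluded —
and no Steiger p-value threshold is applied. Note that some descriptions of
Steiger filtering state the opposite inequality; the direction used here is
the one that guards against reverse causation, which is the filter's stated
purpose.

**Wald-ratio MR.** With a single instrument, the causal effect of one SD of
expression on outcome log-odds is β_MR = β_out/β_exp. The default standard
error is the second-order delta approximation
√(se_out²/β_exp² + β_out²·se_exp²/β_exp⁴); the first-order se_out/|β_exp| is
available by flag. Estimates are reported as OR = exp(β_MR) with 95% CI
exp(β_MR ± 1.959964·se). When a gene × cell state retains several clumped
instruments each is reported separately (no inverse-variance pooling) and
flagged as multi-instrument. Benjamini–Hochberg FDR is applied across all
gene × cell-state tests *within each outcome stratum* (the universe is
configurable to a joint correction; the per-outcome choice matches
per-outcome reporting and is printed in the run header).

**Colocalisation.** FDR-passing tuples are tested for a shared causal
variant. Per-SNP evidence is the Wakefield approximate Bayes factor,
log ABF = ½log(1−r) + ½rz² with r = W/(V+W), V = se², and effect-size prior
SD √W = 0.15 for per-SD expression traits and 0.2 for log-odds traits.
Five hypotheses are compared — no causal variant (H0), causal for one trait
only (H1/H2), distinct causal variants (H3), shared causal variant (H4) —
with per-SNP priors p1 = p2 = 10⁻⁵ and p12 = 10⁻⁷, calibrated for windows of
roughly 1,600 SNPs (under those priors a window's prior P(H4) ≈ 1.6×10⁻⁴
and P(H1) ≈ 1.6×10⁻²; `prior_expectations` computes these exactly).

Because a cis window can hold several independent signals, each trait is
first decomposed by stepwise conditional selection from summary statistics
plus an LD reference. All conditional algebra is done in standardized
z-space: conditioning a SNP j on a set C uses
z_{j|C} = (z_j − R_{jC}R_{CC}⁻¹z_C)/√(1 − R_{jC}R_{CC}⁻¹R_{Cj}), with the
conditioned SE inflated by the same factor. This is an approximation to the
full conditional/joint analysis with explicit allele-frequency bookkeeping;
it is exact for standardized genotypes and phenotypes and is verified
against full-data joint least squares in the test suite (max |Δz| < 0.05 at
n = 2,000). Selection starts at the sentinel (smallest p), adds the SNP with
the smallest conditional p while it stays below 5×10⁻⁸ and its r² with every
selected SNP stays below 0.9, and stops otherwise. For a trait with k ≥ 2
signals, each signal is conditioned on the other k−1; colocalisation runs on
every cross-pair of datasets (always including marginal × marginal), and the
region-level evidence is the maximum H4 over pairs, flagged at
max H4 > 0.8. All ABF accumulation is in log space via log-sum-exp; regions
with |z| ≈ 30–40 overflow in raw space otherwise.

**Prioritization and tissue specificity.** A gene is prioritized when some
gene × cell state × outcome tuple has BH-FDR < 0.05 *and* max H4 > 0.8 —
exactly that conjunction, assertable on any report. For each prioritized
gene the strongest instrument is looked up in a multi-tissue eQTL table; if
the SNP itself is absent, the available SNP in highest LD is used provided
r² ≥ 0.8, otherwise the gene is reported as not available. A tissue counts
as shared at P < 5×10⁻⁸ (the threshold applies to the proxy's own
association p-value). Missing (gene, tissue) entries count as
non-significant in the denominator by default; a strict mode excludes them.
The designated "local" tissues reported as named flags default to the two
colon labels and are configurable.

## Harmonization

Outcome records are oriented to the exposure's effect allele. Identical
allele pairs are kept; swapped pairs have β negated and EAF reflected;
non-palindromic strand flips are resolved by complementing. Palindromic
(A/T, C/G) SNPs are aligned by allele frequency when informative and dropped
when min(EAF, 1−EAF) > 0.42 in either trait or a frequency is missing. The
0.42 cut-off is the package's own default (standard two-sample MR practice);
it is surfaced in config. Every decision is recorded per SNP
(kept / sign_flipped / dropped_palindromic / dropped_incompatible), and
harmonization is idempotent.

## The synthetic-data generator

The generator emulates the five inputs of the analysis — per-profile eQTL
tables, stratified case-control GWAS tables, an LD panel, BED annotation,
and a cross-tissue eQTL table — under a known per-gene architecture: null,
exposure_only, outcome_only, distinct_variants (the H3 configuration),
shared_variant (H4 with an expression-independent outcome effect), or
causal_gene (shared variant whose outcome effect is θ × the expression
effect).

**LD panels.** Haplotype alleles follow a heterogeneous-margin two-state
Markov chain along the region. Two-state chain correlations compose
multiplicatively, so the allele correlation at distance d bp is exactly
ld_decay^(d/1000) — by default 0.95 per kb — clipped to the Fréchet upper
bound when dissimilar MAFs make the target infeasible (as in real genotypes,
where high r² requires similar allele frequencies). Dosages are sums of two
independent haplotypes, giving Hardy–Weinberg genotype frequencies; MAFs are
uniform on (0.05, 0.5) by default, positions span ~1 Mb. Alleles are drawn
from non-strand-ambiguous pairs, i.e. the panel emulates a post-QC
reference; the palindromic harmonization paths are exercised by dedicated
constructed tests instead.

**Summary statistics.** Marginal z-vectors are drawn exactly as
z ~ MVN(Rλ, R), where R is the panel correlation matrix and λ the joint
noncentrality vector. This is the model under which the conditional analysis
and colocalisation operate, so downstream recovery is testable without
individual-level simulation (an individual-level path exists solely as the
oracle for the conditioning test). Noncentralities: the causal exposure SNP
has λ = √(n·h²/(1−h²)); a binary outcome SNP has λ = b·√(n_eff) with b the
standardized log-odds effect (b = θ√h² for a causal gene). Betas and SEs are
back-computed as se = σ/√(n·2f(1−f)), β = z·se, with σ = √(1−h²) for an
exposure region carrying a causal variant (the OLS residual SD) and σ = 1
otherwise. The residual-SD factor matters: without it the implied exposure
beta is inflated by 1/√(1−h²) and the Wald ratio would be attenuated to
θ√(1−h²) rather than recover θ.

**Defaults as study conditions.** n_exp = 119 donors; the outcome defaults
to 78,473 cases / 107,143 controls, with the full set of subsite- and
sex-stratum sample sizes available as `CRC_OUTCOME_STRATA`; 1,600 SNPs per
region (≈ the ~1,621-SNP windows the priors were calibrated for);
θ = −0.15 for causal genes. Two defaults are the package's own choices where
no value is stated anywhere: (i) exposure h² for eQTL-bearing genes is drawn
U(0.30, 0.45) — at n = 119, h² = 0.2 puts the causal z exactly at the
genome-wide threshold, so a lower range would make "gene with an instrument"
a coin flip rather than a study condition; h² ≥ 0.3 gives λ ≥ 7.1 and ≥ 95%
instrument discovery, i.e. lead-eQTL effect sizes typical of variants
actually detectable at donor scale; (ii) the standardized outcome effect for
expression-independent architectures is γ = 0.02, giving λ ≈ 8.5 at the
overall GWAS scale — a clearly detectable hit. The cross-tissue table gives
a seeded subset of tissues (default 60% of 54) the instrument's eQTL
noncentrality and draws the rest from the null.

**What the generator does not emulate.** Sample overlap between exposure and
outcome studies; correlation between cell-state profiles of the same gene
(each profile is an independent draw of the same architecture); fine-scale
recombination structure, allele-frequency/effect-size coupling, and
population stratification; case-control ascertainment beyond the effective-n
approximation; more than one causal variant per trait per region except
through the explicit multi-signal construction used in tests. Passing tests
therefore establish the *internal correctness and calibration* of the
pipeline under its own statistical model — not robustness to pleiotropy,
weak-instrument winner's curse at marginal h², LD-reference mismatch, or the
other failure modes real applications face.

## Numerical choices

- Two-sided normal p-values are clipped at 10⁻³²⁰ rather than underflowing
  to an invalid exact zero.
- On file read, a stated p-value inconsistent with |β/se| by more than 10%
  relative (both away from the underflow region) drops the row to an audit
  log; stated p outside (0,1] is recomputed and flagged.
- Cholesky factors of panel correlation matrices add escalating jitter
  (from 10⁻¹⁰); conditioning systems add a 10⁻⁸ ridge, and a SNP whose
  residual variance after conditioning is ≤ 10⁻⁶ is dropped as collinear
  (this uniformly handles conditioning a SNP on itself).
- H3's sum S₁S₂ − S₁₂ is computed as a log-space difference; with one SNP it
  is exactly zero (H3 impossible).
- TSVs are written with shortest-round-trip float formatting and read with
  round-trip float parsing, so a pipeline run from disk is byte-identical to
  the in-memory run — this is what makes the determinism guarantees exact.
- Clumping and stepwise selection break p ties by genomic position;
  selection caps at 10 signals per trait per region.

## Problem sizes used in verification

The acceptance script and test suite run the analysis at reduced but
representative scale, chosen so the whole verification is a desk-scale
computation: oracle equivalence on 100 coloc regions (≤ 20 SNPs), 1,000
clumping regions (≤ 100 SNPs), 1,000 BH vectors (length ≤ 2,000), and 50
individual-level conditioning simulations (n = 2,000, 20 SNPs); Wald
recovery and coverage on 500 causal-gene replicates of a 200-SNP region at
n_exp = 119 and the full GWAS case/control sizes; colocalisation
discrimination on 200 shared-variant and 200 distinct-variant replicates;
and end-to-end error control on 50 all-null plus 50 causal-gene studies of
50 genes each (100-SNP regions, one profile per gene). Region SNP counts
scale the LD panel, not the statistical model; the per-SNP priors are kept
at their window calibration throughout.

## Known limitations

- The conditional analysis is z-space-standardized; with strong effects and
  allele-frequency-dependent variance differences it deviates from the full
  genotype-variance-weighted formulation (the joint-OLS check bounds the
  deviation at |Δz| < 0.05 under the tested conditions).
- Single-instrument Wald ratios only: no IVW/Egger/weighted-median
  estimators, no reverse-direction MR.
- The F statistic uses the single-SNP z² approximation.
- Colocalisation assumes at most one causal variant per conditioned dataset;
  dense multi-signal regions (e.g. the MHC) are decomposed but not given any
  region-specific LD treatment.
- The tissue lookup is a significance lookup, not a formal multi-tissue
  colocalisation or mediation analysis.
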