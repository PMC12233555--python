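# Methods

`cismr` implements a proteome-wide two-sample *cis* Mendelian-randomization
(MR) and colocalization workflow for GWAS summary statistics, together with
a synthetic summary-statistics generator that provides ground truth for
every stage. This note records the statistical model, the defaults and why
they were chosen, the numerical choices, and what the synthetic experiments
do and do not demonstrate.

## The analysis model

**Instruments.** For each protein assay, the instrument is the lead *cis*
variant: the variant with the smallest association p-value among those that
(i) lie outside the MHC region (chr 6, 26–34 Mb, inclusive) and do not
instrument an MHC-overlapping gene, (ii) have a single-variant F-statistic
(β/se)² ≥ 10, (iii) are present in the outcome GWAS, and (iv) are
genome-wide significant within the platform's *cis* window. Platform
conventions differ and are kept: an Olink-style catalogue uses
p < 3.40×10⁻¹¹ with the window anchored on the gene body ±1 Mb; a
SomaScan-style catalogue uses p < 1.80×10⁻⁹ anchored on the TSS ±1 Mb. Only
autosomes are analysed. When several assays on one platform target the same
protein (UniProt identity), the assay whose lead has the smallest p-value is
kept; ties are broken by position, then variant id, for determinism.

**Harmonization.** Outcome records are re-oriented onto the exposure's
effect allele: direct match, allele swap (β → −β, EAF → 1−EAF), strand flip
(A↔T, C↔G), or both. Palindromic variants (A/T, C/G) carry no strand
information in their allele labels; they are dropped when either study's
EAF lies strictly inside the ambiguity window (0.42, 0.58) or is missing,
and otherwise oriented purely by frequency-side agreement (both EAFs on the
same side of 0.5 ⇒ already aligned). The window is applied to **both**
traits' frequencies and is an open interval (boundary values are retained):
the published description does not fix boundary semantics or sidedness, the
open/both-sided reading retains more data while still protecting against
mismatch, and both choices are config-exposed. Harmonization is an
involution: re-harmonizing an aligned pair is a no-op (property-tested).

**Wald ratio.** The single-variant causal estimate is
β_MR = β_out / β_exp with first-order delta-method standard error
se_out / |β_exp| (the default of the standard two-sample MR toolchain); the
second-order form √(se_out²/β_exp² + β_out²·se_exp²/β_exp⁴) is available by
flag. For binary outcomes β_MR is a log-odds ratio and the CI is
exponentiated for reporting. P-values come from the two-sided normal
reference computed in log space (`log Φ̄`), so |z| beyond the double-precision
underflow point (~38) still yields an exact log₁₀ p; the linear-scale p is
clamped to the smallest positive double to keep it in (0, 1].

**Multiplicity.** Benjamini–Hochberg at 5% FDR, one correction per test
family (the protein–disease screen is a single family pooling platforms and
outcomes; expression and imaging screens are corrected separately). The
reported cutoff is k·α/m for the largest passing rank. The genomic inflation
factor λ is the median of χ²₁ quantile-transformed statistics divided by the
χ²₁ median (0.45494).

**Reverse causation.** Genetic liability to the outcome is modelled by
approximately independent genome-wide-significant variants obtained by
greedy clumping (p ≤ 5×10⁻⁸, 1 Mb window, pairwise r² < 0.001 in the
supplied LD panel; the unusual published phrasing "r² < 0.1%" is read as
0.001 — the value is config-exposed, and the 0.1 reading is exercised in
tests as well). Per-variant outcome→exposure Wald ratios are pooled with a
multiplicative random-effects IVW: weights 1/se², Cochran's Q, and SE
inflation √(max(1, Q/(k−1))) — homogeneous inputs are never inflated.

**Colocalization.** Single-causal-variant Bayesian colocalization from
per-variant Wakefield approximate Bayes factors,
log ABF = ½[log(V/(V+W)) + z²·W/(V+W)], with V = se² and prior effect
variance W = 0.2² for quantitative traits and 0.15² (log-odds) for binary
traits — the conventional defaults of the widely used implementation, since
the source analysis names the package but not the priors. Per-variant
causal priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵. Hypothesis masses are
H0 = 1, H1 = p1·ΣL1, H2 = p2·ΣL2, H3 = p1p2(ΣL1·ΣL2 − ΣL1ᵢL2ᵢ),
H4 = p12·ΣL1ᵢL2ᵢ, accumulated in log space (log-sum-exp; the H3 difference
via log1p, exactly zero for a single-variant locus). PP4 > 0.80 is strong,
0.60 < PP4 ≤ 0.80 moderate; boundary values classify downward per the
strict-inequality wording. The locus is the lead variant ±1 Mb, intersected
on shared variant ids and fully allele-harmonized. Loci are colocalized
only for MR-significant pairs, mirroring the source design (a
`coloc_all` flag lifts this). Evidence tiers require **strong**
colocalization; moderate support does not feed the tiers (the published
tier definitions mention only the strong threshold).

**Evidence tiers.** Among pairs with an MR-significant, strongly
colocalizing plasma pQTL: Category 1 adds the same from a brain-region
eQTL, Category 2 from a plasma eQTL, Category 3 is pQTL-only.
Cross-platform deduplication keys on (protein, outcome). Novelty is
assessed against a user-supplied known-loci list (offline replacement for a
live catalogue query, whose versions drift); the packaged per-platform
tables carry a transcribed novelty column so the published count is
reproducible without network access.

## The synthetic generator

Marginal z-scores for a locus are drawn from the standard multivariate
normal model under LD: z ~ MVN(√n_eff·R·λ, R), with R an AR(1) correlation
matrix (r = ρ^|i−j|), λ the standardized joint (causal) effects, and
n_eff = n for quantitative traits, n·φ(1−φ) for binary traits analysed on
the log-odds scale with case fraction φ. Betas/SEs are placed on the
per-allele scale by dividing by √(2f(1−f)), with f ~ U(0.05, 0.95) drawn
once per variant and shared between cohorts (same-ancestry assumption).
5% of variants receive palindromic allele pairs to exercise harmonization.
Everything is deterministic given the scenario seed; exposure and outcome
noise are independent (non-overlapping two-sample cohorts).

Reference conditions (used by all calibration experiments): 200-variant
locus, ρ = 0.9; exposure n = 35,000 (quantitative, λ_exp = 0.15, causal
z ≈ 28); outcome n = 50,000 with 20% cases; true causal effect θ = 0.3, so
the shared variant's outcome effect is θ·λ_exp = 0.045 (causal z ≈ 4.0).

Architectures: `shared` (one variant drives both traits), `distinct`
(different causal variants — confounding by LD), `null_outcome`,
`null_both`, and `reverse` (the outcome is causal and induces an exposure
effect θ·λ_out at its variant). For `distinct` and `reverse` the outcome's
own causal effect defaults to λ_exp on its trait's standardized scale
(z ≈ 13): a distinct disease locus must be a genuine association for
LD-confounding to arise at all — with a θ-scaled whisper of an effect the
screen would rarely flag the pair and colocalization would see only the
exposure signal, which is neither the phenomenon nor a useful test of it.
The forward causal effect recorded in the truth table is 0 for these kinds.

**What the generator does not emulate:** realistic MAF spectra or selection,
liability-scale case-control subtleties beyond the 1/(nφ(1−φ)) variance
approximation, sample overlap between cohorts, cross-ancestry frequency
differences, haplotype-level LD beyond AR(1), or trans effects. Passing
calibration here shows the estimators are correct under the model MR and
colocalization themselves assume — not that real-data violations of those
assumptions are handled.

## Calibration results the experiments compute

(Recomputed by `tests/test_acceptance.py` and `scripts/acceptance.py`; the
numbers below are the quantities those runs produce, not independent claims.)

- **Recovery** (500 shared replicates): mean Wald estimate within 2 Monte-
  Carlo SEs of θ; 95% CI coverage within [0.93, 0.97].
- **Discrimination:** colocalization is applied where the pipeline applies
  it — to screen discoveries. Among truly shared loci passing the screen's
  published significance cutoff (6.3×10⁻⁴, recomputed from the packaged
  family counts), PP4 > 0.8 in ≥ 90% of replicates. Unconditionally the
  rate is ≈ 0.7: at the reference setting the outcome's causal z ≈ 4 sits
  near the evidence threshold, and loci whose outcome draw lands low are
  exactly those the screen would not forward to colocalization. Both rates
  are reported.
- **Confounding by LD** (distinct variants, r ≈ 0.66): the Wald screen
  flags essentially all such pairs while PP3 is the modal hypothesis in
  essentially all — the failure mode colocalization exists to catch.
- **Null calibration:** Wald p-values uniform (KS), type-I rate ≈ 5%
  within binomial error, λ ≈ 1 ± 0.05.

## Numerical and degenerate-input choices

- Duplicate variant ids within one sumstats file: keep the smallest-p row,
  log the collision. Rows with missing alleles/β/se, non-positive se, or
  p ∉ (0,1] are skipped and counted per reason; file reads report
  rows read = kept + skipped.
- Clumping ties in p are broken by (position, variant id); the result is
  invariant to input row order. Cross-chromosome pairs are never clumped.
- Empty instrument sets, empty screens, and zero-discovery BH runs produce
  empty but well-formed outputs (cutoff 0, no flags), not errors; an empty
  coloc intersection is an error, as there is nothing to colocalize.
- β_exp = 0 makes the Wald ratio undefined and raises; IVW of zero ratios
  raises.
- LD panels validate symmetry, unit diagonal, and entry range on
  construction. AR(1) panels are positive definite for ρ ∈ [0, 1), so the
  Cholesky factorization used for simulation always exists; it is computed
  once and reused across replicates.
- Monte-Carlo problem sizes in the test-suite experiments (500 recovery
  replicates, 300 discrimination replicates, 10,000 null tests on
  25-variant loci) were chosen so Monte-Carlo error is small relative to
  each acceptance band while the whole suite runs in seconds on one CPU.

## Known limitations

- Single-causal-variant colocalization only; no SuSiE-style multi-signal
  decomposition, no conditional analysis.
- No pleiotropy-robust MR estimators (Egger, weighted median): the primary
  design is single-variant *cis* MR, where they are not identified.
- One genome build assumed throughout; no liftover, no proxy-variant search
  for instruments missing from the outcome GWAS.
- Novelty flags are only as good as the supplied known-loci list.
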