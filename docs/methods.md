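# Methods

## The model

Two-sample summary-data Mendelian randomization treats genetic variants
as instruments for an exposure. For variant j, let (β_Xj, se_Xj) be its
estimated per-SD effect on the exposure in one GWAS and (β_Yj, se_Yj)
its effect on the outcome in an independent GWAS. Under the three
instrumental-variable assumptions — relevance (the variant is robustly
associated with the exposure), exchangeability (independent of
confounders), and exclusion restriction (no effect on the outcome
except through the exposure) — each Wald ratio r_j = β_Yj/β_Xj
estimates the same causal effect θ. These assumptions are contracts on
the input data, not checkable code; the diagnostics below probe their
observable footprints (heterogeneity, directional pleiotropy,
single-variant leverage).

The package's estimators and conventions:

- **IVW.** Weighted least squares of β_Y on β_X through the origin with
  w_j = 1/se²_Yj. This is the classical inverse-variance-weighted
  meta-analysis of the Wald ratios. The *multiplicative random-effects*
  variant (the primary analysis) scales the fixed-effect SE by
  max(1, √(Q/(J−1))), where Q = Σ w_j (β_Yj − β̂ β_Xj)² is the weighted
  residual sum. The floor at 1 makes RE reduce to FE under homogeneity
  and guarantees se_RE ≥ se_FE. P-values are two-sided normal. The
  "random-effects model" could also have been additive
  (DerSimonian–Laird); the multiplicative form is the standard
  convention in the summary-data MR literature and was chosen for its
  exact reduction to FE under homogeneity.
- **MR-Egger.** The same weighted regression with a free intercept,
  after orienting every variant so β_Xj > 0 (negating both betas where
  needed — the intercept is only identified up to this orientation).
  The slope is a pleiotropy-robust causal estimate under the InSIDE
  assumption (pleiotropic effects independent of instrument strength);
  the intercept estimates mean directional pleiotropy. Both SEs carry
  the multiplicative floor with J−2 degrees of freedom; p-values use
  t(J−2) because two parameters are estimated from J points. The WLS
  solve itself is delegated to statsmodels; the scale-floor and
  orientation policy are applied on top.
- **Weighted median.** Sort the Wald ratios; with normalized weights
  w_j = 1/ratio-se²_j (ratio-se_j = se_Yj/|β_Xj|, see below), define
  the cumulative midpoint mass s_j = Σ_{k≤j} w_k − w_j/2 and linearly
  interpolate r against s at s = 0.5. The estimator is consistent when
  instruments carrying more than half of the total weight are valid.
  No closed-form SE exists; a parametric bootstrap (redraw β_Xj, β_Yj
  from normals at the observed values with their SEs, default 5000
  replicates, seeded generator) supplies it, with a two-sided normal
  p-value.
- **Wald-ratio SE.** First order: ratio-se_j = se_Yj/|β_Xj|, ignoring
  exposure-side noise. Instruments pass F = (β_Xj/se_Xj)² > 10, so the
  neglected second-order term inflates the SE by
  √(1 + (r_j · se_Xj/se_Yj)²) ≤ 5% across the regimes the tests cover.
  This choice also makes the ratio-form Cochran Q *identical* to the
  regression residual sum driving the IVW-RE inflation:
  v_j (r_j − β̂)² = w_j (β_Yj − β̂ β_Xj)² with v_j = β²_Xj/se²_Yj.
- **Confidence intervals** use the normal multiplier 1.959964
  everywhere (including the Egger slope/intercept, whose *p*-values are
  t-based; the printed CI is the conventional normal one).
- **Odds-ratio scale.** For binary outcomes all linear-scale fields are
  log-odds; estimates and CI bounds are exponentiated into OR columns,
  never the SEs.

## Instrument selection

Three filters in a fixed order, all strict inequalities: p < 5×10⁻⁸;
LD clumping; F > 10. Clumping builds a conflict graph — an edge when
two variants share a chromosome, lie within 10,000 kb (inclusive,
centre-to-centre), and have r² > 0.001 — and greedily deletes the
maximum-degree vertex until no edges remain. Ties are broken by larger
p-value, then by lexicographically larger variant ID; the result is a
deterministic, order-independent retained set, verified in tests
against an independent re-statement of the rule on exhaustive 3-node
and random 20-node graphs. F is the per-variant summary-data
approximation (β/se)², applied per SNP (not as a mean across
instruments). An empty set after any stage is a hard error naming the
stage.

## Harmonization

Join strictly on variant ID. Outcome rows are rewritten onto the
exposure's effect allele: label swaps negate β and complement the
allele frequency; non-palindromic pairs matching only under strand
complement are relabelled first. Palindromic pairs (A/T, C/G) carry no
strand information in their labels; the default policy infers
orientation from allele frequencies when both are present and both
minor-allele frequencies are below 0.42 (discordant minor alleles ⇒
strand flip), and drops the variant otherwise; a `drop` mode discards
all palindromic variants. The 0.42 threshold is the field's customary
default for "frequency close enough to 0.5 to be uninformative".
Exposure rows with β_X = 0 are dropped rather than divided by. Every
joined row ends as exactly one audit entry (kept with its action, or
dropped with one reason), and the whole pipeline is exactly invariant —
bit-for-bit in every estimate — to swapping allele orientation on any
subset of outcome rows.

## The synthetic-data generator

`tsmr.simulate` emulates the data regime of a large food-intake
exposure GWAS meta-analysed against consortium disease/biomarker
GWASs. Per variant: minor-allele frequency p_j ~ Uniform(maf_range);
standardized-trait standard errors se = 1/√(2p(1−p)n); observed
β_Xj ~ N(γ_j, se²_Xj) and β_Yj ~ N(θγ_j + α_j, se²_Yj); two-sided
normal p-values. Defaults are the emulated study's conditions and are
not tuning knobs:

- J = 65 variants, exposure n = 451,486, outcome n = 218,792 (the
  UK-Biobank-scale exposure and a FinnGen-scale outcome).
- γ_j ~ N(0.035, 0.003), maf ∈ (0.10, 0.40): chosen so that *every*
  instrument reaches genome-wide significance with F > 10 (per-SNP
  failure probability ≈ 3×10⁻⁴) — the selection outcome the emulated
  study reports. The true per-SNP effect distribution of a real intake
  GWAS is unknown; these values reproduce its observable consequence
  (65/65 significant, all F ≫ 10), not its latent parameters.
- Pleiotropy: a configurable fraction of instruments receives
  α_j ~ N(mean, sd); `balanced` mode forces mean = 0 (InSIDE holds),
  `directional` uses the configured mean. Valid instruments have
  α_j = 0 exactly.
- Alleles: a configurable fraction of variants gets palindromic A/T or
  C/G pairs (frequencies away from 0.5 so inference is exercised; an
  `ambiguous_palindromes` flag pushes them toward 0.5 to exercise the
  drop path); `allele_scramble_fraction` emits exactly round(f·J)
  outcome rows with swapped alleles, negated β and complemented eaf.
- LD: block-diagonal r², one chromosome, blocks separated by 20,000 kb
  (beyond the clumping window) so clumping behaviour is governed purely
  by r²; within-block r² ~ Uniform(within_block_r2_range); default is
  one variant per block (independent instruments, the post-clumping
  regime of the emulated study).

What the generator deliberately does *not* emulate: realistic LD from
reference panels, sample overlap between the two GWASs, indels or
multi-allelic sites, population stratification, or winner's-curse
selection of instruments. Passing calibration here therefore
demonstrates the estimators and plumbing are correct under the stated
sampling model, not that any real-data finding is confirmed.

## Calibration scenarios (tests and the reproduction script)

Problem sizes were chosen to give stable Monte-Carlo bands at a few
seconds' runtime each.

- **IVW coverage**: θ = −0.43, J = 65, no pleiotropy, 1000 replicates;
  the 95% RE interval covers θ in 93–97% (weak-instrument attenuation
  is ≈0.4% of θ here, well inside the interval).
- **Egger intercept level**: balanced pleiotropy on *all* instruments
  with σ_α = 0.002, θ = 0, 2000 replicates. σ_α is kept below the
  smallest outcome SE so the pleiotropy variance is a mild, nearly
  proportional inflation — the regime where the multiplicative
  overdispersion model is well specified and the t-test should hold
  its 5% level (band 3–7%). Larger σ_α would make the additive
  pleiotropy variance visibly heteroscedastic under 1/se²_Y weights and
  test the model's misspecification instead of its level.
- **Egger intercept recovery**: directional α with mean 0.02
  (sd 0.005) on all instruments, 1000 replicates; mean intercept within
  3 MC SEs of 0.02.
- **Weighted-median robustness**: θ = 0.5 with 40% invalid instruments
  carrying directional α ~ N(0.05, 0.01) — pleiotropy of the same
  order as θ·γ, i.e. "large"; over 500 replicates the absolute mean
  bias of the weighted median must beat IVW's.
- **Cochran's Q null**: θ = 0, no pleiotropy, J = 30, 1000 replicates.
  θ = 0 is used because it is the *exact* χ²(J−1) null: for θ ≠ 0 the
  first-order ratio pivot is genuinely over-dispersed by
  θ²se²_X/se²_Y (exposure noise), a property of the statistic rather
  than an implementation artefact.
- **Family-wise error**: 10 null outcomes per replicate study, 200
  replicates; the rate of ≥1 "significant" tier stays at or below the
  nominal family-wise α.

## Reporting conventions

Bonferroni thresholds are exact quotients α/m per outcome family
(display rounded to 4 decimals: 0.05/10 = 0.005, 0.05/12 → 0.0042);
tiers are half-open: significant iff p < α/m, suggestive iff
α/m ≤ p < α, else null, keyed to the IVW-RE p-value only. Instruments
are selected once per exposure and reused for every outcome; outcome
results are therefore mutually independent, and per-outcome attrition
happens only at harmonization (reports always carry per-outcome nsnp).
P-values are floored at the smallest positive double so they remain in
(0, 1]. Numbers round-trip through the TSV writers at 17 significant
digits, making write→read an exact identity and the study report
byte-reproducible for a fixed seed.

## Known limitations

Single-SNP analyses fall back to the Wald ratio (IVW requires J ≥ 2;
Egger, the weighted median and leave-one-out require J ≥ 3). The Egger
slope is weakly identified when per-SNP exposure effects span a narrow
range (as in the worked example) — expected, and the reason it is a
sensitivity analysis. No proxy-SNP search, reference-panel LD, GWAS-VCF
parsing, liftover, MR-PRESSO/mode-based/multivariable estimators, or
reverse-direction analyses are provided.
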