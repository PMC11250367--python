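# Methods

## Screen data model

A screen is a variants x samples integer count matrix. Samples are keyed
by target region, template library (A or B — two independent editing
experiments per region with different synonymous PAM/protospacer
protection edits, PPEs), replicate (1–3) and collection day (plasmid
library, or day 4/7/10/14/21 after transfection). Days map to the
continuous times 0, 3, 6, 10 and 17 used in the regression, so the slope
is a rate per day anchored at the first genomic timepoint. Two special
rows per region carry reads matching the unedited wild-type sequence
(`ref_seq_<region>`) and the PPE-only edited sequence
(`pam_seq_<region>`); their fractions of total mapped reads are the
editing-efficiency summary.

Template counting is full-length exact matching of trimmed reads against
the designed template library: any read containing `N` or differing at
one or more positions is unmapped. Read trimming and sequencing QC are
out of scope; trimmed reads (or a pre-made count table) are the input.

## Filters and quality control

- **Low-count filter.** A variant is dropped from a (region, library)
  experiment when its total count across all genomic timepoint
  replicates (days 4–21; the plasmid sample does not count) is below 10.
  The filter is applied per experiment, not globally: a variant can
  survive in library B after failing in library A. The threshold is
  strict (`< 10`), so a total of exactly 10 is retained.
- **Replicate correlation.** Pearson correlation of log2(count+1)
  between replicates at each timepoint; a replicate-timepoint whose
  median pairwise correlation falls below 0.7 is flagged. The 0.7
  default is a package choice (no published numeric threshold exists);
  it is configurable. Constant replicates are flagged `degenerate`.
- **Positional editing effect.** The per-variant early log ratio
  log2((mean D4 + 0.5)/(plasmid + 0.5)) is Spearman-correlated with
  distance to the Cas9 cut site; |rho| ≥ 0.5 with p < 0.01 flags the
  library-experiment. This operationalizes "strong positional effect"
  through the stated D4-versus-plasmid comparison; both thresholds are
  configurable. Fewer than 10 positioned variants yields
  `insufficient_data` rather than a test.
- **Late wild-type fraction.** A day-14/21 sample whose unedited read
  fraction exceeds 30% (strictly) is flagged as an editing failure.

Flags are advisory by default and a strict mode applies them as
exclusions; screens historically involved per-region judgment, so the
report always records machine-readable reasons.

## Growth-rate estimation

Counts follow NB2 with a log-linear mean in time (see README). The
implementation is a vectorized IRLS fit over all variants of an
experiment simultaneously (they share one design matrix), with:

- normalization factors as fixed per-sample offsets: median-of-ratios
  over controls, reference = geometric mean across samples, controls
  with any zero count excluded from the reference set, factors rescaled
  to geometric mean 1; at least 5 usable controls are required;
- convergence when the deviance change is below 1e-8 *and* the
  coefficients move by less than 1e-10 (the deviance is quadratic near
  the optimum, so a deviance-only stop leaves coefficients at ~sqrt(tol)
  precision), with at most 100 iterations;
- Wald standard errors from the observed Fisher information,
  `I = sum_j mu_j (1 + alpha y_j) / (1 + alpha mu_j)^2 x_j x_j'`;
- no pseudocounts in model fitting (the NB likelihood handles zeros);
  the +0.5 appears only in QC log ratios;
- natural-log internals, converted to log2 at the interface so the slope
  is the screen's log2-per-day fold change.

**Dispersion.** Per-variant `alpha_v` maximizes the Cox–Reid adjusted
profile log-likelihood (penalty −0.5 log det X'WX, W = mu/(1+alpha mu))
at fixed fitted means, bracketed from a method-of-moments estimate and
optimized by a coarse grid plus golden-section refinement, floored at
1e-8 for under-dispersed data. Means and dispersion are iterated once
(Poisson means → alpha → NB means → alpha). An optional moderation step
fits the parametric trend `alpha(mu) = a0 + a1/mu` across variants by
trimmed least squares and re-estimates each variant as the MAP under a
log-normal prior (sd 0.5) centered on the trend. Moderation is **off by
default**: the classification z-test consumes raw per-variant estimates
and standard errors, and no shrinkage is applied to the slopes either.

**Pairwise LFC.** The same NB machinery with a two-level day factor
yields the D4-versus-later-day log2 fold changes; the two-group fit is
saturated, so it equals the closed-form log2 ratio of normalized means.

## Combination and classification

Per (region, library), the median control slope is subtracted from every
slope (so control medians are exactly 0). Per variant, estimates are
combined by fixed-effect inverse-variance weighting — A/B within region,
then across overlapping regions; the weighting is associative, so the
staged result equals pooling all sources. PPE-codon variants seen by
only one library are excluded (their counts reflect the
library-specific protection edit); variants from single-library regions
pass through flagged `single_library`. Exclusion happens before the
z-test, and Benjamini–Hochberg FDR is computed once across all remaining
unique variants (never per region). Two-tailed p-values use the normal
survival function for stability at |z| > 8. A zero score below the FDR
threshold (a measure-zero event) stays `unchanged`.

## Clinical calibration

ROC analysis orients scores so that *lower predicts pathogenic*
(predict pathogenic iff score ≤ threshold). AUC uses the rank
(Mann–Whitney) formulation with tie correction; the reported threshold
maximizes Youden's J with ties broken toward the lower (more
conservative) score; PR AUC is the step-interpolated precision-recall
area.

Evidence tables count depleted versus unchanged/enriched readouts for
pathogenic and benign truth variants. Likelihood ratios use a
conservative +1 correction on the opposing class's discordant count:

```
LR_path = (a/(a+b)) / ((c+1)/(c+d))      LR_ben = (d/(c+d)) / ((b+1)/(a+b))
```

so a zero discordant cell cannot produce an infinite ratio; raw
uncorrected ratios are reported alongside. Reported values are rounded
half-up to one decimal. Evidence strengths use the published
odds-of-pathogenicity calibration constants (2.08 / 4.33 / 18.7 / 350),
stored as named configuration. Depleted variants are split into
strongly/weakly depleted about the median depleted score, scores equal
to the median going to the strong side.

`compare_groups` is a thin facade over the standard two-sided tests used
around screen results (Mann–Whitney, Kruskal–Wallis with Dunn's
BH-adjusted post hoc comparisons, chi-square without continuity
correction, Spearman/Pearson). Dunn's test is implemented here (rank z
statistics with tie correction) since no post hoc package is assumed.

## Synthetic screens

The generator emulates the statistical structure the scoring assumes:
latent abundance `a_v * 2^(beta_v t)` with log-normal initial
representation (sigma 0.5 natural-log units — plausible oligo-synthesis
unevenness), renormalized to per-sample read fractions, NB2 observation
noise (default alpha 0.05), expected depth 500 reads per variant,
constant unedited (1%, matching the optimized-protocol regime) and
PPE-only (3%) read fractions, one plasmid library sample per
(region, library), triplicates at days 4–21, and independent initial
abundances per library/region (independent transfections). Default
class effects: loss-of-function −0.13 log2/day (the typical depleted
magnitude in an essential gene), hypomorphic −0.06, neutral 0. Variant
identities are drawn collision-free from each 245-bp region's possible
SNVs (three alts per base) and codon deletions; a region cannot hold
more variants than its sequence supports.

What the generator does **not** model: cell-population bottlenecks and
drift (depletion is deterministic decay plus observation noise),
positional editing artifacts, sequencing error, library
cross-contamination, or between-replicate batch effects. Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness to every
real-data pathology — the QC module exists precisely because real
screens violate these assumptions in flagged, excludable ways.

## Numerical and design notes

- Problem sizes in the test suite (two regions x 500 variants for
  recovery; ten regions x 500 for the all-neutral calibration screen)
  keep full-pipeline runs in seconds while leaving >=1,000 variants per
  estimate; the vectorized IRLS makes cost linear in variants.
- Per-variant Wald z at 15 samples is slightly heavy-tailed (t-like, sd
  ~1.1 for neutral variants). Consequences: the empirical fraction of
  false calls on an all-neutral screen stays well under 2%, but single
  extreme-null crossings of the BH boundary can occur; dispersion
  moderation reduces this at the cost of non-raw estimates.
- Exact sample-scaling invariance of the slope holds for saturated fits;
  in overdetermined designs a scaled sample also carries more likelihood
  weight, shifting slopes O(1/depth).
- Ties and degenerate inputs: constant replicate vectors flag as
  `degenerate`; all-zero variants carry no growth information and are
  reported absent with reason; Youden ties resolve to the lower
  threshold; BH is computed with the step-up algorithm via scipy.

## Limitations

- Truth sets are inputs; ClinVar/gnomAD curation is out of scope.
- The +1-corrected likelihood-ratio formula is validated against the
  four published table values; it is a conservative zero-cell handling
  generalized to all tables, not a claim about the original authors'
  derivation beyond those values.
- No empirical-Bayes LFC shrinkage, outlier replacement or independent
  filtering: the functional score is defined as raw estimate over
  standard error.
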