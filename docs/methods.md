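# Methods

This note documents the models implemented in `xenoquant`, the
assumptions behind them, the defaults of the synthetic-data generator,
and the numerical conventions used throughout.

## The measurement chain

A xenografted larva yields one DNA extract that must answer two
questions: what is the host's *ache* genotype, and how much human tumor
DNA does the larva carry?  Three primer pairs are run in duplicate on
each sample — mutant-specific *ache* N, wild-type-specific *ache* S, and
AluYb8, which targets a young, primate-specific Alu subfamily abundant
enough in the human genome to act as a sensitive human-DNA marker in a
zebrafish background.

### Genotype calling

The allele-specific primers amplify their non-target allele late, so the
replicate-averaged difference Δ = Ct(N) − Ct(S) separates genotypes.
Wild-type homozygotes sit near Δ = +9.85 cycles (SD 1.07), mutant
homozygotes near −5.65 (SD 0.64), heterozygotes near 0.  The caller uses
two windows, both configurable: |Δ| ≤ 1 cycle is heterozygous, |Δ| ≥ 4
homozygous with the sign giving the allele, and the open band (1, 4) is
unclassified.  Boundary values are assigned to the classified side; with
class centers at 0 and beyond ±5.6, a reading *exactly* on a boundary is
far more consistent with the adjacent class than with the dead band, and
the dead band exists to absorb ambiguity, not to swallow decisive
readings.  When exactly one allele amplifies, the detected allele's
homozygote is called and flagged `single_allele_call`, because a total
primer failure is indistinguishable from allele absence; the flag keeps
such calls auditable and excludable.

### Copy-number correction and load

AluYb8 signal is normalized against the host *ache* locus by ΔCt.  A
homozygote presents two template copies to its primary primer while a
heterozygote presents one per primer; at perfect doubling chemistry one
cycle equals a 2-fold template difference, so the homozygote's primary
Ct gets +1 and the heterozygote uses the mean of its two allele Ct
values.  The corrected reference and load are

    load_dct = ct_ref_adjusted − ct_alu.

The sign convention (host minus human, larger = more human DNA) is a
single configuration point recorded in every output's metadata, chosen
so that the quantity reads as a *burden*.  The correction is applied to
replicate-averaged Ct values; correcting before averaging would give the
same result for complete duplicates and a noisier one when a replicate
drops out.

### Standard curve

Ct is regressed on log10(human DNA, pg) over the detected points of a
dilution series (ten-fold steps, 10 ng → 0.01 pg).  Efficiency is
10^(−1/slope) − 1; a slope of −1/log10(2) ≈ −3.3219 cycles/decade is
exact doubling.  The limit of detection is defined empirically — the
smallest input amount whose Ct lies under the 35-cycle non-detect
cutoff — rather than by a parametric LOD model, because the assay's
floor is set by Alu-primer cross-reactivity with host DNA (Ct > 35),
not by Poisson sampling of the template.  Fits need at least three
detected points spanning two decades; a non-negative slope is returned
flagged invalid instead of raising, so screening code can inspect it.

### Quality control

DNA extracts fail QC when A260/A230 ≤ 0.6 or concentration
< 30 ng/µl; A260/A280 is recorded but deliberately not filtered on.
Wells whose melting peaks all fall outside the expected amplicon Tm ±
tolerance (default 1.5 °C) amplified only primer dimer and are excluded;
a dimer peak *alongside* an in-window peak is acceptable, since the Alu
reaction is known to produce double melting peaks.  Missing melt data
produces a warning, never a silent exclusion.  Replicate pairs in which
one well is numeric and the other non-detect keep the numeric value with
a `discordant` flag — no rule is imposed where the assay gives no basis
for one, but the case is never hidden.

### Imaging

Tumor area is measured two ways, mirroring bench practice: automatic
threshold segmentation (Otsu within the yolk ROI by default, fixed
threshold optional) counting all foreground pixels of connected
components that intersect the ROI, and manual polygon tracing evaluated
with the shoelace formula; downstream analysis uses their mean.
Dispersed cells are connected components strictly outside the ROI with
areas inside [min_spot_area, max_spot_area] (defaults 4–400 px, gating
out single noise pixels and debris).  A larva with ≥ 5 dispersed cells
(configurable) is metastasis-positive; statuses partition into
`no_cells` / `localized` / `invaded`.  Segmentation refuses uniformly
saturated regions ("no contrast") and scores regions whose intensity
range falls below `min_contrast` (default 50 of 255) as empty rather
than Otsu-splitting pure noise.  Cohort tables report tumorigenicity %
as 100 × localized / injected with half-up rounding to one decimal; the
metastasis denominator is explicitly configurable (default: embryos with
any tumor signal) because published cohort accounting conventions are
not always recoverable, and an empty denominator yields an absent value,
never 0.

### Statistics

The statistics module wraps scipy/statsmodels with explicit contracts:
pooled-variance Student's t by default (Welch by flag) with one-tailed
p-values derived from the stated direction; one-way ANOVA + Tukey HSD
(levels with n < 2 excluded with a warning); two/three-way factorial
ANOVA with all interactions, Type II sums of squares by default because
they are order-invariant for main effects in unbalanced designs, and an
error naming the first empty design cell; 2×2 Pearson chi-square without
continuity correction unless requested; Pearson correlation that reports
zero-variance inputs as undefined.  Constant-and-equal t-test groups
return p = 1 with a `degenerate` flag.

## The synthetic-data generator

The generator emulates the statistical structure of the emulated study
and carries ground-truth labels for every embryo.  Defaults:

| parameter | default | rationale |
|---|---|---|
| genotype_probs | (0.25, 0.5, 0.25) | heterozygote in-cross Mendelian ratio |
| allele_offsets | +9.85 ± 1.07, −5.65 ± 0.64, 0 ± 0.3 | observed per-embryo ΔCt(N−S) dispersions |
| load_fold_mutant | 2.5 | within the observed up-to-3-fold mutant enlargement |
| tumor_load_median_pg / sigma | 30 pg / 0.8 (ln) | ~300 injected cells at ~6.6 pg human DNA per diploid genome leave tens of pg after early clearance; loads are positive and right-skewed, hence lognormal |
| tumor_take_prob | 0.8 | matches ~71–81% observed tumorigenicity |
| curve_slope / intercept | −3.3219 / 30 Ct at 1 pg | perfect doubling; places the last detected ten-fold step at 0.1 pg under the 35-cycle cutoff |
| ct_noise_sd | 0.25 cycles | typical SYBR duplicate scatter |
| dropout_cutoff | 35 cycles | Alu cross-reactivity floor |
| dimer_rate | 0.02 | occasional dimer-only wells, Tm drawn 8–12 °C below amplicon (no dimer Tm is specified anywhere, so a clearly out-of-window band is used) |
| metastasis_rate | 0.378 siblings / 0.066 mutants | observed positive-metastasis fractions |
| qc_fail_fraction | 0.1 | a realistic single-larva extraction failure rate |

Host-allele construction is the biophysical premise of the +1
correction made literal: at equal total host DNA a homozygote's
two-copy primary allele amplifies exactly one cycle earlier than each
single-copy heterozygote allele.  This makes the correction exactly
unbiased in simulation — which is a *design property of the generator*,
verified by the copy-number-invariance check, not evidence about real
chemistry.  The configured ΔCt SDs describe the observed dispersion of
replicate-averaged differences, so the embryo-level draw subtracts the
technical replicate-mean variance before sampling; the emitted collapsed
ΔCt then has exactly the configured SD.

Host reference Ct tracks DNA concentration at one cycle per doubling
around 20 Ct at 30 ng/µl, which is what makes the
concentration-predicts-Ct diagnostic reproduce a strong negative
correlation.

Larva images are deliberately minimal: Gaussian background
(mean 20, SD 4 on a 0–255 scale), a single 200-intensity tumor disk at
the ROI center with area proportional to true human DNA (12 px/pg), and
dispersed 180-intensity spots on a jittered grid in the tail region,
mutually separated and strictly outside the ROI.  All randomness derives
from a single config seed through named sub-streams (cohort, qPCR,
standards, per-embryo image), so every emitted table is a pure function
of (config, seed).

What the generator does **not** emulate — and what passing tests
therefore cannot show about real data: overlapping or out-of-focus
cells, autofluorescence (iridophore) artifacts, yolk-edge gradients,
uneven illumination; spatial structure in dispersal (cells ride the
circulation, they do not land on grids); plate-position or batch effects
in qPCR; inhibitor-driven efficiency loss; and any per-embryo load
variance measured in vivo — the lognormal sigma is a free parameter, so
only directions and configured effect sizes, not published p-values, are
recoverable.

## Validation problem sizes

The headline checks run at: genotype recovery n = 1000 embryos;
copy-number invariance n = 5000 (gap < 0.05 cycles); pipeline power 100
replicate cohorts of 800 embryos (mutant arm ≈ 200, as an in-cross
yields 1:3 mutant:sibling); type-I calibration 10⁴ replicate cohorts of
60 embryos — 60 keeps both arms above the t-test's minimum after
engraftment and QC attrition; image metrics on 500 rendered larvae.

## Known limitations

- Genotype calls assume the two allele-specific reactions ran on the
  same extract under the same conditions; cross-plate Δ values are not
  corrected for plate effects.
- The empirical LOD is resolution-limited by the dilution grid: a true
  detection floor between two steps reports as the upper step.
- Segmentation is single-channel; colocalization-based artifact
  rejection is out of scope.
- `est_human_dna_pg` extrapolates the standard curve beyond its fitted
  range without warning other than the `below_lod` flag.
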