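# xenoquant

Quantitative analysis for genotyped zebrafish liver-cancer xenografts.

Human cancer cells injected into the yolk sac of zebrafish embryos form
tumors whose burden depends on the host genotype — here, loss of
acetylcholinesterase (*ache*) function.  Because each larva must be both
genotyped and assayed for human tumor DNA from one tiny DNA extract, the
measurement chain is unusually intertwined: allele-specific qPCR primers
genotype the embryo, the same host locus serves as the normalizer for an
AluYb8-repeat assay that quantifies human DNA, and fluorescence images
provide an independent tumor-size and metastasis readout.  `xenoquant`
implements this chain end to end, together with the group-comparison
statistics and a ground-truthed synthetic-cohort generator used to
validate every step.

## What it computes

**Genotype from allele-specific Ct.**  With mutant-specific (N) and
wild-type-specific (S) primers, Δ = Ct(N) − Ct(S) calls the genotype:

    |Δ| ≤ 1        → heterozygote
    Δ ≥ 4          → wild-type homozygote
    Δ ≤ −4         → mutant homozygote
    1 < |Δ| < 4    → unclassified

**Copy-number-corrected human-DNA load.**  Homozygotes carry two copies
of their primary allele, heterozygotes one per primer, so the reference
Ct is adjusted before ΔCt normalization of the AluYb8 signal:

    Ct_ref = Ct_primary + 1          (homozygote; +1 ≡ 2-fold)
    Ct_ref = (Ct_N + Ct_S) / 2       (heterozygote)
    load_dct = Ct_ref − Ct_Alu       (larger ⇒ more human DNA)

**Standard curve.**  Ordinary least squares of Ct on log10(human DNA, pg)
over a ten-fold dilution series, with efficiency E = 10^(−1/slope) − 1
and an empirical limit of detection (smallest detected step).
`StandardCurve` and `GenotypeCaller` are scikit-learn estimators and
compose with sklearn pipelines.

**Imaging.**  Otsu/fixed-threshold segmentation of the yolk tumor,
shoelace polygon areas for manual tracing, dispersed-cell counting
outside the yolk ROI, and the ≥5-cell metastasis rule; cohorts are
tabulated into tumorigenicity/metastasis percentage tables.

**Statistics.**  Student's t (one- or two-tailed), one-way ANOVA + Tukey
HSD, two/three-way factorial ANOVA (Type II), 2×2 chi-square, Pearson
correlation — each with explicit degenerate-input contracts.

## Worked example

Simulate a 200-embryo cohort from a heterozygote in-cross (2.5-fold
mutant load enlargement), run QC, genotype, fit the standard curve and
test the mutant-vs-sibling load difference:

```python
from xenoquant import (SimConfig, simulate_cohort, simulate_qpcr,
                       simulate_standards, collapse_replicates,
                       genotype_cohort, fit_standard_curve,
                       tumor_load_table, filter_usable_wells, QcConfig,
                       stats, WT_HOM, HET, MUT_HOM)

cfg = SimConfig(n_embryos=200, seed=7)
truths, samples, _ = simulate_cohort(cfg)
wells = filter_usable_wells(simulate_qpcr(truths, cfg),
                            QcConfig(amplicon_tm=84.0))
collapsed = collapse_replicates(wells)
calls, summary = genotype_cohort(collapsed)
fit = fit_standard_curve(simulate_standards(cfg, noise_sd=0.0))
loads = tumor_load_table(collapsed, calls, curve=fit)

ok = loads["load_dct"].notna()
mut = loads.loc[ok & (loads.genotype == MUT_HOM), "load_dct"]
sib = loads.loc[ok & loads.genotype.isin([WT_HOM, HET]), "load_dct"]
res = stats.t_test(mut, sib, tails="one", direction="greater")
```

This prints:

```
genotype summary: {'WT_HOM': 52, 'HET': 105, 'MUT_HOM': 43,
                   'UNCLASSIFIED': 0, 'no_amplification': 0}
curve: slope=-3.3219 eff=1.000 r=-1.000 lod=0.1 pg
mean load_dct: mutant=-3.48 (n=38), sibling=-5.26 (n=117)
one-tailed t: t=6.71, p=1.77e-10
```

The genotype counts follow the Mendelian 1:2:1 in-cross ratio; the
noise-free dilution series returns the perfect-doubling slope
(−3.3219 cycles/decade, 100% efficiency) with a 0.1 pg detection limit;
and mutant larvae carry ~1.8 cycles more normalized Alu signal
(≈ 2⁰·⁵⁴ per cycle at this slope, i.e. a multi-fold DNA excess), a
highly significant one-tailed difference.  Arm sizes are smaller than
the cohort because non-engrafting embryos (Alu below detection) and
QC-failing extracts are excluded, with flags, not silently.

There is also a CLI for file-based workflows:

```sh
xenoquant simulate --n 96 --seed 1 --out sim/
xenoquant genotype --wells sim/wells.csv --out geno.csv
xenoquant quantify --wells sim/wells.csv --genotypes geno.csv \
                   --curve sim/standards.csv --amplicon-tm 84 --out loads.csv
```

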