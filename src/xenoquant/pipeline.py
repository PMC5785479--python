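"""End-to-end simulate → QC → genotype → quantify → test runs.

Glue for the single-number questions the assay is designed to answer:
does the mutant host carry more human tumor DNA than its siblings, and
is the pipeline calibrated (type-I error at nominal level) when the
true fold difference is 1?
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .qpcr import (QcConfig, qc_filter_sample, filter_usable_wells,
                   _collapse_rows)
from .genotyping import (GenotypeWindows, genotype_cohort, WT_HOM, HET,
                         MUT_HOM)
from .quantify import tumor_load_table
from .simulate import SimConfig, simulate_cohort, simulate_qpcr
from . import stats


def run_load_pipeline(cfg: SimConfig, qc: QcConfig | None = None,
                      windows: GenotypeWindows | None = None):
    """Run the full tumor-load pipeline on one simulated cohort.

    Simulates a cohort and its qPCR plate, drops QC-failing DNA
    extracts and dimer-only wells, collapses replicates, genotypes every
    remaining embryo and computes the copy-number-corrected load.

    Returns ``(load_df, truths)`` where ``load_df`` is the per-embryo
    load table (see :func:`xenoquant.quantify.tumor_load_table`).
    """
    qc = qc or QcConfig(amplicon_tm=cfg.amplicon_tm,
                        ct_nondetect_cutoff=cfg.dropout_cutoff)
    truths, samples, _ = simulate_cohort(cfg)
    wells = simulate_qpcr(truths, cfg)

    passing = {s.sample_id for s in samples if qc_filter_sample(s, qc).passed}
    usable = [w for w in filter_usable_wells(wells, qc)
              if w.sample_id in passing]
    collapsed = _collapse_rows(usable)
    calls, _ = genotype_cohort(collapsed, windows)
    load_df = tumor_load_table(collapsed, calls)
    return load_df, truths


def load_significance(cfg: SimConfig, tails: str = "one") -> float:
    """P-value of the mutant-vs-sibling load comparison for one cohort.

    Mutant homozygotes are tested against pooled siblings (wild-type
    homozygotes plus heterozygotes, the un-genotyped "+/?" class) with a
    Student's t-test on load_dct, one-tailed for *more* human DNA in the
    mutant.  Embryos whose Alu reaction was below detection or whose
    genotype stayed unclassified are excluded, as in the analysis
    contract.  Returns NaN when either arm has fewer than two usable
    embryos.
    """
    load_df, _ = run_load_pipeline(cfg)
    ok = load_df["load_dct"].notna()
    mut = load_df.loc[ok & (load_df["genotype"] == MUT_HOM), "load_dct"]
    sib = load_df.loc[ok & load_df["genotype"].isin([WT_HOM, HET]),
                      "load_dct"]
    if len(mut) < 2 or len(sib) < 2:
        return math.nan
    res = stats.t_test(mut.to_numpy(), sib.to_numpy(), tails=tails,
                       direction="greater")
    return res.p_value


def rejection_rate(cfg: SimConfig, n_replicates: int, alpha: float,
                   seed: int) -> tuple[float, int]:
    """Fraction of replicate cohorts whose load test rejects at alpha.

    Each replicate re-runs the full pipeline under a fresh sub-seed of
    ``seed``; replicates with an undersized arm are skipped (counted
    out of the denominator).  Returns (rate, n_effective).
    """
    hits = 0
    n_eff = 0
    sub_seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    for i in range(n_replicates):
        p = load_significance(replace(cfg, seed=int(sub_seeds[i] % (2 ** 31))))
        if math.isnan(p):
            continue
        n_eff += 1
        hits += p < alpha
    return (hits / n_eff if n_eff else math.nan), n_eff
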