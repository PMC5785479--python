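"""Synthetic xenograft cohorts with ground truth.

Emulates the data-generating process of a genotyped zebrafish
xenograft experiment: embryos from a heterozygote in-cross (1:2:1
Mendelian genotypes), a lognormal human-tumor-DNA load per embryo with
a configurable fold enlargement in mutants, allele-specific host-gene
Ct values whose N−S difference carries the genotype signal, Alu Ct
values on a log-linear standard-curve model with non-detection above a
cutoff, occasional primer-dimer-only wells with out-of-window melting
peaks, DNA extracts of which a configurable fraction fails QC, and
larva images with a yolk tumor blob plus dispersed tail spots.

The host-allele construction makes the "+1" copy-number correction
exactly unbiased: at equal total host DNA a homozygote's two-copy
primary allele amplifies one cycle earlier than each single-copy
allele of a heterozygote, so primary Ct + 1 and the heterozygote
allele mean estimate the same quantity.

All randomness flows from ``SimConfig.seed``; sub-streams are derived
deterministically per operation and per embryo, so every emitted table
is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .qpcr import NON_DETECT, ACHE_N, ACHE_S, ALU_YB8, DnaSample, QpcrWell
from .genotyping import WT_HOM, HET, MUT_HOM
from .quantify import StandardCurvePoint
from .tumor import YolkRoi, MetastasisConfig, classify_embryo

# Sub-stream tags, so independent draws never share a stream.
_STREAM_COHORT = 1
_STREAM_QPCR = 2
_STREAM_IMAGE = 3
_STREAM_STANDARDS = 4


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the simulated experiment.

    Defaults encode the emulated study: Mendelian (0.25, 0.5, 0.25)
    genotype probabilities from a heterozygote in-cross; per-embryo
    ΔCt(N−S) of +9.85 ± 1.07 cycles for wild-type homozygotes,
    −5.65 ± 0.64 for mutant homozygotes and 0 ± 0.3 for heterozygotes;
    a −3.3219 cycles/decade curve (perfect doubling) with intercept
    30 Ct at 1 pg, which places the last detectable ten-fold dilution
    step at 0.1 pg under the 35-cycle non-detect cutoff; and a 2.5-fold
    mutant tumor-load enlargement (within the observed up-to-3-fold
    range).  The load distribution is lognormal (median 30 pg, log-SD
    0.8): a few hundred injected cells at ~6.6 pg of human DNA per
    diploid genome leave tens of pg after early clearance, and loads
    are positive and right-skewed.
    """

    n_embryos: int = 96
    genotype_probs: tuple = (0.25, 0.5, 0.25)  # (WT_HOM, HET, MUT_HOM)
    tumor_load_median_pg: float = 30.0
    tumor_load_sigma: float = 0.8          # log-space SD (natural log)
    load_fold_mutant: float = 2.5
    tumor_take_prob: float = 0.8           # P(any engrafted human DNA)
    curve_slope: float = -3.3219           # cycles per log10(pg)
    curve_intercept: float = 30.0          # Ct at 1 pg human DNA
    ct_noise_sd: float = 0.25              # per-well technical noise, cycles
    embryo_ct_sd: float = 0.2              # embryo-level host Ct wobble
    allele_offsets: dict = field(default_factory=lambda: {
        WT_HOM: (9.85, 1.07), MUT_HOM: (-5.65, 0.64), HET: (0.0, 0.3)})
    dropout_cutoff: float = 35.0
    dimer_rate: float = 0.02               # P(well is dimer-only)
    double_peak_rate: float = 0.1          # P(extra dimer peak on a good well)
    amplicon_tm: float = 84.0
    ref_ct_at_30ng: float = 20.0           # two-copy host Ct at 30 ng/ul
    concentration_median: float = 60.0     # ng/ul
    concentration_sigma: float = 0.4
    qc_fail_fraction: float = 0.1
    metastasis_rate: dict = field(default_factory=lambda: {
        WT_HOM: 0.378, HET: 0.378, MUT_HOM: 0.066})
    dispersed_neg_mean: float = 1.2        # Poisson mean, capped < min_cells
    dispersed_pos_extra_mean: float = 5.0  # min_cells + Poisson(this)
    min_cells: int = 5
    image_size: tuple = (220, 340)         # (rows, cols)
    roi_center: tuple = (85, 110)          # (x, y)
    roi_radii: tuple = (50, 60)            # (rx, ry)
    area_per_pg: float = 12.0              # tumor blob pixels per pg
    spot_radius: int = 2                   # dispersed-cell disk radius, px
    replicates: int = 2
    cell_line: str = "Hep3B"
    experiment_set: int = 1
    seed: int | None = None

    def __post_init__(self):
        p = self.genotype_probs
        if len(p) != 3 or any(x < 0 for x in p) or abs(sum(p) - 1) > 1e-9:
            raise ValueError("genotype_probs must be 3 non-negative values summing to 1")
        for name in ("tumor_load_sigma", "ct_noise_sd", "embryo_ct_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tumor_take_prob", "dimer_rate", "double_peak_rate",
                     "qc_fail_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")

    def _rng(self, stream: int, *extra) -> np.random.Generator:
        if self.seed is None:
            raise ValueError("SimConfig.seed must be set for stochastic calls")
        return np.random.default_rng([int(self.seed), stream, *map(int, extra)])


@dataclass(frozen=True)
class GroundTruth:
    embryo_id: str
    index: int
    true_genotype: str
    true_human_dna_pg: float
    true_tumor_area_px: int
    true_dispersed_count: int
    true_status: str
    true_metastasis_positive: bool
    concentration_ng_ul: float
    host_base_ct: float      # two-copy host reference Ct for this embryo
    qc_pass: bool


_GENOTYPES = (WT_HOM, HET, MUT_HOM)


def simulate_cohort(cfg: SimConfig):
    """Draw a cohort; returns (truths, dna_samples, phenotype_skeleton).

    Genotypes are multinomial in ``genotype_probs``; each embryo's
    human-DNA load is lognormal with the mutant median multiplied by
    ``load_fold_mutant``, zeroed for non-engrafting embryos
    (``tumor_take_prob``).  DNA concentration and purity are drawn so
    that about ``qc_fail_fraction`` of extracts fail the QC thresholds.
    """
    rng = cfg._rng(_STREAM_COHORT)
    n = cfg.n_embryos
    genotypes = rng.choice(_GENOTYPES, size=n, p=list(cfg.genotype_probs))
    take = rng.random(n) < cfg.tumor_take_prob
    mu = np.log(cfg.tumor_load_median_pg) + np.where(
        genotypes == MUT_HOM, np.log(cfg.load_fold_mutant), 0.0)
    pg = np.exp(rng.normal(mu, cfg.tumor_load_sigma)) * take

    conc = np.exp(rng.normal(np.log(cfg.concentration_median),
                             cfg.concentration_sigma, size=n))
    conc = np.maximum(conc, 31.0)  # passing draws stay above threshold
    a260_230 = np.clip(rng.normal(1.8, 0.3, size=n), 0.7, None)
    a260_280 = rng.normal(1.9, 0.06, size=n)
    fail = rng.random(n) < cfg.qc_fail_fraction
    fail_mode = rng.random(n) < 0.5
    conc = np.where(fail & fail_mode, rng.uniform(5.0, 29.0, size=n), conc)
    a260_230 = np.where(fail & ~fail_mode, rng.uniform(0.1, 0.6, size=n),
                        a260_230)

    base_ct = (cfg.ref_ct_at_30ng - np.log2(conc / 30.0)
               + rng.normal(0.0, cfg.embryo_ct_sd, size=n))

    met_p = np.array([cfg.metastasis_rate[g] for g in genotypes])
    met = (rng.random(n) < met_p) & take
    neg_counts = np.minimum(rng.poisson(cfg.dispersed_neg_mean, size=n),
                            cfg.min_cells - 1)
    pos_counts = cfg.min_cells + rng.poisson(cfg.dispersed_pos_extra_mean,
                                             size=n)
    dispersed = np.where(met, pos_counts, np.where(take, neg_counts, 0))

    truths, samples, pheno = [], [], []
    for i in range(n):
        embryo_id = f"E{i + 1:04d}"
        area = int(round(cfg.area_per_pg * pg[i]))
        status, positive = classify_embryo(
            area, int(dispersed[i]), MetastasisConfig(min_cells=cfg.min_cells))
        truths.append(GroundTruth(
            embryo_id=embryo_id, index=i, true_genotype=str(genotypes[i]),
            true_human_dna_pg=float(pg[i]), true_tumor_area_px=area,
            true_dispersed_count=int(dispersed[i]), true_status=status,
            true_metastasis_positive=bool(positive),
            concentration_ng_ul=float(conc[i]),
            host_base_ct=float(base_ct[i]), qc_pass=not bool(fail[i])))
        samples.append(DnaSample(
            sample_id=embryo_id, concentration_ng_ul=float(conc[i]),
            a260_280=float(a260_280[i]), a260_230=float(a260_230[i]),
            cell_line=cfg.cell_line, experiment_set=cfg.experiment_set))
        pheno.append({"embryo_id": embryo_id, "cell_line": cfg.cell_line,
                      "experiment_set": cfg.experiment_set,
                      "phenotype": str(genotypes[i])})
    return truths, samples, pd.DataFrame(pheno)


def _emit_well(rng, cfg, sample_id, primer, expected_ct, wells):
    """Append replicate wells for one reaction, with dropout and dimers."""
    for rep in range(1, cfg.replicates + 1):
        if rng.random() < cfg.dimer_rate:
            # primer-dimer-only reaction: spurious late Ct, low Tm peak
            wells.append(QpcrWell(
                sample_id, primer, float(rng.uniform(30.0, 34.0)),
                tm_peaks=(float(cfg.amplicon_tm - rng.uniform(8.0, 12.0)),),
                replicate_index=rep))
            continue
        if expected_ct is None:
            wells.append(QpcrWell(sample_id, primer, NON_DETECT,
                                  replicate_index=rep))
            continue
        ct = expected_ct + rng.normal(0.0, cfg.ct_noise_sd)
        peaks = [cfg.amplicon_tm + rng.normal(0.0, 0.3)]
        if rng.random() < cfg.double_peak_rate:
            peaks.append(cfg.amplicon_tm - rng.uniform(8.0, 12.0))
        if ct > cfg.dropout_cutoff:
            # emitted as the raw over-cutoff reading; readers map it to
            # NON_DETECT under the configured cutoff
            wells.append(QpcrWell(sample_id, primer, NON_DETECT,
                                  tm_peaks=tuple(peaks), replicate_index=rep,
                                  ct_raw=float(min(ct, 40.0)),
                                  flags=("over_cutoff",)))
        else:
            wells.append(QpcrWell(sample_id, primer, float(ct),
                                  tm_peaks=tuple(peaks), replicate_index=rep))
    return wells


def simulate_qpcr(truths, cfg: SimConfig) -> list[QpcrWell]:
    """Amplify a cohort: ACHE_N, ACHE_S and ALU_YB8 wells in duplicate.

    Host alleles: a homozygote's primary allele sits at the embryo's
    two-copy base Ct and its off-target allele at base + |offset|; a
    heterozygote's two single-copy alleles straddle base + 1 with the
    configured ΔCt(N−S) spread.  Alu Ct follows the standard-curve
    model from the embryo's true human-DNA amount.
    """
    wells: list[QpcrWell] = []
    for t in truths:
        rng = cfg._rng(_STREAM_QPCR, t.index)
        mean, sd = cfg.allele_offsets[t.true_genotype]
        # The configured SDs describe the observed per-embryo dispersion of
        # the replicate-averaged Ct difference, which already contains the
        # technical component; remove it from the embryo-level draw so the
        # emitted collapsed ΔCt(N−S) has exactly the configured SD.
        tech_var = 2.0 * cfg.ct_noise_sd ** 2 / cfg.replicates
        sd_embryo = math.sqrt(max(sd ** 2 - tech_var, 0.0))
        delta = rng.normal(mean, sd_embryo)
        base = t.host_base_ct
        if t.true_genotype == WT_HOM:
            ct_s, ct_n = base, base + delta
        elif t.true_genotype == MUT_HOM:
            ct_n, ct_s = base, base - delta
        else:  # HET: single-copy alleles, one cycle later than two-copy
            ct_n = base + 1.0 + delta / 2.0
            ct_s = base + 1.0 - delta / 2.0
        if t.true_human_dna_pg > 0:
            ct_alu = (cfg.curve_intercept
                      + cfg.curve_slope * math.log10(t.true_human_dna_pg))
        else:
            ct_alu = None
        _emit_well(rng, cfg, t.embryo_id, ACHE_N, ct_n, wells)
        _emit_well(rng, cfg, t.embryo_id, ACHE_S, ct_s, wells)
        _emit_well(rng, cfg, t.embryo_id, ALU_YB8, ct_alu, wells)
    return wells


def simulate_standards(cfg: SimConfig, noise_sd: float | None = None
                       ) -> list[StandardCurvePoint]:
    """Ten-fold dilution series, 10 ng down to 0.01 pg (7 steps).

    Steps whose expected Ct exceeds the dropout cutoff are emitted as
    non-detects; with the default curve the last detected step is
    0.1 pg.  ``noise_sd`` overrides ``cfg.ct_noise_sd`` (0 gives the
    noise-free series).
    """
    sd = cfg.ct_noise_sd if noise_sd is None else noise_sd
    rng = cfg._rng(_STREAM_STANDARDS) if sd > 0 else None
    points = []
    for exponent in range(4, -3, -1):
        pg = 10.0 ** exponent
        expected = cfg.curve_intercept + cfg.curve_slope * exponent
        if expected > cfg.dropout_cutoff:
            points.append(StandardCurvePoint(pg, NON_DETECT))
        else:
            ct = expected + (rng.normal(0.0, sd) if rng is not None else 0.0)
            points.append(StandardCurvePoint(pg, float(ct)))
    return points


def simulate_larva_image(truth: GroundTruth, cfg: SimConfig):
    """Render one larva; returns (pixels uint8, YolkRoi).

    A tumor disk of the embryo's true area sits at the ROI center;
    ``true_dispersed_count`` small spots are placed on a jittered grid
    in the tail region (strictly outside the ROI, mutually separated);
    the background is low-amplitude Gaussian noise.  Deterministic per
    (config, seed, embryo).
    """
    rng = cfg._rng(_STREAM_IMAGE, truth.index)
    h, w = cfg.image_size
    roi = YolkRoi(center=cfg.roi_center, radii=cfg.roi_radii)
    img = np.clip(rng.normal(20.0, 4.0, size=(h, w)), 0.0, None)

    if truth.true_tumor_area_px > 0:
        radius = math.sqrt(truth.true_tumor_area_px / math.pi)
        radius = min(radius, min(cfg.roi_radii) - 6.0)
        rr, cc = draw_disk((cfg.roi_center[1], cfg.roi_center[0]),
                           max(radius, 1.0), shape=(h, w))
        img[rr, cc] = 200.0

    n_spots = truth.true_dispersed_count
    if n_spots > 0:
        x0 = cfg.roi_center[0] + cfg.roi_radii[0] + 15
        spacing = 4 * cfg.spot_radius + 1
        xs = np.arange(x0, w - 2 * cfg.spot_radius - 2, spacing)
        ys = np.arange(2 * cfg.spot_radius + 2,
                       h - 2 * cfg.spot_radius - 2, spacing)
        slots = [(x, y) for x in xs for y in ys]
        if n_spots > len(slots):
            raise ValueError("image too small for the requested spot count")
        chosen = rng.choice(len(slots), size=n_spots, replace=False)
        for idx in chosen:
            x, y = slots[idx]
            jx, jy = rng.integers(-1, 2, size=2)
            rr, cc = draw_disk((y + jy, x + jx), cfg.spot_radius + 0.5,
                               shape=(h, w))
            img[rr, cc] = 180.0
    return np.clip(img, 0, 255).astype(np.uint8), roi


def truth_table(truths) -> pd.DataFrame:
    """Ground-truth labels as a frame keyed by embryo_id."""
    return pd.DataFrame([{
        "embryo_id": t.embryo_id, "true_genotype": t.true_genotype,
        "true_human_dna_pg": t.true_human_dna_pg,
        "true_tumor_area_px": t.true_tumor_area_px,
        "true_dispersed_count": t.true_dispersed_count,
        "true_status": t.true_status,
        "true_metastasis_positive": t.true_metastasis_positive,
        "concentration_ng_ul": t.concentration_ng_ul,
        "qc_pass": t.qc_pass,
    } for t in truths])
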