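"""Human-tumor-DNA load, standard curves and relative expression.

Human DNA carried by a xenografted larva is measured with primers against
the AluYb8 repeat (abundant and primate-specific, hence a sensitive
human-DNA marker in a zebrafish host) and normalized against the host
*ache* locus by the ΔCt method.  Because the allele-specific reference
primers see two template copies in homozygotes but one per primer in
heterozygotes, one cycle — the Ct equivalent of a 2-fold template
difference — is added to the homozygote's primary-primer Ct, while
heterozygotes use the mean of both primers.  The normalized load is

    load_dct = ct_ref_adjusted − ct_alu

oriented so that a larger value means more human DNA; the convention is
recorded in every output's metadata.

Standard curves are ordinary least squares of Ct on log10(human DNA, pg)
over the detected points of a dilution series, with amplification
efficiency 10^(−1/slope) − 1 and an empirical limit of detection (the
smallest input amount still detected under the non-detect cutoff).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

from .qpcr import NON_DETECT, ACHE_N, ACHE_S, ALU_YB8, DnaSample, is_nondetect
from .genotyping import WT_HOM, HET, MUT_HOM, GenotypeCall

LOAD_ORIENTATION = "host_minus_human: larger load_dct = more human DNA"


class GenotypeRequiredError(ValueError):
    """Copy-number correction needs a classified genotype."""


class InsufficientCurveError(ValueError):
    """Too few detected points (or too narrow a range) to fit a curve."""


class CalibratorError(ValueError):
    """The ΔΔCt calibrator sample does not express the target."""


def adjusted_reference_ct(call: str, ct_n=None, ct_s=None) -> float:
    """Copy-number-corrected host reference Ct.

    Homozygotes: primary primer Ct + 1 (S for wild type, N for mutant);
    heterozygotes: mean of both primers.  Unclassified genotypes cannot
    be normalized.
    """
    if call == WT_HOM:
        if is_nondetect(ct_s):
            raise ValueError("WT_HOM correction needs a numeric ache S Ct")
        return float(ct_s) + 1.0
    if call == MUT_HOM:
        if is_nondetect(ct_n):
            raise ValueError("MUT_HOM correction needs a numeric ache N Ct")
        return float(ct_n) + 1.0
    if call == HET:
        if is_nondetect(ct_n) or is_nondetect(ct_s):
            raise ValueError("HET correction needs both allele Ct values")
        return (float(ct_n) + float(ct_s)) / 2.0
    raise GenotypeRequiredError(
        f"genotype required before normalization (got {call!r})")


def alu_load(ct_alu, ct_ref_adjusted) -> float:
    """Normalized human-DNA load in cycles (host minus human)."""
    if is_nondetect(ct_alu) or is_nondetect(ct_ref_adjusted):
        raise ValueError("alu_load requires numeric Ct values")
    return float(ct_ref_adjusted) - float(ct_alu)


@dataclass(frozen=True)
class StandardCurvePoint:
    """One dilution step: human DNA (pg) spiked into constant host DNA."""

    human_dna_pg: float
    ct: object  # float or NON_DETECT
    constant_background: bool = True

    def __post_init__(self):
        if self.human_dna_pg <= 0:
            raise ValueError("human_dna_pg must be positive")


@dataclass(frozen=True)
class StandardCurveFit:
    slope: float            # cycles per log10(pg)
    intercept: float        # Ct at 1 pg
    r: float                # Pearson correlation of the fitted pairs
    efficiency: float       # 10**(-1/slope) - 1
    lod_pg: float           # smallest detected dilution step
    n_points: int
    valid: bool


def _numeric_points(points, cutoff):
    pairs = []
    for p in points:
        if not is_nondetect(p.ct) and float(p.ct) < cutoff:
            pairs.append((math.log10(p.human_dna_pg), float(p.ct),
                          p.human_dna_pg))
    return pairs


def fit_standard_curve(points, cutoff: float = 35.0) -> StandardCurveFit:
    """Least-squares Ct vs log10(pg) fit of a dilution series.

    Requires at least three detected points spanning two decades.  A
    non-negative slope yields a fit flagged invalid rather than an
    error.  The limit of detection is empirical: the smallest input
    amount whose Ct is numeric under ``cutoff``.
    """
    pairs = _numeric_points(points, cutoff)
    if len(pairs) < 3:
        raise InsufficientCurveError(
            f"insufficient curve: {len(pairs)} detected point(s), need >= 3")
    logs = np.array([p[0] for p in pairs])
    cts = np.array([p[1] for p in pairs])
    if logs.max() - logs.min() < 2.0:
        raise InsufficientCurveError(
            "insufficient curve: detected points span < 2 log10 units")
    res = sps.linregress(logs, cts)
    slope, intercept, r = float(res.slope), float(res.intercept), float(res.rvalue)
    efficiency = 10.0 ** (-1.0 / slope) - 1.0 if slope != 0 else math.nan
    lod = min(p[2] for p in pairs)
    return StandardCurveFit(slope=slope, intercept=intercept, r=r,
                            efficiency=efficiency, lod_pg=lod,
                            n_points=len(pairs), valid=slope < 0)


@dataclass(frozen=True)
class DnaEstimate:
    pg: float
    below_lod: bool


def predict_human_dna(fit: StandardCurveFit, ct) -> DnaEstimate:
    """Inverse prediction: pg = 10**((ct − intercept) / slope)."""
    if not fit.valid:
        raise ValueError("cannot predict from an invalid standard curve")
    if is_nondetect(ct):
        raise ValueError("cannot predict from a non-detect Ct")
    pg = 10.0 ** ((float(ct) - fit.intercept) / fit.slope)
    return DnaEstimate(pg=pg, below_lod=pg < fit.lod_pg)


class StandardCurve(RegressorMixin, BaseEstimator):
    """scikit-learn estimator for the qPCR dilution standard curve.

    ``fit(X, y)`` takes human-DNA amounts (pg) and their Ct readings
    (NaN = non-detect); ``predict(X)`` maps pg to expected Ct and
    :meth:`inverse_predict` maps Ct back to pg.

    Parameters
    ----------
    cutoff : float, default 35.0
        Non-detect cutoff in cycles; readings at or above it are
        excluded from the fit and the LOD.

    Attributes
    ----------
    slope_, intercept_ : float
        Line of Ct on log10(pg).
    r_ : float
        Pearson correlation of the fitted pairs.
    efficiency_ : float
        Amplification efficiency, 10^(−1/slope) − 1 (1.0 = perfect
        doubling each cycle).
    lod_pg_ : float
        Empirical limit of detection.
    valid_ : bool
        False when the fitted slope is non-negative.
    """

    def __init__(self, cutoff: float = 35.0):
        self.cutoff = cutoff

    def fit(self, X, y):
        X = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        points = [StandardCurvePoint(pg, NON_DETECT if math.isnan(ct) else ct)
                  for pg, ct in zip(X, y)]
        f = fit_standard_curve(points, cutoff=self.cutoff)
        self.slope_, self.intercept_, self.r_ = f.slope, f.intercept, f.r
        self.efficiency_, self.lod_pg_ = f.efficiency, f.lod_pg
        self.n_points_, self.valid_ = f.n_points, f.valid
        self.fit_ = f
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float).ravel()
        return self.intercept_ + self.slope_ * np.log10(X)

    def inverse_predict(self, ct):
        ct = np.asarray(ct, dtype=float)
        return 10.0 ** ((ct - self.intercept_) / self.slope_)


@dataclass(frozen=True)
class ExpressionRecord:
    sample_id: str | None
    target_gene: str
    reference_gene: str
    ct_target: float
    ct_reference: float
    ddct: float
    log2_fold_change: float

    @property
    def fold_change(self) -> float:
        return 2.0 ** self.log2_fold_change


def ddct_expression(ct_target, ct_reference, calibrator_ct_target,
                    calibrator_ct_reference, sample_id=None,
                    target_gene="target", reference_gene="reference"
                    ) -> ExpressionRecord:
    """Relative expression by the ΔΔCt method.

    ΔΔCt = (Ct_target − Ct_ref) − (Ct_target − Ct_ref)_calibrator and
    log2 fold change = −ΔΔCt.  The calibrator (conventionally the
    lowest expresser) must itself express the target.
    """
    if is_nondetect(calibrator_ct_target):
        raise CalibratorError("calibrator must express target; "
                              "choose the next-lowest expresser")
    for v in (ct_target, ct_reference, calibrator_ct_reference):
        if is_nondetect(v):
            raise ValueError("ddct_expression requires four numeric Ct values")
    ddct = ((float(ct_target) - float(ct_reference))
            - (float(calibrator_ct_target) - float(calibrator_ct_reference)))
    return ExpressionRecord(sample_id, target_gene, reference_gene,
                            float(ct_target), float(ct_reference),
                            ddct, -ddct)


def concentration_ct_check(samples, ct_ref):
    """Pearson r between log2(DNA concentration) and host reference Ct.

    A good extraction shows a significantly negative correlation (more
    template, earlier Ct), so concentration predicts the host Ct.
    Accepts :class:`DnaSample` objects or raw concentrations.

    Returns ``(r, p)``; on constant input r is undefined and both are
    NaN.
    """
    conc = np.asarray(
        [s.concentration_ng_ul if isinstance(s, DnaSample) else s
         for s in samples], dtype=float)
    ct = np.asarray(ct_ref, dtype=float)
    if conc.shape != ct.shape:
        raise ValueError("samples and ct_ref must be paired")
    if conc.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    x = np.log2(conc)
    if np.ptp(x) == 0 or np.ptp(ct) == 0:
        return math.nan, math.nan
    r, p = sps.pearsonr(x, ct)
    return float(r), float(p)


def tumor_load_table(collapsed, calls, curve: StandardCurveFit | None = None
                     ) -> pd.DataFrame:
    """Per-embryo normalized human-DNA load table.

    Joins collapsed Ct means with genotype calls, applies the
    copy-number correction and the ΔCt normalization, and (optionally)
    converts Alu Ct to pg through a fitted standard curve.  Samples
    whose Alu reaction was non-detect are kept with flag
    ``below_detection`` and a NaN load so mean comparisons can report
    how many were excluded; unclassified genotypes are flagged rather
    than silently dropped.  The frame's ``attrs["load_orientation"]``
    records the sign convention.
    """
    if isinstance(collapsed, pd.DataFrame):
        rows = collapsed.to_dict("records")
    else:
        rows = list(collapsed)
    ct_by_sample: dict[str, dict] = {}
    for row in rows:
        ct_by_sample.setdefault(row["sample_id"], {})[row["primer_id"]] = \
            row["ct_mean"]

    out = []
    for call in calls:
        cts = ct_by_sample.get(call.sample_id, {})
        ct_alu = cts.get(ALU_YB8, math.nan)
        rec = {"sample_id": call.sample_id, "genotype": call.call,
               "ct_ref_adjusted": math.nan, "ct_alu": ct_alu,
               "load_dct": math.nan, "est_human_dna_pg": math.nan,
               "flags": ""}
        flags = list(call.flags)
        try:
            ct_ref = adjusted_reference_ct(call.call, ct_n=call.ct_n,
                                           ct_s=call.ct_s)
            rec["ct_ref_adjusted"] = ct_ref
        except (GenotypeRequiredError, ValueError):
            flags.append("unclassified_genotype")
            ct_ref = math.nan
        if is_nondetect(ct_alu):
            flags.append("below_detection")
        elif not math.isnan(ct_ref):
            rec["load_dct"] = alu_load(ct_alu, ct_ref)
            if curve is not None and curve.valid:
                est = predict_human_dna(curve, ct_alu)
                rec["est_human_dna_pg"] = est.pg
                if est.below_lod:
                    flags.append("below_lod")
        rec["flags"] = ";".join(flags)
        out.append(rec)
    df = pd.DataFrame(out, columns=["sample_id", "genotype",
                                    "ct_ref_adjusted", "ct_alu", "load_dct",
                                    "est_human_dna_pg", "flags"])
    df.attrs["load_orientation"] = LOAD_ORIENTATION
    return df
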