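"""Single-embryo genotype calling from allele-specific qPCR.

The host carries a loss-of-function point mutation; two competing primer
pairs amplify preferentially the mutant (N) or wild-type (S) allele.  The
Ct difference Δ = Ct(N) − Ct(S) separates the three genotypes of a
heterozygote in-cross: wild-type homozygotes amplify late with N
(Δ ≈ +10), mutant homozygotes late with S (Δ ≈ −6), heterozygotes
symmetrically (Δ ≈ 0).  Calls use two windows: |Δ| ≤ het_halfwidth is
heterozygous, |Δ| ≥ hom_threshold homozygous with the sign giving the
allele, and the open band in between is left unclassified.  Boundary
values are assigned to the classified side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .qpcr import NON_DETECT, ACHE_N, ACHE_S, is_nondetect

WT_HOM = "WT_HOM"
HET = "HET"
MUT_HOM = "MUT_HOM"
UNCLASSIFIED = "UNCLASSIFIED"
NO_AMPLIFICATION = "no_amplification"

GENOTYPE_CLASSES = (WT_HOM, HET, MUT_HOM, UNCLASSIFIED)


class NoAmplificationError(ValueError):
    """Neither allele-specific primer amplified for a sample."""


@dataclass(frozen=True)
class GenotypeWindows:
    """Classification windows, in cycles.

    Defaults are the assay's validated values: 1 cycle for the
    heterozygote band, 4 cycles for the homozygote threshold; Δ strictly
    between them is unclassified.
    """

    het_halfwidth: float = 1.0
    hom_threshold: float = 4.0

    def __post_init__(self):
        if not (0 < self.het_halfwidth < self.hom_threshold):
            raise ValueError("require 0 < het_halfwidth < hom_threshold")


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str | None
    ct_n: float | None
    ct_s: float | None
    delta_ct_ns: float | None
    call: str
    flags: tuple = ()


def classify_delta(delta, windows: GenotypeWindows | None = None):
    """Vectorized window logic on Δ = Ct(N) − Ct(S).

    Accepts a scalar or array; returns call labels of the same shape.
    """
    w = windows or GenotypeWindows()
    d = np.asarray(delta, dtype=float)
    out = np.select(
        [np.abs(d) <= w.het_halfwidth, d >= w.hom_threshold,
         d <= -w.hom_threshold],
        [HET, WT_HOM, MUT_HOM],
        default=UNCLASSIFIED,
    )
    return out.item() if np.isscalar(delta) else out


def call_genotype(ct_n, ct_s, windows: GenotypeWindows | None = None,
                  sample_id: str | None = None) -> GenotypeCall:
    """Call one embryo's genotype from its two allele-specific Ct values.

    Either Ct may be :data:`NON_DETECT` (or NaN).  With exactly one
    allele detected, the homozygote favored by the detected allele is
    called and flagged ``single_allele_call`` — total primer failure is
    indistinguishable from allele absence, so the flag preserves the
    audit trail.  Both non-detect raises :class:`NoAmplificationError`.
    """
    n_nd, s_nd = is_nondetect(ct_n), is_nondetect(ct_s)
    if n_nd and s_nd:
        raise NoAmplificationError(f"no amplification for {sample_id!r}")
    if n_nd or s_nd:
        call = WT_HOM if n_nd else MUT_HOM  # detected allele wins
        return GenotypeCall(sample_id, None if n_nd else float(ct_n),
                            None if s_nd else float(ct_s), None, call,
                            flags=("single_allele_call",))
    ct_n, ct_s = float(ct_n), float(ct_s)
    delta = ct_n - ct_s
    return GenotypeCall(sample_id, ct_n, ct_s, delta,
                        classify_delta(delta, windows))


def genotype_cohort(collapsed, windows: GenotypeWindows | None = None):
    """Genotype every sample of a collapsed Ct table.

    Parameters
    ----------
    collapsed : DataFrame or iterable of mappings
        Rows with ``sample_id``, ``primer_id`` and ``ct_mean`` (NaN when
        all replicates were non-detect), as produced by
        :func:`xenoquant.qpcr.collapse_replicates`.

    Returns
    -------
    (calls, summary)
        One :class:`GenotypeCall` per sample (samples with neither
        primer amplifying are recorded with call ``no_amplification``,
        never dropped) and a count per class summing to the cohort size.
    """
    if isinstance(collapsed, pd.DataFrame):
        rows = collapsed.to_dict("records")
    else:
        rows = list(collapsed)
    per_sample: dict[str, dict] = {}
    order: list[str] = []
    for row in rows:
        sid = row["sample_id"]
        if sid not in per_sample:
            per_sample[sid] = {}
            order.append(sid)
        per_sample[sid][row["primer_id"]] = row["ct_mean"]

    calls = []
    summary = {c: 0 for c in GENOTYPE_CLASSES}
    summary[NO_AMPLIFICATION] = 0
    for sid in order:
        cts = per_sample[sid]
        ct_n = cts.get(ACHE_N, math.nan)
        ct_s = cts.get(ACHE_S, math.nan)
        try:
            call = call_genotype(ct_n, ct_s, windows, sample_id=sid)
        except NoAmplificationError:
            call = GenotypeCall(sid, None, None, None, NO_AMPLIFICATION)
        calls.append(call)
        summary[call.call] += 1
    return calls, summary


def genotype_table(calls) -> pd.DataFrame:
    """Tabulate calls for CSV export."""
    return pd.DataFrame([{
        "sample_id": c.sample_id, "ct_n": c.ct_n, "ct_s": c.ct_s,
        "delta_ct_ns": c.delta_ct_ns, "call": c.call,
        "flags": ";".join(c.flags),
    } for c in calls])


class GenotypeCaller(ClassifierMixin, BaseEstimator):
    """Threshold classifier over (Ct_N, Ct_S) pairs.

    A scikit-learn-compatible wrapper around the window rule so cohorts
    can be genotyped inside sklearn pipelines.  ``fit`` only validates
    the windows (the decision rule is fixed by the assay, not learned).

    Parameters
    ----------
    het_halfwidth : float, default 1.0
        |Δ| at or below this is heterozygous.
    hom_threshold : float, default 4.0
        |Δ| at or above this is homozygous; the open band between the
        two windows is unclassified.

    Attributes
    ----------
    classes_ : ndarray of shape (4,)
        The possible call labels.
    windows_ : GenotypeWindows
        Validated window parameters.
    """

    def __init__(self, het_halfwidth: float = 1.0, hom_threshold: float = 4.0):
        self.het_halfwidth = het_halfwidth
        self.hom_threshold = hom_threshold

    def fit(self, X=None, y=None):
        self.windows_ = GenotypeWindows(self.het_halfwidth, self.hom_threshold)
        self.classes_ = np.asarray(GENOTYPE_CLASSES)
        return self

    def predict(self, X):
        """Predict call labels.

        ``X`` is (n, 2) with columns Ct_N, Ct_S (NaN = non-detect), or
        (n,) of precomputed Δ values.
        """
        if not hasattr(self, "windows_"):
            self.fit()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            return classify_delta(X, self.windows_)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2) Ct pairs or (n,) deltas")
        out = np.empty(X.shape[0], dtype=object)
        for i, (ct_n, ct_s) in enumerate(X):
            if math.isnan(ct_n) and math.isnan(ct_s):
                out[i] = NO_AMPLIFICATION
            else:
                out[i] = call_genotype(ct_n, ct_s, self.windows_).call
        return out.astype(str)
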