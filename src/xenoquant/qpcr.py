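"""Well-table I/O and quality control for SYBR-green qPCR runs.

A *well* is one amplification reaction: a sample, a primer pair, a cycle
threshold (Ct) and the melting-curve peak temperatures recorded after the
run.  Ct values above a configurable cutoff (default 35 cycles, where the
Alu primers begin to cross-react with host DNA) and "Undetermined" entries
are mapped to a typed :data:`NON_DETECT` sentinel; the raw over-cutoff
value is retained for audit.  DNA extracts are screened on A260/A230 and
concentration before any quantitative use; A260/A280 is recorded but not
used as a hard filter.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


class WellParseError(ValueError):
    """A row of a well table could not be parsed; carries the row index."""

    def __init__(self, message: str, row_index: int):
        super().__init__(f"row {row_index}: {message}")
        self.row_index = row_index


class _NonDetect:
    """Singleton sentinel for reactions with no amplification call."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NON_DETECT"

    def __bool__(self) -> bool:
        return False


NON_DETECT = _NonDetect()

# Canonical primer identifiers.  Free-text gene names are allowed for
# expression targets/references; the three assay primers are normalized.
ACHE_N = "ACHE_N"   # mutant-allele-specific host primer
ACHE_S = "ACHE_S"   # wild-type-allele-specific host primer
ALU_YB8 = "ALU_YB8"  # human-specific Alu repeat primer

_PRIMER_ALIASES = {
    "achen": ACHE_N, "ache_n": ACHE_N, "ache n": ACHE_N, "ache-n": ACHE_N,
    "aches": ACHE_S, "ache_s": ACHE_S, "ache s": ACHE_S, "ache-s": ACHE_S,
    "aluyb8": ALU_YB8, "alu_yb8": ALU_YB8, "alu yb8": ALU_YB8, "alu": ALU_YB8,
}

_NONDETECT_TOKENS = {"", "undetermined", "undet", "nd", "na", "nan", "none"}


def canonical_primer(name: str) -> str:
    """Normalize spelling variants of the three assay primers."""
    return _PRIMER_ALIASES.get(str(name).strip().lower(), str(name).strip())


def is_nondetect(ct) -> bool:
    """True for the sentinel, ``None`` and NaN."""
    if ct is NON_DETECT or ct is None:
        return True
    try:
        return math.isnan(float(ct))
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class QpcrWell:
    """One amplification reaction.

    ``ct`` is a non-negative cycle count or :data:`NON_DETECT`; when a
    numeric reading above the non-detect cutoff was mapped to the sentinel
    the original reading is kept in ``ct_raw``.
    """

    sample_id: str
    primer_id: str
    ct: object  # float or NON_DETECT
    tm_peaks: tuple = ()
    replicate_index: int = 1
    ct_raw: float | None = None
    flags: tuple = ()

    def __post_init__(self):
        if not is_nondetect(self.ct) and float(self.ct) < 0:
            raise ValueError(f"negative Ct {self.ct!r} for {self.sample_id}")


@dataclass(frozen=True)
class DnaSample:
    """A whole-larva DNA extract with spectrophotometric QC readings."""

    sample_id: str
    concentration_ng_ul: float | None = None
    a260_280: float | None = None
    a260_230: float | None = None
    cell_line: str = "other"
    experiment_set: int = 1


@dataclass(frozen=True)
class QcConfig:
    """Quality-control thresholds.

    Defaults follow the study design: extracts need A260/A230 > 0.6 and
    ≥ 30 ng/µl; Ct > 35 is treated as non-detection (Alu primer
    cross-reactivity floor); melting peaks within ``tm_tolerance`` of the
    expected amplicon Tm distinguish product from primer dimer.
    """

    min_a260_230: float = 0.6
    min_concentration: float = 30.0
    ct_nondetect_cutoff: float = 35.0
    amplicon_tm: float | None = None
    tm_tolerance: float = 1.5

    def __post_init__(self):
        if self.min_a260_230 <= 0 or self.min_concentration <= 0:
            raise ValueError("QC thresholds must be positive")
        if self.ct_nondetect_cutoff <= 0:
            raise ValueError("ct_nondetect_cutoff must be positive")
        if not (0 < self.tm_tolerance < 10):
            raise ValueError("tm_tolerance must lie in (0, 10) °C")


@dataclass(frozen=True)
class QcVerdict:
    passed: bool
    violations: tuple = ()


@dataclass(frozen=True)
class WellVerdict:
    category: str  # "usable" | "dimer_only" | "nondetect"
    warnings: tuple = ()


_WELL_COLUMNS = ("sample_id", "primer_id", "ct", "tm_peaks", "replicate")


def _parse_ct(token, row_index: int, cutoff: float | None):
    """Map a raw Ct cell to (ct, ct_raw, flags)."""
    if token is None:
        return NON_DETECT, None, ()
    text = str(token).strip()
    if text.lower() in _NONDETECT_TOKENS:
        return NON_DETECT, None, ()
    try:
        value = float(text)
    except ValueError:
        raise WellParseError(f"unparseable Ct {text!r}", row_index) from None
    if value < 0:
        raise WellParseError(f"negative Ct {value}", row_index)
    if cutoff is not None and value > cutoff:
        return NON_DETECT, value, ("over_cutoff",)
    return value, None, ()


def _parse_tm(token) -> tuple:
    if token is None:
        return ()
    text = str(token).strip()
    if not text:
        return ()
    return tuple(float(t) for t in text.split(";") if t.strip())


def read_well_table(path, schema: dict | None = None,
                    qc: QcConfig | None = None) -> list[QpcrWell]:
    """Read a well table CSV into a list of :class:`QpcrWell`.

    Parameters
    ----------
    path : str or path-like
        CSV with a header row.  Mandatory columns: ``sample_id``,
        ``primer_id``, ``ct``.  Optional: ``tm_peaks`` (semicolon-joined
        °C values) and ``replicate``.
    schema : dict, optional
        Maps the canonical column names above to the file's actual
        column names.
    qc : QcConfig, optional
        When given, numeric Ct readings above ``qc.ct_nondetect_cutoff``
        are mapped to :data:`NON_DETECT` with the raw value retained.
    """
    schema = schema or {}
    cutoff = qc.ct_nondetect_cutoff if qc is not None else None
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        colmap = {}
        for name in _WELL_COLUMNS:
            actual = schema.get(name, name)
            if actual in header:
                colmap[name] = actual
            elif name in ("sample_id", "primer_id", "ct"):
                raise SchemaError(f"missing mandatory column {actual!r}")
        wells = []
        for i, row in enumerate(reader):
            ct, ct_raw, flags = _parse_ct(row.get(colmap["ct"]), i, cutoff)
            tm = _parse_tm(row.get(colmap.get("tm_peaks", ""), None))
            rep_token = row.get(colmap.get("replicate", ""), None)
            try:
                rep = int(rep_token) if rep_token not in (None, "") else 1
            except ValueError:
                raise WellParseError(f"unparseable replicate {rep_token!r}", i) from None
            wells.append(QpcrWell(
                sample_id=str(row[colmap["sample_id"]]).strip(),
                primer_id=canonical_primer(row[colmap["primer_id"]]),
                ct=ct, tm_peaks=tm, replicate_index=rep,
                ct_raw=ct_raw, flags=flags,
            ))
    return wells


def write_well_table(wells: Iterable[QpcrWell], path) -> None:
    """Write wells back to CSV; inverse of :func:`read_well_table` on
    usable fields (over-cutoff readings are written as their raw value)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_WELL_COLUMNS)
        for w in wells:
            if not is_nondetect(w.ct):
                ct_text = repr(float(w.ct))
            elif w.ct_raw is not None:
                ct_text = repr(float(w.ct_raw))
            else:
                ct_text = "Undetermined"
            writer.writerow([w.sample_id, w.primer_id, ct_text,
                             ";".join(repr(t) for t in w.tm_peaks),
                             w.replicate_index])


def read_sample_table(path) -> list[DnaSample]:
    """Read a DNA-sample QC table CSV."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise SchemaError("missing mandatory column 'sample_id'")

    def _get(row, col):
        v = row.get(col)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)

    samples = []
    for _, row in df.iterrows():
        samples.append(DnaSample(
            sample_id=str(row["sample_id"]),
            concentration_ng_ul=_get(row, "concentration_ng_ul"),
            a260_280=_get(row, "a260_280"),
            a260_230=_get(row, "a260_230"),
            cell_line=str(row.get("cell_line", "other")),
            experiment_set=int(row.get("experiment_set", 1)),
        ))
    return samples


def qc_filter_sample(sample: DnaSample, cfg: QcConfig | None = None) -> QcVerdict:
    """Pass/fail a DNA extract on purity and concentration.

    Fails iff A260/A230 ≤ ``min_a260_230`` or concentration <
    ``min_concentration``; every violated criterion is listed.  A260/A280
    is deliberately not part of the filter.
    """
    cfg = cfg or QcConfig()
    violations = []
    if sample.a260_230 is None or sample.concentration_ng_ul is None:
        violations.append("missing_measurement")
    if sample.a260_230 is not None and sample.a260_230 <= cfg.min_a260_230:
        violations.append("a260_230")
    if (sample.concentration_ng_ul is not None
            and sample.concentration_ng_ul < cfg.min_concentration):
        violations.append("concentration")
    return QcVerdict(passed=not violations, violations=tuple(violations))


def qc_filter_well(well: QpcrWell, cfg: QcConfig) -> WellVerdict:
    """Classify a well as usable, dimer-only, or non-detect.

    A well whose melting peaks all fall outside ``amplicon_tm ±
    tm_tolerance`` amplified only primer dimer and is excluded; a dimer
    peak co-occurring with an in-window amplicon peak is acceptable.
    Absent melt data is never a silent exclusion: the well stays usable
    with a warning.
    """
    if is_nondetect(well.ct):
        return WellVerdict("nondetect")
    if cfg.amplicon_tm is None:
        return WellVerdict("usable")
    if not well.tm_peaks:
        return WellVerdict("usable", warnings=("melt_data_absent",))
    in_window = any(abs(t - cfg.amplicon_tm) <= cfg.tm_tolerance
                    for t in well.tm_peaks)
    return WellVerdict("usable" if in_window else "dimer_only")


def filter_usable_wells(wells: Iterable[QpcrWell], cfg: QcConfig
                        ) -> list[QpcrWell]:
    """Drop dimer-only and non-detect wells ahead of replicate collapsing."""
    return [w for w in wells if qc_filter_well(w, cfg).category == "usable"]


def _collapse_rows(wells: Sequence[QpcrWell]) -> list[dict]:
    groups: dict[tuple, list[QpcrWell]] = {}
    for w in wells:
        groups.setdefault((w.sample_id, w.primer_id), []).append(w)
    rows = []
    for (sample_id, primer_id), members in groups.items():
        cts = [float(w.ct) for w in members if not is_nondetect(w.ct)]
        n = len(cts)
        mean = sum(cts) / n if n else math.nan
        if n >= 2:
            sd = math.sqrt(sum((c - mean) ** 2 for c in cts) / (n - 1))
        else:
            sd = math.nan
        rows.append({
            "sample_id": sample_id, "primer_id": primer_id,
            "ct_mean": mean, "ct_sd": sd,
            "n_detected": n, "n_total": len(members),
            "discordant": 0 < n < len(members),
        })
    return rows


def collapse_replicates(wells: Sequence[QpcrWell]) -> pd.DataFrame:
    """Collapse replicate wells to per (sample, primer) mean Ct.

    Returns a frame with ``ct_mean`` (NaN when every replicate was
    non-detect), ``ct_sd`` (NaN for n < 2), detected/total counts and a
    ``discordant`` flag set when numeric and non-detect replicates
    coexisted — the numeric mean is kept but flagged, never dropped.
    """
    rows = _collapse_rows(wells)
    return pd.DataFrame(rows, columns=["sample_id", "primer_id", "ct_mean",
                                       "ct_sd", "n_detected", "n_total",
                                       "discordant"])


def qc_report(samples: Iterable[DnaSample], wells: Iterable[QpcrWell],
              cfg: QcConfig, path) -> None:
    """Write a JSON-lines QC report, one record per sample and per well."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in samples:
            v = qc_filter_sample(s, cfg)
            fh.write(json.dumps({"kind": "sample", "sample_id": s.sample_id,
                                 "passed": v.passed,
                                 "violations": list(v.violations)}) + "\n")
        for w in wells:
            v = qc_filter_well(w, cfg)
            fh.write(json.dumps({"kind": "well", "sample_id": w.sample_id,
                                 "primer_id": w.primer_id,
                                 "replicate": w.replicate_index,
                                 "category": v.category,
                                 "warnings": list(v.warnings)}) + "\n")
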