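"""Multi-reader benchmark comparison machinery.

The benchmark defines, per case, a *reference TMTV* as the median of the
3-4 expert readers' values, and calls a measurement concordant when it is
within 10 cm^3 or within 10% of the reference (either arm suffices; strict
``<`` is used throughout, documented in every report).  Reader agreement
across a panel is summarised by ICC(2,1) — two-way random effects, absolute
agreement, single rater — plus paired difference statistics for
Bland-Altman-style plots.  Cases where any reader strays far from the
median (default: more than 25% relative or more than 45 cm^3 absolute) are
flagged for adjudication; in the published benchmark every >25% flag traced
back to diffuse splenic uptake.

``validate_implementation`` is the user-facing entry point: it compares a
table of locally measured TMTVs against a reference table and reports the
pass fraction per workflow stage, which is how a site demonstrates that its
tool reproduces the benchmark.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field
from importlib.resources import files
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import ValidationDataError

log = logging.getLogger("tmtvbench")

__all__ = [
    "CaseRecord",
    "AgreementResult",
    "ICCResult",
    "DiffStats",
    "DiscrepancyReport",
    "reference_tmtv",
    "agreement",
    "icc",
    "diff_stats",
    "flag_discrepancies",
    "validate_implementation",
    "load_discrepant_cases",
]

DEFAULT_ABS_TOL_CM3 = 10.0
DEFAULT_REL_TOL = 0.10
DEFAULT_FLAG_REL = 0.25
DEFAULT_FLAG_ABS_CM3 = 45.0


@dataclass
class CaseRecord:
    """Per-case multi-reader TMTVs (3 or 4 readers; missing allowed)."""

    case_id: str
    readers: dict[str, float]
    subtype: str = ""
    stage: int = 4
    adjudicator_note: str = ""

    @property
    def values(self) -> list[float]:
        return [v for v in self.readers.values() if np.isfinite(v)]


@dataclass(frozen=True)
class AgreementResult:
    case_id: str
    value: float
    reference: float
    abs_diff: float
    rel_diff: float
    passed: bool
    abs_tol: float
    rel_tol: float
    rule: str = "pass iff abs_diff < abs_tol OR rel_diff < rel_tol (strict <)"


@dataclass(frozen=True)
class ICCResult:
    icc: float
    model: str
    n_cases: int
    n_readers: int


@dataclass
class DiffStats:
    mean_diff: float
    sd_diff: float
    pearson_r: float  # NaN when either series is constant
    n: int
    table: pd.DataFrame = field(repr=False, default=None)


@dataclass
class DiscrepancyReport:
    case_id: str
    reference: float
    flagged: bool
    rel_thresh: float
    abs_thresh: float
    deviations: pd.DataFrame = field(repr=False, default=None)


def reference_tmtv(values) -> float:
    """Reference value for a case: the median of the readers' TMTVs.

    For an even reader count this is the mean of the two middle order
    statistics.  Requires at least 2 finite values.
    """
    vals = [float(v) for v in values if v is not None and np.isfinite(v)]
    if len(vals) < 2:
        raise ValueError(f"need >= 2 reader values for a reference, got {len(vals)}")
    return float(np.median(vals))


def agreement(
    value: float,
    reference: float,
    abs_tol: float = DEFAULT_ABS_TOL_CM3,
    rel_tol: float = DEFAULT_REL_TOL,
    case_id: str = "",
) -> AgreementResult:
    """Tolerance-rule concordance of one measurement with its reference."""
    if reference <= 0:
        raise ValueError(f"reference must be positive, got {reference}")
    abs_diff = abs(value - reference)
    rel_diff = abs_diff / reference
    return AgreementResult(
        case_id=case_id,
        value=float(value),
        reference=float(reference),
        abs_diff=float(abs_diff),
        rel_diff=float(rel_diff),
        passed=bool(abs_diff < abs_tol or rel_diff < rel_tol),
        abs_tol=float(abs_tol),
        rel_tol=float(rel_tol),
    )


_ICC_MODEL = "ICC(2,1): two-way random effects, absolute agreement, single rater"


def icc(matrix) -> ICCResult:
    """ICC(2,1) for a cases x readers matrix.

    Rows with any missing (NaN) cell are dropped (case-wise deletion, the
    benchmark mixed 3- and 4-reader cases).  A degenerate panel with zero
    total variance is defined as perfect agreement (ICC 1) with a warning.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D cases x readers matrix")
    m = m[np.isfinite(m).all(axis=1)]
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 complete cases and >= 2 readers, got {n} x {k}")
    if np.allclose(m, m.ravel()[0]):
        log.warning("zero total variance: ICC defined as 1")
        return ICCResult(1.0, _ICC_MODEL, n, k)
    import pingouin as pg  # deferred: heavy import

    long = pd.DataFrame(
        {
            "case": np.repeat(np.arange(n), k),
            "reader": np.tile(np.arange(k), n),
            "tmtv": m.ravel(),
        }
    )
    with np.errstate(invalid="ignore", divide="ignore"):  # degenerate CI arithmetic
        res = pg.intraclass_corr(data=long, targets="case", raters="reader", ratings="tmtv")
    # two-way random / absolute agreement / single rater: labeled ICC2 in
    # older pingouin, ICC(A,1) in the McGraw-Wong naming of newer releases
    sel = res.loc[res["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"]
    val = float(sel.iloc[0])
    return ICCResult(val, _ICC_MODEL, n, k)


def diff_stats(values, references, case_ids=None) -> DiffStats:
    """Paired difference statistics (value - reference) for difference plots.

    ``sd_diff`` is the sample standard deviation (ddof=1); ``pearson_r`` is
    NaN when either series is constant (correlation undefined).
    """
    v = np.asarray(values, dtype=float)
    r = np.asarray(references, dtype=float)
    if v.shape != r.shape:
        raise ValueError(f"length mismatch: {v.shape} vs {r.shape}")
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need paired 1-D inputs of length >= 2")
    diff = v - r
    if np.std(v) == 0 or np.std(r) == 0:
        pear = math.nan
    else:
        pear = float(sstats.pearsonr(v, r).statistic)
    table = pd.DataFrame(
        {
            "case_id": case_ids if case_ids is not None else np.arange(v.size),
            "value": v,
            "reference": r,
            "diff": diff,
            "mean_pair": (v + r) / 2.0,
        }
    )
    return DiffStats(float(diff.mean()), float(diff.std(ddof=1)), pear, int(v.size), table)


def flag_discrepancies(
    record: CaseRecord,
    rel_thresh: float = DEFAULT_FLAG_REL,
    abs_thresh: float = DEFAULT_FLAG_ABS_CM3,
) -> DiscrepancyReport:
    """Flag a case for adjudication when any reader strays from the median.

    A case is flagged iff some reader deviates from the case median by more
    than ``rel_thresh`` (relative to the median) or by more than
    ``abs_thresh`` cm^3.  Per-reader deviations are reported either way.
    """
    finite = {rid: v for rid, v in record.readers.items() if np.isfinite(v)}
    ref = reference_tmtv(list(finite.values()))
    rows = []
    for rid, v in finite.items():
        dev = abs(v - ref)
        rows.append(
            {
                "reader_id": rid,
                "tmtv_cm3": v,
                "abs_dev_cm3": dev,
                "rel_dev": dev / ref,
                "exceeds": bool(dev / ref > rel_thresh or dev > abs_thresh),
            }
        )
    dev_table = pd.DataFrame(rows)
    return DiscrepancyReport(
        case_id=record.case_id,
        reference=ref,
        flagged=bool(dev_table["exceeds"].any()),
        rel_thresh=rel_thresh,
        abs_thresh=abs_thresh,
        deviations=dev_table,
    )


def _as_table(obj, what: str) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj.copy()
    p = Path(obj)
    if not p.exists():
        raise ValidationDataError(f"{what} table not found: {p}")
    return pd.read_csv(p)


def validate_implementation(
    measured,
    reference,
    abs_tol: float = DEFAULT_ABS_TOL_CM3,
    rel_tol: float = DEFAULT_REL_TOL,
) -> dict:
    """Compare a measured TMTV table against a reference table.

    ``measured`` needs columns ``case_id, stage, tmtv_cm3`` (plus optional
    ``reader_id``/``subtype``); ``reference`` needs
    ``case_id, stage, reference_tmtv_cm3``.  Rows are matched on
    (case_id, stage); every matched row is scored with the tolerance rule.
    Returns a JSON-ready report with per-stage pass fractions and the list
    of failures.
    """
    mdf = _as_table(measured, "measured")
    rdf = _as_table(reference, "reference")
    for col in ("case_id", "stage", "tmtv_cm3"):
        if col not in mdf.columns:
            raise ValidationDataError(f"measured table lacks column {col!r}")
    for col in ("case_id", "stage", "reference_tmtv_cm3"):
        if col not in rdf.columns:
            raise ValidationDataError(f"reference table lacks column {col!r}")
    merged = mdf.merge(rdf[["case_id", "stage", "reference_tmtv_cm3"]],
                       on=["case_id", "stage"], how="inner")
    if merged.empty:
        raise ValidationDataError("measured and reference tables share no (case_id, stage) keys")

    results = []
    for _, row in merged.iterrows():
        res = agreement(row["tmtv_cm3"], row["reference_tmtv_cm3"], abs_tol, rel_tol,
                        case_id=str(row["case_id"]))
        entry = asdict(res)
        entry["stage"] = int(row["stage"])
        if "reader_id" in merged.columns:
            entry["reader_id"] = str(row["reader_id"])
        results.append(entry)

    per_stage = {}
    for stage in sorted({e["stage"] for e in results}):
        sub = [e for e in results if e["stage"] == stage]
        n_pass = sum(e["passed"] for e in sub)
        per_stage[f"TMTV{stage}"] = {
            "n": len(sub),
            "n_pass": n_pass,
            "pass_fraction": n_pass / len(sub),
        }
    n_pass = sum(e["passed"] for e in results)
    return {
        "params": {"abs_tol_cm3": abs_tol, "rel_tol": rel_tol,
                   "rule": "pass iff abs_diff < abs_tol OR rel_diff < rel_tol (strict <)"},
        "n": len(results),
        "n_pass": n_pass,
        "pass_fraction": n_pass / len(results),
        "all_pass": n_pass == len(results),
        "per_stage": per_stage,
        "failures": [e for e in results if not e["passed"]],
        "results": results,
    }


def load_discrepant_cases() -> pd.DataFrame:
    """The packaged table of the 8 published benchmark cases adjudicated for
    large inter-reader discrepancies (per-reader final TMTVs in cm^3 plus
    the adjudicator's note; ``note_category`` is 'spleen' for the five
    diffuse-splenic-uptake cases)."""
    path = files("tmtvbench").joinpath("data/benchmark_discrepant_cases.csv")
    with path.open("r") as fh:
        return pd.read_csv(fh)


def discrepant_case_records(df: pd.DataFrame | None = None) -> list[CaseRecord]:
    """Group the packaged (or a same-shaped) table into CaseRecords."""
    if df is None:
        df = load_discrepant_cases()
    records = []
    for case_id, grp in df.groupby("case_id", sort=False):
        records.append(
            CaseRecord(
                case_id=str(case_id),
                readers={str(r): float(v) for r, v in zip(grp["reader_id"], grp["tmtv_cm3"])},
                subtype=str(grp["subtype"].iloc[0]),
                stage=int(grp["stage"].iloc[0]),
                adjudicator_note=str(grp["adjudicator_note"].iloc[0]),
            )
        )
    return records
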