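"""Cohort data model, table I/O, validation and characteristics summary.

A screening cohort is a :class:`pandas.DataFrame` with one row per screening
examination and a fixed, documented column schema (:data:`COHORT_COLUMNS`).
Reader decisions are encoded ``{0 = normal, 1 = recall}``; an empty cell
means *absent* (no recorded arbitration, no cancer). Dates are ISO-8601
strings. A cancer record is present on a row exactly when ``dx_offset_days``
is non-missing; tumour attributes that apply to invasive cancers only
(size, grade, TNM, nodes, ER, HER2) must be absent or ``"unknown"`` for
DCIS.

Files are CSV (RFC 4180) or TSV, transparently gzip-compressed by file
extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

NORMAL = 0
RECALL = 1

#: Mandatory columns, in canonical order.
COHORT_COLUMNS: tuple[str, ...] = (
    "exam_id",
    "woman_id",
    "site",
    "age_years",
    "screen_date",
    "reader1",
    "reader2",
    "arbitration",
    "ai_score",
    "dx_offset_days",
    "next_screen_offset_days",
    "invasive",
    "subtype",
    "size_class",
    "grade",
    "tnm",
    "node_positive",
    "er",
    "her2",
)

#: Columns that describe the cancer record (absent on cancer-free exams).
CANCER_COLUMNS: tuple[str, ...] = (
    "dx_offset_days",
    "next_screen_offset_days",
    "invasive",
    "subtype",
    "size_class",
    "grade",
    "tnm",
    "node_positive",
    "er",
    "her2",
)

#: Tumour attributes reported for invasive cancers only.
INVASIVE_ONLY_COLUMNS: tuple[str, ...] = (
    "size_class",
    "grade",
    "tnm",
    "node_positive",
    "er",
    "her2",
)

SUBTYPE_LEVELS = ("invasive ductal", "invasive lobular", "other invasive", "DCIS")
SIZE_LEVELS = ("0-10 mm", "11-20 mm", "21-50 mm", "51+ mm", "unknown")
GRADE_LEVELS = ("1", "2", "3", "unknown")
TNM_LEVELS = ("local I+II", "locally advanced III", "distant metastasis IV", "unknown")
NODE_LEVELS = ("no", "yes")
ER_LEVELS = ("0%", "1-9%", "10-100%", "unknown")
HER2_LEVELS = ("negative", "positive", "unknown")

_DECISION_VALUES = {0, 1}


class CohortError(ValueError):
    """Base class for cohort schema/validation problems."""


class SchemaError(CohortError):
    """The file header does not match the documented column schema."""


class ValidationError(CohortError):
    """Row-level contract violations; carries the offending exam ids."""

    def __init__(self, message: str, exam_ids: Sequence[str] = ()):  # noqa: D107
        super().__init__(message)
        self.exam_ids = list(exam_ids)


class IncompleteRecordError(CohortError):
    """A historical record is missing a required decision (e.g. arbitration)."""

    def __init__(self, message: str, exam_ids: Sequence[str] = ()):  # noqa: D107
        super().__init__(message)
        self.exam_ids = list(exam_ids)


@dataclass(frozen=True)
class CancerRecord:
    """Outcome linkage for one cancer: timing and tumour characteristics."""

    dx_offset_days: int
    next_screen_offset_days: int | None = None
    invasive: bool | None = None
    subtype: str | None = None
    size_class: str | None = None
    grade: str | None = None
    tnm: str | None = None
    node_positive: str | None = None
    er: str | None = None
    her2: str | None = None

    def __post_init__(self) -> None:
        if self.dx_offset_days < 0:
            raise ValidationError("dx_offset_days must be >= 0")
        if self.subtype == "DCIS":
            for name in INVASIVE_ONLY_COLUMNS:
                value = getattr(self, name)
                if value not in (None, "unknown"):
                    raise ValidationError(
                        f"invasive-only attribute {name!r}={value!r} set on a DCIS record"
                    )


@dataclass(frozen=True)
class ScreeningExam:
    """One screening examination: reader decisions, AI score, outcome linkage."""

    exam_id: str
    woman_id: str
    site: str
    age_years: float
    screen_date: str
    reader1: int
    reader2: int
    ai_score: float
    arbitration: int | None = None
    cancer: CancerRecord | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.ai_score <= 10.0):
            raise ValidationError(
                f"ai_score {self.ai_score} outside [0, 10]", [self.exam_id]
            )
        for name in ("reader1", "reader2"):
            if getattr(self, name) not in _DECISION_VALUES:
                raise ValidationError(f"{name} must be 0 or 1", [self.exam_id])
        if self.arbitration is not None and self.arbitration not in _DECISION_VALUES:
            raise ValidationError("arbitration must be 0, 1 or absent", [self.exam_id])


def exam_to_row(exam: ScreeningExam) -> dict:
    """Flatten a :class:`ScreeningExam` into a schema row (dict of scalars)."""
    row: dict = {c: None for c in COHORT_COLUMNS}
    for name in ("exam_id", "woman_id", "site", "age_years", "screen_date",
                 "reader1", "reader2", "arbitration", "ai_score"):
        row[name] = getattr(exam, name)
    if exam.cancer is not None:
        for name in CANCER_COLUMNS:
            row[name] = getattr(exam.cancer, name)
    return row


def row_to_exam(row: Mapping) -> ScreeningExam:
    """Build a validated :class:`ScreeningExam` from a schema row."""
    def _opt(v):
        return None if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA else v

    cancer = None
    if _opt(row["dx_offset_days"]) is not None:
        nso = _opt(row["next_screen_offset_days"])
        inv = _opt(row["invasive"])
        cancer = CancerRecord(
            dx_offset_days=int(row["dx_offset_days"]),
            next_screen_offset_days=None if nso is None else int(nso),
            invasive=None if inv is None else bool(inv),
            subtype=_opt(row["subtype"]),
            size_class=_opt(row["size_class"]),
            grade=_opt(row["grade"]),
            tnm=_opt(row["tnm"]),
            node_positive=_opt(row["node_positive"]),
            er=_opt(row["er"]),
            her2=_opt(row["her2"]),
        )
    arb = _opt(row["arbitration"])
    return ScreeningExam(
        exam_id=str(row["exam_id"]),
        woman_id=str(row["woman_id"]),
        site=str(row["site"]),
        age_years=float(row["age_years"]),
        screen_date=str(row["screen_date"]),
        reader1=int(row["reader1"]),
        reader2=int(row["reader2"]),
        arbitration=None if arb is None else int(arb),
        ai_score=float(row["ai_score"]),
        cancer=cancer,
    )


def _empty_frame(n: int) -> pd.DataFrame:
    return pd.DataFrame(index=range(n), columns=list(COHORT_COLUMNS))


def cohort_from_exams(exams: Iterable[ScreeningExam]) -> pd.DataFrame:
    """Assemble a cohort table from ScreeningExam objects (row order kept)."""
    rows = [exam_to_row(e) for e in exams]
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return _coerce_dtypes(df)


def _coerce_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["exam_id"] = df["exam_id"].astype(str)
    df["woman_id"] = df["woman_id"].astype(str)
    df["site"] = df["site"].astype(str)
    df["screen_date"] = df["screen_date"].astype(str)
    df["age_years"] = df["age_years"].astype(float)
    df["ai_score"] = df["ai_score"].astype(float)
    for col in ("reader1", "reader2"):
        df[col] = df[col].astype("int8")
    df["arbitration"] = df["arbitration"].astype("Int8")
    for col in ("dx_offset_days", "next_screen_offset_days"):
        df[col] = df[col].astype("Int64")
    df["invasive"] = df["invasive"].astype("boolean")
    for col in ("subtype", "size_class", "grade", "tnm", "node_positive", "er", "her2"):
        df[col] = df[col].astype("string")
    return df


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema and row-level invariants; return the coerced frame.

    Raises
    ------
    SchemaError
        If a mandatory column is missing.
    ValidationError
        On out-of-range AI scores, invalid decisions, duplicate exam ids,
        negative diagnosis offsets or invasive-only attributes on DCIS;
        the exception lists the offending ``exam_id`` values.
    """
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    df = _coerce_dtypes(df[list(COHORT_COLUMNS)])

    dup = df["exam_id"][df["exam_id"].duplicated()].unique()
    if len(dup):
        raise ValidationError(
            f"duplicate exam_id values: {', '.join(map(str, dup[:10]))}", list(dup)
        )
    bad_score = df.loc[(df["ai_score"] < 0) | (df["ai_score"] > 10) | df["ai_score"].isna(), "exam_id"]
    if len(bad_score):
        raise ValidationError(
            "ai_score outside [0, 10] for exam(s): " + ", ".join(bad_score.head(10)),
            list(bad_score),
        )
    for col in ("reader1", "reader2"):
        bad = df.loc[~df[col].isin([0, 1]), "exam_id"]
        if len(bad):
            raise ValidationError(f"{col} not in {{0,1}} for exam(s): " + ", ".join(bad.head(10)), list(bad))
    arb = df["arbitration"]
    bad = df.loc[arb.notna() & ~arb.isin([0, 1]), "exam_id"]
    if len(bad):
        raise ValidationError("arbitration not in {0,1} for exam(s): " + ", ".join(bad.head(10)), list(bad))

    has_cancer = df["dx_offset_days"].notna()
    bad = df.loc[has_cancer & (df["dx_offset_days"] < 0), "exam_id"]
    if len(bad):
        raise ValidationError("negative dx_offset_days for exam(s): " + ", ".join(bad.head(10)), list(bad))
    dcis = has_cancer & (df["subtype"] == "DCIS")
    for col in INVASIVE_ONLY_COLUMNS:
        bad = df.loc[dcis & df[col].notna() & (df[col] != "unknown"), "exam_id"]
        if len(bad):
            raise ValidationError(
                f"invasive-only attribute {col!r} set on DCIS exam(s): " + ", ".join(bad.head(10)),
                list(bad),
            )
    return df


def read_cohort(path, *, sep: str | None = None, validate: bool = True) -> pd.DataFrame:
    """Read a cohort table from CSV/TSV (gzip-transparent) and validate it.

    Parameters
    ----------
    path
        File path; ``.tsv``/``.txt`` select tab separation unless *sep* is
        given, ``.gz`` is decompressed transparently.
    sep
        Field separator override.
    validate
        Run :func:`validate_cohort` (default).
    """
    p = str(path)
    if sep is None:
        stem = p[:-3] if p.endswith(".gz") else p
        sep = "\t" if stem.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(
        p,
        sep=sep,
        dtype={
            "exam_id": str, "woman_id": str, "site": str, "screen_date": str,
            # categorical levels like "1"/"2"/"3" must not be numerified
            "subtype": str, "size_class": str, "grade": str, "tnm": str,
            "node_positive": str, "er": str, "her2": str,
        },
        keep_default_na=True,
        na_values=[""],
        compression="infer",
    )
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    return validate_cohort(df) if validate else _coerce_dtypes(df[list(COHORT_COLUMNS)])


def write_cohort(df: pd.DataFrame, path, *, sep: str | None = None) -> None:
    """Write a cohort table (CSV/TSV, gzip by extension); absent values as empty cells."""
    p = str(path)
    if sep is None:
        stem = p[:-3] if p.endswith(".gz") else p
        sep = "\t" if stem.endswith((".tsv", ".txt")) else ","
    out = df.copy()
    # Int64/boolean columns render without trailing '.0'; NA renders empty.
    out.to_csv(p, sep=sep, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Combined double-reading outcome
# ---------------------------------------------------------------------------

def combined_reading_outcome(exam: ScreeningExam | Mapping) -> tuple[int, bool]:
    """Final decision of double reading with arbitration for one exam.

    Concordant readers give their shared decision unless an arbitration was
    recorded anyway (a small overlap of studies carries a recorded
    arbitration despite reader agreement, and the recorded decision then
    rules); discordant readers require a recorded arbitration, whose
    decision rules.

    Returns ``(decision, arbitrated)``.
    """
    if isinstance(exam, ScreeningExam):
        r1, r2, arb, eid = exam.reader1, exam.reader2, exam.arbitration, exam.exam_id
    else:
        r1, r2, arb, eid = exam["reader1"], exam["reader2"], exam["arbitration"], exam["exam_id"]
        if arb is pd.NA or (isinstance(arb, float) and np.isnan(arb)):
            arb = None
    if arb is not None:
        return int(arb), True
    if r1 == r2:
        return int(r1), False
    raise IncompleteRecordError(
        f"reader disagreement without recorded arbitration on exam {eid}", [str(eid)]
    )


def combined_reading_outcomes(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`combined_reading_outcome` over a cohort.

    Returns ``(decisions, arbitrated)`` aligned with the frame; raises
    :class:`IncompleteRecordError` listing every discordant exam that lacks
    a recorded arbitration.
    """
    r1 = df["reader1"].to_numpy(dtype=np.int8)
    r2 = df["reader2"].to_numpy(dtype=np.int8)
    has_arb = df["arbitration"].notna().to_numpy()
    arb = df["arbitration"].fillna(0).to_numpy(dtype=np.int8)
    incomplete = (r1 != r2) & ~has_arb
    if incomplete.any():
        ids = df.loc[incomplete, "exam_id"]
        raise IncompleteRecordError(
            f"{incomplete.sum()} discordant exam(s) lack a recorded arbitration: "
            + ", ".join(ids.head(10)),
            list(ids),
        )
    decision = np.where(has_arb, arb, r1).astype(np.int8)
    return decision, has_arb


# ---------------------------------------------------------------------------
# Table-1-style characteristics summary
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    """Clinical characteristics of a cohort (counts with stated denominators)."""

    n_exams: int
    n_women: int
    site_counts: dict[str, int]
    age_mean: float
    age_sd: float
    n_cancers: int
    n_screen_detected: int
    n_interval: int
    n_invasive: int
    n_dcis: int
    n_abnormal: int
    n_normal: int
    n_arbitrations: int
    n_reader_agreement: int
    extras: dict[str, int] = field(default_factory=dict)

    @property
    def abnormal_rate(self) -> float:
        return self.n_abnormal / self.n_exams

    @property
    def cancer_prevalence(self) -> float:
        return self.n_cancers / self.n_exams

    @property
    def reader_agreement_rate(self) -> float:
        return self.n_reader_agreement / self.n_exams

    @property
    def detection_rate_per_1000(self) -> float:
        """Screen-detected cancers per 1000 screening exams."""
        return 1000.0 * self.n_screen_detected / self.n_exams

    def to_frame(self) -> pd.DataFrame:
        """Machine-readable long-format rendering (item, count, denominator, pct)."""
        rows: list[tuple[str, float, int]] = []

        def add(item: str, count: float, denom: int) -> None:
            rows.append((item, count, denom))

        add("exams", self.n_exams, self.n_exams)
        add("women", self.n_women, self.n_exams)
        for site, n in sorted(self.site_counts.items()):
            add(f"site:{site}", n, self.n_exams)
        add("cancers", self.n_cancers, self.n_exams)
        add("screen_detected", self.n_screen_detected, self.n_cancers)
        add("interval", self.n_interval, self.n_cancers)
        add("invasive", self.n_invasive, self.n_cancers)
        add("DCIS", self.n_dcis, self.n_cancers)
        add("outcome_normal", self.n_normal, self.n_exams)
        add("outcome_abnormal", self.n_abnormal, self.n_exams)
        add("arbitrations", self.n_arbitrations, self.n_exams)
        add("reader_agreement", self.n_reader_agreement, self.n_exams)
        df = pd.DataFrame(rows, columns=["item", "count", "denominator"])
        df["percent"] = 100.0 * df["count"] / df["denominator"].where(df["denominator"] > 0, np.nan)
        return df

    def to_text(self) -> str:
        lines = [f"Screening cohort: {self.n_exams:,} exams from {self.n_women:,} women",
                 f"  age {self.age_mean:.1f} ({self.age_sd:.1f}) years"]
        for site, n in sorted(self.site_counts.items()):
            lines.append(f"  site {site}: {n:,} ({100 * n / self.n_exams:.1f}%)")
        d = max(self.n_cancers, 1)
        lines += [
            f"  cancers: {self.n_cancers:,} ({100 * self.cancer_prevalence:.1f}%)",
            f"    screen-detected {self.n_screen_detected:,} ({100 * self.n_screen_detected / d:.1f}%), "
            f"interval {self.n_interval:,} ({100 * self.n_interval / d:.1f}%)",
            f"    invasive {self.n_invasive:,} ({100 * self.n_invasive / d:.1f}%), "
            f"DCIS {self.n_dcis:,} ({100 * self.n_dcis / d:.1f}%)",
            f"  combined outcome: normal {self.n_normal:,} ({100 * self.n_normal / self.n_exams:.1f}%), "
            f"abnormal {self.n_abnormal:,} ({100 * self.abnormal_rate:.1f}%)",
            f"  arbitrations: {self.n_arbitrations:,} ({100 * self.n_arbitrations / self.n_exams:.1f}%)",
            f"  inter-reader agreement: {self.n_reader_agreement:,} "
            f"({100 * self.reader_agreement_rate:.1f}%)",
        ]
        return "\n".join(lines)


def summarize_cohort(df: pd.DataFrame, *, window_days: int = 730) -> CohortSummary:
    """Tally the cohort characteristics (counts on their stated denominators).

    Cancer-category percentages are on the cancer count, outcome percentages
    on the exam count. Screen-detected/interval classification follows the
    reference standard convention (``dx_offset_days == 0`` vs an interval
    diagnosis inside the follow-up window).
    """
    if len(df) == 0:
        raise CohortError("empty cohort")
    from .reference import classify_outcomes  # local import to avoid a cycle

    decisions, arbitrated = combined_reading_outcomes(df)
    labels = classify_outcomes(df, window_days=window_days)
    cat = labels["category"]
    positive = labels["positive"].to_numpy()
    n_sd = int((cat == "screen_detected").sum())
    n_iv = int(cat.isin(["interval_lt12", "interval_ge12"]).sum())
    has_cancer = positive
    inv = df["invasive"].fillna(False).to_numpy(dtype=bool)
    return CohortSummary(
        n_exams=len(df),
        n_women=int(df["woman_id"].nunique()),
        site_counts={str(k): int(v) for k, v in df["site"].value_counts().items()},
        age_mean=float(df["age_years"].mean()),
        age_sd=float(df["age_years"].std(ddof=1)) if len(df) > 1 else 0.0,
        n_cancers=int(has_cancer.sum()),
        n_screen_detected=n_sd,
        n_interval=n_iv,
        n_invasive=int((has_cancer & inv).sum()),
        n_dcis=int((has_cancer & (df["subtype"] == "DCIS")).sum()),
        n_abnormal=int(decisions.sum()),
        n_normal=int((decisions == 0).sum()),
        n_arbitrations=int(arbitrated.sum()),
        n_reader_agreement=int((df["reader1"].to_numpy() == df["reader2"].to_numpy()).sum()),
    )
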