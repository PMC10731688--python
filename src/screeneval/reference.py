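"""Reference-standard outcome classification.

The primary reference standard labels an exam positive when a
histopathologically verified breast cancer (invasive or DCIS) is attributed
to the index screen (``dx_offset_days == 0``, i.e. diagnosed through the
recall work-up) or diagnosed in the interval before the next consecutive
screening and within 24 months. Interval cancers split at 12 months
(< 365 d vs >= 365 d). Everything else — cancer-free follow-up, next-round
screen-detected cancers, long-term cancers — is negative under the primary
standard.

The exploratory *extended* standard additionally counts next-round cancers
(diagnosed at the subsequent screening) and long-term cancers (> 2 and
<= ``long_term_max_years`` years after screening) as positive, leaving all
screening decisions untouched: scenario decisions are simply re-scored
against the wider truth labels.

Day-level conventions (half-open windows) are fixed here and configurable:
interval requires ``0 < dx <= min(window_days, next_screen - 1)``; the
12-month split is right-open at 365 days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ScreeningExam, ValidationError

CATEGORIES = ("negative", "screen_detected", "interval_lt12", "interval_ge12",
              "next_round", "long_term")

DAYS_PER_YEAR = 365
DEFAULT_WINDOW_DAYS = 730


@dataclass(frozen=True)
class OutcomeLabel:
    """Ground-truth classification of one exam under a chosen standard.

    ``category`` is the label under the chosen standard (``negative`` for
    anything not positive under it); ``extended_category`` retains the
    next-round/long-term metadata even when the primary standard scores the
    exam negative. ``basis`` records which censoring rule fired:
    ``diagnosis`` (a counted cancer), ``next_screen_censor`` or
    ``fixed_window_censor``.
    """

    positive: bool
    category: str
    basis: str
    extended_category: str = "negative"


def _classify_offsets(
    dx: float | None,
    next_screen: float | None,
    window_days: int,
    long_term_max_years: float,
) -> tuple[str, str]:
    """Return (primary category, extended-metadata category) for one cancer."""
    if dx is None:
        return "negative", "negative"
    if dx < 0:
        raise ValidationError("negative dx_offset_days")
    if dx == 0:
        return "screen_detected", "screen_detected"
    limit = window_days if next_screen is None else min(window_days, next_screen - 1)
    if dx <= limit:
        cat = "interval_lt12" if dx < DAYS_PER_YEAR else "interval_ge12"
        return cat, cat
    # Beyond the primary window: metadata only.
    if next_screen is not None and dx == next_screen:
        return "negative", "next_round"
    if window_days < dx <= long_term_max_years * DAYS_PER_YEAR:
        return "negative", "long_term"
    return "negative", "negative"


def classify_outcome(
    exam: ScreeningExam,
    window_days: int = DEFAULT_WINDOW_DAYS,
    *,
    long_term_max_years: float = 7.0,
) -> OutcomeLabel:
    """Classify one exam under the primary (24-month) reference standard."""
    if exam.cancer is None:
        return OutcomeLabel(False, "negative", "fixed_window_censor")
    dx = exam.cancer.dx_offset_days
    ns = exam.cancer.next_screen_offset_days
    cat, ext = _classify_offsets(dx, ns, window_days, long_term_max_years)
    if cat != "negative":
        basis = "diagnosis"
    elif ns is not None and ns - 1 < window_days:
        basis = "next_screen_censor"
    else:
        basis = "fixed_window_censor"
    return OutcomeLabel(cat != "negative", cat, basis, ext)


def classify_outcome_extended(
    exam: ScreeningExam,
    window_days: int = DEFAULT_WINDOW_DAYS,
    long_term_max_years: float = 7.0,
) -> OutcomeLabel:
    """Classify one exam with next-round and long-term cancers counted positive."""
    primary = classify_outcome(exam, window_days, long_term_max_years=long_term_max_years)
    ext = primary.extended_category
    if primary.positive or ext == "negative":
        return primary
    return OutcomeLabel(True, ext, "diagnosis", ext)


def classify_outcomes(
    df: pd.DataFrame,
    window_days: int = DEFAULT_WINDOW_DAYS,
    *,
    extended: bool = False,
    long_term_max_years: float = 7.0,
    recalled=None,
    recall_attribution_days: int = 0,
) -> pd.DataFrame:
    """Vectorised outcome classification over a cohort.

    Returns a frame aligned with *df* holding ``positive`` (bool),
    ``category``, ``extended_category`` and ``basis``. With
    ``extended=True`` the positive set widens to include next-round and
    long-term cancers (a superset of the primary positives).

    Whether a cancer diagnosed a few days *after* a recalled (abnormal)
    screen is attributed to the screen or counted as an interval cancer is
    a labelling convention: passing a boolean ``recalled`` vector together
    with ``recall_attribution_days > 0`` re-labels cancers diagnosed within
    that many days of a recalled exam as screen-detected. The default (0)
    keeps the strict ``dx_offset_days == 0`` convention.
    """
    n = len(df)
    dx = df["dx_offset_days"].to_numpy(dtype="float64", na_value=np.nan)
    ns = df["next_screen_offset_days"].to_numpy(dtype="float64", na_value=np.nan)
    if np.nanmin(dx, initial=0.0) < 0:
        bad = df.loc[dx < 0, "exam_id"]
        raise ValidationError("negative dx_offset_days", list(bad))

    has = ~np.isnan(dx)
    limit = np.where(np.isnan(ns), float(window_days), np.minimum(window_days, ns - 1))

    cat = np.full(n, "negative", dtype=object)
    ext = np.full(n, "negative", dtype=object)
    sd = has & (dx == 0)
    if recall_attribution_days > 0 and recalled is not None:
        recalled = np.asarray(recalled, dtype=bool)
        sd |= has & recalled & (dx > 0) & (dx <= recall_attribution_days)
    interval = has & ~sd & (dx > 0) & (dx <= limit)
    lt12 = interval & (dx < DAYS_PER_YEAR)
    cat[sd] = ext[sd] = "screen_detected"
    cat[lt12] = ext[lt12] = "interval_lt12"
    cat[interval & ~lt12] = ext[interval & ~lt12] = "interval_ge12"
    beyond = has & (dx > limit)
    nr = beyond & ~np.isnan(ns) & (dx == ns)
    lt = beyond & ~nr & (dx > window_days) & (dx <= long_term_max_years * DAYS_PER_YEAR)
    ext[nr] = "next_round"
    ext[lt] = "long_term"

    basis = np.full(n, "fixed_window_censor", dtype=object)
    basis[~np.isnan(ns) & (ns - 1 < window_days)] = "next_screen_censor"
    basis[cat != "negative"] = "diagnosis"
    if extended:
        widened = (cat == "negative") & (ext != "negative")
        cat = cat.copy()
        cat[widened] = ext[widened]
        basis[widened] = "diagnosis"

    return pd.DataFrame(
        {
            "positive": cat != "negative",
            "category": pd.Categorical(cat, categories=list(CATEGORIES)),
            "extended_category": pd.Categorical(ext, categories=list(CATEGORIES)),
            "basis": basis,
        },
        index=df.index,
    )


def truth_vector(df: pd.DataFrame, *, extended: bool = False,
                 window_days: int = DEFAULT_WINDOW_DAYS) -> np.ndarray:
    """Boolean ground-truth vector (positive under the chosen standard)."""
    return classify_outcomes(df, window_days=window_days, extended=extended)["positive"].to_numpy()
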