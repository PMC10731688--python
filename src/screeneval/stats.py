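"""Diagnostic-accuracy battery: exact intervals, paired tests, subgroup tables.

Endpoints per scenario are sensitivity and specificity (coprimary) and PPV,
NPV, recall rate and arbitration rate (secondary), each an exact ratio of
integer counts with a 95% Clopper-Pearson interval. Two scenarios on the
same cohort and truth labelling are compared pairwise: McNemar's test on
the discordant decision pairs (exact two-sided binomial fallback when the
discordant total is small) for sensitivity, specificity and arbitration
rate; exact McNemar-style binomial tests on paired indicators for the
secondary proportion endpoints.

Subgroup detection tables report detected/total cancers per cancer category
and tumour-characteristic level (invasive cancers only for size, grade,
TNM, nodes, ER, HER2), with paired p-values against a reference scenario.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import INVASIVE_ONLY_COLUMNS
from .scenarios import COMBINED_READING, INTEGRATED_AI, ScenarioResult

MCNEMAR_EXACT = "mcnemar_exact"
MCNEMAR_ASYMPTOTIC = "mcnemar_asymptotic"
EXACT_BINOMIAL = "exact_binomial"

#: Endpoints that Table-2-style reports carry, in order.
ENDPOINTS = ("sensitivity", "specificity", "ppv", "npv", "recall_rate", "arbitration_rate")


class StatsError(ValueError):
    """Invalid counts or mismatched inputs."""


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 decision-vs-truth counts for one scenario."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise StatsError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def recalls(self) -> int:
        return self.tp + self.fp

    @property
    def sensitivity(self) -> float:
        return self.tp / self.positives

    @property
    def specificity(self) -> float:
        return self.tn / self.negatives

    @property
    def ppv(self) -> float:
        return self.tp / self.recalls

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn)

    @property
    def recall_rate(self) -> float:
        return self.recalls / self.n


def confusion(decisions, truth) -> ConfusionCounts:
    """Tally the exhaustive 2x2 partition of exams (aligned by position)."""
    d = np.asarray(decisions).astype(bool)
    t = np.asarray(truth).astype(bool)
    if d.shape != t.shape:
        raise StatsError("decisions and truth must have equal length")
    return ConfusionCounts(
        tp=int((d & t).sum()),
        fp=int((d & ~t).sum()),
        tn=int((~d & ~t).sum()),
        fn=int((~d & t).sum()),
    )


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided confidence interval for k/n.

    Computed from beta quantiles, the standard inversion of the binomial
    tails; the lower bound is 0 when ``k == 0`` and the upper bound 1 when
    ``k == n``.
    """
    if not (0 <= k <= n) or n < 1:
        raise StatsError(f"invalid counts k={k}, n={n}")
    low = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def mcnemar_test(b: int, c: int, small_cutoff: int = 25, *,
                 continuity: bool = False) -> tuple[float, str]:
    """Paired test on the discordant counts of two classifiers.

    ``b`` and ``c`` are the two discordant cells. When ``b + c <
    small_cutoff`` the exact two-sided binomial test of ``b`` successes in
    ``b + c`` trials at probability 1/2 is used; otherwise the asymptotic
    McNemar chi-square with 1 df, by default without continuity correction
    (``continuity=True`` gives the corrected variant). Returns ``(p,
    method)`` with p capped at 1; ``b + c == 0`` gives p = 1.
    """
    if b < 0 or c < 0:
        raise StatsError("discordant counts must be non-negative")
    m = b + c
    if m == 0:
        return 1.0, MCNEMAR_EXACT
    if m < small_cutoff:
        p = float(sps.binomtest(b, m, 0.5).pvalue)
        return min(p, 1.0), MCNEMAR_EXACT
    adj = max(abs(b - c) - 1, 0) if continuity else abs(b - c)
    chi2 = adj * adj / m
    return float(sps.chi2.sf(chi2, 1)), MCNEMAR_ASYMPTOTIC


def exact_binomial_paired(b: int, c: int) -> tuple[float, str]:
    """Exact two-sided binomial test on discordant paired indicators (no
    asymptotic branch) — the secondary-endpoint procedure."""
    if b < 0 or c < 0:
        raise StatsError("discordant counts must be non-negative")
    if b + c == 0:
        return 1.0, EXACT_BINOMIAL
    return min(float(sps.binomtest(b, b + c, 0.5).pvalue), 1.0), EXACT_BINOMIAL


def _discordant(x_a: np.ndarray, x_b: np.ndarray) -> tuple[int, int]:
    return int((x_a & ~x_b).sum()), int((~x_a & x_b).sum())


@dataclass
class EndpointRow:
    """One endpoint's estimate, interval and paired comparison."""

    endpoint: str
    k: int
    n: int
    estimate: float
    ci_low: float
    ci_high: float
    comparator_k: int | None = None
    comparator_n: int | None = None
    comparator_estimate: float | None = None
    p_value: float | None = None
    method: str | None = None
    b: int | None = None  # discordant: index-only cell
    c: int | None = None  # discordant: comparator-only cell


@dataclass
class AccuracyReport:
    """Endpoint battery for one scenario, optionally against a comparator."""

    scenario: str
    comparator: str | None
    rows: list[EndpointRow]
    extras: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.rows])
        return df.astype({
            "comparator_k": "Int64", "comparator_n": "Int64",
            "comparator_estimate": "Float64", "p_value": "Float64",
            "method": "string", "b": "Int64", "c": "Int64",
        })

    def __getitem__(self, endpoint: str) -> EndpointRow:
        for r in self.rows:
            if r.endpoint == endpoint:
                return r
        raise KeyError(endpoint)

    def to_text(self) -> str:
        head = f"Accuracy: {self.scenario}"
        if self.comparator:
            head += f" vs {self.comparator}"
        lines = [head]
        for r in self.rows:
            line = (f"  {r.endpoint:<17}{100 * r.estimate:6.1f}% "
                    f"({100 * r.ci_low:.1f}-{100 * r.ci_high:.1f})"
                    f"  [{r.k}/{r.n}]")
            if r.p_value is not None:
                line += f"  p={format_p(r.p_value)} ({r.method})"
            lines.append(line)
        return "\n".join(lines)


def format_p(p: float) -> str:
    """The report style for p-values: two significant figures, '<0.0001' floor."""
    if p < 1e-4:
        return "<0.0001"
    if p > 0.99:
        return ">0.99"
    return f"{p:.2g}"


def _endpoint_counts(result: ScenarioResult, truth: np.ndarray) -> dict[str, tuple[int, int]]:
    cm = confusion(result.decisions, truth)
    counts = {
        "sensitivity": (cm.tp, cm.positives),
        "specificity": (cm.tn, cm.negatives),
        "ppv": (cm.tp, cm.recalls),
        "npv": (cm.tn, cm.tn + cm.fn),
        "recall_rate": (cm.recalls, cm.n),
    }
    if result.scenario in (COMBINED_READING, INTEGRATED_AI):
        counts["arbitration_rate"] = (result.n_arbitrations, result.n_exams)
    return counts


def _label(result: ScenarioResult) -> str:
    if result.threshold_mode in (None, "none"):
        return result.scenario
    return f"{result.scenario}[{result.threshold_mode}]"


def accuracy_report(result: ScenarioResult, truth) -> AccuracyReport:
    """Endpoint estimates with Clopper-Pearson intervals, no comparison."""
    truth = np.asarray(truth, dtype=bool)
    rows = []
    for name, (k, n) in _endpoint_counts(result, truth).items():
        low, high = clopper_pearson(k, n)
        rows.append(EndpointRow(name, k, n, k / n, low, high))
    return AccuracyReport(_label(result), None, rows)


def compare_scenarios(
    result_a: ScenarioResult,
    result_b: ScenarioResult,
    truth,
    *,
    small_cutoff: int = 25,
    ppv_variant: str = "restricted",
) -> AccuracyReport:
    """Paired endpoint comparison of scenario *a* (index) against *b* (reference).

    Sensitivity and specificity use McNemar's test on the positive/negative
    subsets; the arbitration rate uses McNemar on paired arbitration
    indicators; recall rate, PPV and NPV use exact McNemar-style binomial
    tests on paired indicators. For PPV/NPV the default pairing restricts
    to exams recalled (resp. cleared) by *both* scenarios — degenerate
    (p = 1) under a shared reference standard and kept for completeness —
    while ``ppv_variant="either"`` pairs the recalled-and-correct
    indicator over exams recalled by either scenario; both discordant
    counts are reported either way.
    """
    truth = np.asarray(truth, dtype=bool)
    if result_a.n_exams != result_b.n_exams or len(truth) != result_a.n_exams:
        raise StatsError("scenario results and truth must cover the same cohort")
    if not np.array_equal(result_a.exam_ids, result_b.exam_ids):
        raise StatsError("scenario results are not aligned on the same exams")
    if ppv_variant not in ("restricted", "either"):
        raise StatsError(f"unknown ppv_variant {ppv_variant!r}")

    d_a = result_a.decisions.astype(bool)
    d_b = result_b.decisions.astype(bool)
    counts_a = _endpoint_counts(result_a, truth)
    counts_b = _endpoint_counts(result_b, truth)

    rows: list[EndpointRow] = []
    for name in ENDPOINTS:
        if name not in counts_a:
            continue
        k, n = counts_a[name]
        low, high = clopper_pearson(k, n)
        row = EndpointRow(name, k, n, k / n, low, high)
        if name in counts_b:
            kb, nb = counts_b[name]
            row.comparator_k, row.comparator_n = kb, nb
            row.comparator_estimate = kb / nb

            if name == "sensitivity":
                b, c = _discordant(d_a[truth], d_b[truth])
                p, method = mcnemar_test(b, c, small_cutoff)
            elif name == "specificity":
                b, c = _discordant(~d_a[~truth], ~d_b[~truth])
                p, method = mcnemar_test(b, c, small_cutoff)
            elif name == "arbitration_rate":
                b, c = _discordant(result_a.arbitrated, result_b.arbitrated)
                p, method = mcnemar_test(b, c, small_cutoff)
            elif name == "recall_rate":
                b, c = _discordant(d_a, d_b)
                p, method = exact_binomial_paired(b, c)
            elif name == "ppv":
                if ppv_variant == "restricted":
                    both = d_a & d_b
                    b, c = _discordant(truth[both], truth[both])
                else:
                    either = d_a | d_b
                    b, c = _discordant((d_a & truth)[either], (d_b & truth)[either])
                p, method = exact_binomial_paired(b, c)
            else:  # npv
                if ppv_variant == "restricted":
                    both = ~d_a & ~d_b
                    b, c = _discordant(~truth[both], ~truth[both])
                else:
                    either = ~d_a | ~d_b
                    b, c = _discordant((~d_a & ~truth)[either], (~d_b & ~truth)[either])
                p, method = exact_binomial_paired(b, c)
            row.p_value, row.method, row.b, row.c = p, method, b, c
        rows.append(row)
    return AccuracyReport(_label(result_a), _label(result_b), rows,
                          extras={"ppv_variant": ppv_variant})


# ---------------------------------------------------------------------------
# Subgroup detection tables and agreement cross-tabs
# ---------------------------------------------------------------------------

#: Subgroup variables reported for invasive cancers only.
INVASIVE_ONLY_VARS = tuple(INVASIVE_ONLY_COLUMNS)


def _subgroup_masks(df: pd.DataFrame, labels: pd.DataFrame,
                    subgroup_fields: tuple[str, ...]) -> list[tuple[str, str, np.ndarray]]:
    cat = labels["category"].astype(str).to_numpy()
    cancer = labels["positive"].to_numpy()
    interval = np.isin(cat, ("interval_lt12", "interval_ge12"))
    rows = [
        ("all", "all cancers", cancer),
        ("category", "screen_detected", cat == "screen_detected"),
        ("category", "interval", interval),
        ("category", "interval_lt12", cat == "interval_lt12"),
        ("category", "interval_ge12", cat == "interval_ge12"),
    ]
    invasive = cancer & df["invasive"].fillna(False).to_numpy(dtype=bool)
    for var in subgroup_fields:
        base = invasive if var in INVASIVE_ONLY_VARS else cancer
        values = df[var].fillna("unknown").astype(str).to_numpy()
        for level in pd.unique(values[base]):
            rows.append((var, str(level), base & (values == level)))
    return rows


def detection_table(
    results: list[ScenarioResult],
    df: pd.DataFrame,
    labels: pd.DataFrame,
    *,
    subgroup_fields: tuple[str, ...] = ("subtype",) + INVASIVE_ONLY_VARS,
    reference: int = 0,
    small_cutoff: int = 25,
    subset=None,
) -> pd.DataFrame:
    """Cancer detection rates per subgroup for each scenario.

    Rates are detected/total true cancers of the subgroup row. The first
    listed scenario (``reference`` index) is the comparator: every other
    scenario gets a paired p-value on the subgroup's detection indicators
    (McNemar, exact-binomial fallback for small discordant cells). Empty
    levels yield a row with total 0 and no test. ``subset`` (boolean mask)
    restricts every row, e.g. to screen-detected or interval cancers for
    split detection tables.
    """
    if not results:
        raise StatsError("no scenario results")
    ref = results[reference]
    masks = _subgroup_masks(df, labels, subgroup_fields)
    if subset is not None:
        subset = np.asarray(subset, dtype=bool)
        masks = [(v, l, m & subset) for v, l, m in masks]
    out_rows = []
    for var, level, mask in masks:
        total = int(mask.sum())
        row: dict = {"variable": var, "level": level, "n_total": total}
        ref_det = ref.decisions.astype(bool) & mask
        for res in results:
            name = res.scenario if res.threshold_mode == "none" else (
                f"{res.scenario}[{res.threshold_mode}]")
            det = res.decisions.astype(bool) & mask
            k = int(det.sum())
            row[f"{name}:detected"] = k
            row[f"{name}:rate"] = k / total if total else np.nan
            if res is ref or total == 0:
                row[f"{name}:p"] = np.nan
                row[f"{name}:method"] = "ref" if res is ref else ""
            else:
                b, c = _discordant(det[mask], ref_det[mask])
                p, method = mcnemar_test(b, c, small_cutoff)
                row[f"{name}:p"] = p
                row[f"{name}:method"] = method
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def detection_crosstab(result_a: ScenarioResult, result_b: ScenarioResult,
                       truth) -> dict[str, int]:
    """Detected/missed agreement among true cancers for two scenarios.

    Returns counts ``both``, ``a_only``, ``b_only``, ``neither``; marginals
    equal each scenario's detected totals among cancers.
    """
    truth = np.asarray(truth, dtype=bool)
    d_a = result_a.decisions.astype(bool)[truth]
    d_b = result_b.decisions.astype(bool)[truth]
    return {
        "both": int((d_a & d_b).sum()),
        "a_only": int((d_a & ~d_b).sum()),
        "b_only": int((~d_a & d_b).sum()),
        "neither": int((~d_a & ~d_b).sum()),
    }


def render_detection_table(table: pd.DataFrame) -> str:
    """Aligned-text rendering of a detection table (rates to 1 d.p.)."""
    scen_names = sorted({c.split(":")[0] for c in table.columns if ":" in c})
    lines = []
    header = f"{'variable':<14}{'level':<18}{'n':>6}"
    for s in scen_names:
        header += f"  {s[:24]:>26}"
    lines.append(header)
    for _, row in table.iterrows():
        line = f"{row['variable']:<14}{row['level']:<18}{row['n_total']:>6}"
        for s in scen_names:
            k = row[f"{s}:detected"]
            rate = row[f"{s}:rate"]
            p = row[f"{s}:p"]
            cell = f"{k} ({100 * rate:.1f})" if row["n_total"] else "-"
            if not np.isnan(p):
                cell += f"; {format_p(p)}"
            elif row[f"{s}:method"] == "ref":
                cell += "; ref."
            line += f"  {cell:>26}"
        lines.append(line)
    return "\n".join(lines)
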