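"""Synthetic screening-cohort generator.

Emulates the statistical structure of a biennial double-reading screening
programme so the whole pipeline is testable without the (restricted) real
data: ~0.8% cancer prevalence split ~72.5/27.5 between screen-detected and
interval cancers, two readers with fixed marginal operating points whose
raw agreement (~97.3%) is induced by a shared Gaussian latent, a recorded
arbitration for every reader disagreement (plus a small overlap of
concordant exams carrying one), and a right-skewed exam-level AI score on
[0, 10] concentrated near 10 for cancers.

The generator states a world; it does not model tumour growth, reader
behaviour change, or dependence between the AI score and reader errors
(the AI score is class-conditionally independent of the readers by
default). Subgroup labels are drawn independently of detectability, so
definitional couplings of the real registry data — e.g. that double
reading detects every screen-detected cancer — are *not* enforced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .cohort import validate_cohort
from .reference import truth_vector

__all__ = [
    "GeneratorParams",
    "generate",
    "operating_point_check",
    "solve_reader_correlation",
]


class GeneratorError(ValueError):
    """Infeasible or invalid generator parameters."""


# Subgroup marginals follow a population-wide screening registry's
# composition: counts per level, normalised at draw time. Size, grade, TNM,
# nodes, ER and HER2 apply to invasive cancers only.
_SUBTYPE = {"invasive ductal": 1393, "invasive lobular": 222,
            "other invasive": 215, "DCIS": 211}
_SIZE = {"0-10 mm": 577, "11-20 mm": 790, "21-50 mm": 380, "51+ mm": 49, "unknown": 34}
_GRADE = {"1": 507, "2": 815, "3": 358, "unknown": 150}
_TNM = {"local I+II": 1761, "locally advanced III": 44,
        "distant metastasis IV": 20, "unknown": 5}
_NODES = {"no": 1340, "yes": 490}
_ER = {"0%": 207, "1-9%": 98, "10-100%": 1514, "unknown": 11}
_HER2 = {"negative": 1581, "positive": 225, "unknown": 24}
_SITES = {"Aabenraa": 49641, "Esbjerg": 49860, "Odense": 104984, "Vejle": 53186}


@dataclass
class GeneratorParams:
    """Stated world of the synthetic cohort (all proportions in [0, 1]).

    Reader operating points are marginal over all within-window cancers;
    the latent agreement correlation is solved numerically from
    ``agreement_target`` unless given explicitly. ``interval_visibility``
    is the weight on the cancer-like AI-score component for interval
    cancers (most interval cancers look normal at screen).
    ``next_round_fraction``/``long_term_fraction`` add cancers beyond the
    24-month window (negative under the primary standard) to exercise the
    extended reference standard; they default off.
    """

    n_exams: int = 200_000
    prevalence: float = 0.0079
    screen_detected_fraction: float = 0.725
    interval_lt12_fraction: float = 170 / 562
    next_round_fraction: float = 0.0
    long_term_fraction: float = 0.0
    reader1_sensitivity: float = 0.637
    reader1_specificity: float = 0.978
    reader2_sensitivity: float = 0.70
    reader2_specificity: float = 0.978
    agreement_target: float = 0.973
    agreement_correlation: float | None = None  # solved from target when None
    arbitrator_sensitivity: float = 0.80
    arbitrator_specificity: float = 0.90
    overlap_fraction: float = 426 / 251_089  # concordant exams with a recorded arbitration
    ai_noncancer_beta: tuple[float, float] = (2.0, 5.0)
    ai_cancer_beta: tuple[float, float] = (12.0, 1.2)
    interval_visibility: float = 0.25
    next_screen_offset_days: int = 730
    long_term_max_days: int = 2555  # 7 years
    age_mean: float = 59.3
    age_sd: float = 6.0
    exams_per_woman: float = 257_671 / 158_732
    seed: int = 0
    site_counts: dict = field(default_factory=lambda: dict(_SITES))
    subtype_counts: dict = field(default_factory=lambda: dict(_SUBTYPE))
    size_counts: dict = field(default_factory=lambda: dict(_SIZE))
    grade_counts: dict = field(default_factory=lambda: dict(_GRADE))
    tnm_counts: dict = field(default_factory=lambda: dict(_TNM))
    node_counts: dict = field(default_factory=lambda: dict(_NODES))
    er_counts: dict = field(default_factory=lambda: dict(_ER))
    her2_counts: dict = field(default_factory=lambda: dict(_HER2))

    def validate(self) -> None:
        if self.n_exams < 1:
            raise GeneratorError("n_exams must be >= 1")
        for name in ("prevalence", "screen_detected_fraction", "interval_lt12_fraction",
                     "next_round_fraction", "long_term_fraction",
                     "reader1_sensitivity", "reader1_specificity",
                     "reader2_sensitivity", "reader2_specificity",
                     "agreement_target", "arbitrator_sensitivity",
                     "arbitrator_specificity", "overlap_fraction",
                     "interval_visibility"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise GeneratorError(f"{name} = {v} outside [0, 1]")
        if self.next_round_fraction + self.long_term_fraction > 1.0:
            raise GeneratorError("extended-class fractions exceed 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# Bivariate-normal machinery for the shared-latent reader model
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(200)


def _bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(Z1 < h, Z2 < k) under a standard bivariate normal, correlation rho.

    Deterministic fixed-order Gauss-Legendre quadrature of
    ``int phi(z) Phi((k - rho z)/sqrt(1-rho^2)) dz`` over (-8, h).
    """
    if rho >= 1.0 - 1e-12:
        return float(sps.norm.cdf(min(h, k)))
    lo = -8.0
    if h <= lo:
        return 0.0
    z = 0.5 * (h - lo) * _GL_NODES + 0.5 * (h + lo)
    w = 0.5 * (h - lo) * _GL_WEIGHTS
    inner = sps.norm.cdf((k - rho * z) / np.sqrt(1.0 - rho * rho))
    return float(np.sum(w * sps.norm.pdf(z) * inner))


def _pair_agreement(p1: float, p2: float, rho: float) -> float:
    """P(two thresholded shared-latent Bernoullis agree) given marginals."""
    eps = 1e-12
    a1 = sps.norm.ppf(np.clip(p1, eps, 1 - eps))
    a2 = sps.norm.ppf(np.clip(p2, eps, 1 - eps))
    both = _bvn_cdf(a1, a2, rho)
    return 1.0 - p1 - p2 + 2.0 * both


def solve_reader_correlation(classes: list[tuple[float, float, float]],
                             target: float) -> float:
    """Solve the shared-latent correlation hitting a raw-agreement target.

    ``classes`` holds ``(weight, p1, p2)`` per truth class (recall
    probabilities of the two readers). Agreement is monotone increasing in
    the correlation; infeasible targets raise with the attainable range.
    """

    def agreement(rho: float) -> float:
        return sum(w * _pair_agreement(p1, p2, rho) for w, p1, p2 in classes)

    lo, hi = 0.0, 1.0 - 1e-9
    a0, a1 = agreement(lo), agreement(hi)
    if target < a0 - 1e-12 or target > a1 + 1e-12:
        raise GeneratorError(
            f"agreement target {target:.4f} unattainable with these operating "
            f"points: achievable range is [{a0:.4f}, {a1:.4f}]"
        )
    if target <= a0:
        return 0.0
    return float(optimize.brentq(lambda r: agreement(r) - target, lo, hi, xtol=1e-10))


def _draw_levels(rng: np.random.Generator, counts: dict, n: int) -> np.ndarray:
    levels = np.array(list(counts), dtype=object)
    w = np.array([counts[k] for k in counts], dtype=float)
    return rng.choice(levels, size=n, p=w / w.sum())


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate(params: GeneratorParams | None = None, **overrides) -> pd.DataFrame:
    """Generate a validated synthetic screening cohort.

    Fully reproducible from ``params.seed``. Keyword overrides patch the
    default :class:`GeneratorParams`.
    """
    if params is None:
        params = GeneratorParams(**overrides)
    elif overrides:
        params = GeneratorParams(**{**asdict(params), **overrides})
    params.validate()
    p = params
    n = p.n_exams
    rng = np.random.default_rng(p.seed)

    # --- truth: cancer status and timing category -------------------------
    cancer = rng.random(n) < p.prevalence
    n_cancer = int(cancer.sum())
    within = 1.0 - p.next_round_fraction - p.long_term_fraction
    probs = np.array([
        within * p.screen_detected_fraction,
        within * (1 - p.screen_detected_fraction) * p.interval_lt12_fraction,
        within * (1 - p.screen_detected_fraction) * (1 - p.interval_lt12_fraction),
        p.next_round_fraction,
        p.long_term_fraction,
    ])
    cat_codes = rng.choice(5, size=n_cancer, p=probs / probs.sum())

    dx = np.full(n, np.nan)
    idx_cancer = np.flatnonzero(cancer)
    dx_c = np.zeros(n_cancer)
    lt12 = cat_codes == 1
    ge12 = cat_codes == 2
    dx_c[lt12] = rng.integers(1, 365, size=int(lt12.sum()))
    dx_c[ge12] = rng.integers(365, min(730, p.next_screen_offset_days), size=int(ge12.sum()))
    dx_c[cat_codes == 3] = p.next_screen_offset_days
    dx_c[cat_codes == 4] = rng.integers(731, p.long_term_max_days + 1,
                                        size=int((cat_codes == 4).sum()))
    dx[idx_cancer] = dx_c

    # Primary-standard truth: screen-detected or interval within the window.
    truth = np.zeros(n, dtype=bool)
    truth[idx_cancer] = cat_codes <= 2

    # --- reader decisions via shared Gaussian latent ----------------------
    classes = [
        (p.prevalence, p.reader1_sensitivity, p.reader2_sensitivity),
        (1 - p.prevalence, 1 - p.reader1_specificity, 1 - p.reader2_specificity),
    ]
    rho = (p.agreement_correlation if p.agreement_correlation is not None
           else solve_reader_correlation(classes, p.agreement_target))
    z0 = rng.standard_normal(n)
    z1 = np.sqrt(rho) * z0 + np.sqrt(1 - rho) * rng.standard_normal(n)
    z2 = np.sqrt(rho) * z0 + np.sqrt(1 - rho) * rng.standard_normal(n)
    p1 = np.where(truth, p.reader1_sensitivity, 1 - p.reader1_specificity)
    p2 = np.where(truth, p.reader2_sensitivity, 1 - p.reader2_specificity)
    reader1 = (z1 < sps.norm.ppf(p1)).astype(np.int8)
    reader2 = (z2 < sps.norm.ppf(p2)).astype(np.int8)

    # --- recorded arbitration ---------------------------------------------
    disagree = reader1 != reader2
    overlap = ~disagree & (rng.random(n) < p.overlap_fraction)
    arbitrated = disagree | overlap
    arb_recall_p = np.where(truth, p.arbitrator_sensitivity, 1 - p.arbitrator_specificity)
    arb_draw = (rng.random(n) < arb_recall_p).astype(np.int8)
    arbitration = pd.Series(arb_draw, dtype="Int8").where(arbitrated)

    # --- AI exam score ------------------------------------------------------
    a_nc, b_nc = p.ai_noncancer_beta
    a_ca, b_ca = p.ai_cancer_beta
    score = rng.beta(a_nc, b_nc, size=n)
    sd_mask = np.zeros(n, dtype=bool)
    sd_mask[idx_cancer] = cat_codes == 0
    other_cancer = cancer & ~sd_mask  # interval + extended classes
    score[sd_mask] = rng.beta(a_ca, b_ca, size=int(sd_mask.sum()))
    vis = rng.random(n) < p.interval_visibility
    visible = other_cancer & vis
    score[visible] = rng.beta(a_ca, b_ca, size=int(visible.sum()))
    ai_score = np.round(score * 10.0, 5)

    # --- demographics and subgroup labels ----------------------------------
    n_women = max(1, int(round(n / p.exams_per_woman)))
    woman_idx = np.arange(n) % n_women
    age = np.clip(rng.normal(p.age_mean, p.age_sd, size=n), 45.0, 95.0).round(1)
    site = _draw_levels(rng, p.site_counts, n)
    start = np.datetime64("2014-08-04")
    dates = start + rng.integers(0, 1472, size=n).astype("timedelta64[D]")

    subtype = np.full(n, None, dtype=object)
    subtype[idx_cancer] = _draw_levels(rng, p.subtype_counts, n_cancer)
    invasive = np.where(cancer, subtype != "DCIS", None)
    inv_mask = cancer & (subtype != "DCIS")
    n_inv = int(inv_mask.sum())

    def inv_col(counts: dict) -> np.ndarray:
        col = np.full(n, None, dtype=object)
        col[inv_mask] = _draw_levels(rng, counts, n_inv)
        return col

    df = pd.DataFrame(
        {
            "exam_id": np.char.add("E", np.char.zfill(np.arange(n).astype(str), 8)),
            "woman_id": np.char.add("W", np.char.zfill(woman_idx.astype(str), 8)),
            "site": site,
            "age_years": age,
            "screen_date": np.datetime_as_string(dates, unit="D"),
            "reader1": reader1,
            "reader2": reader2,
            "arbitration": arbitration,
            "ai_score": ai_score,
            "dx_offset_days": pd.array(dx, dtype="Int64"),
            "next_screen_offset_days": pd.array(
                np.where(cancer, float(p.next_screen_offset_days), np.nan), dtype="Int64"),
            "invasive": pd.array(invasive, dtype="boolean"),
            "subtype": subtype,
            "size_class": inv_col(p.size_counts),
            "grade": inv_col(p.grade_counts),
            "tnm": inv_col(p.tnm_counts),
            "node_positive": inv_col(p.node_counts),
            "er": inv_col(p.er_counts),
            "her2": inv_col(p.her2_counts),
        }
    )
    return validate_cohort(df)


# ---------------------------------------------------------------------------
# Construction-validity diagnostics
# ---------------------------------------------------------------------------

def _binom_se(p_: float, n_: int) -> float:
    return float(np.sqrt(max(p_ * (1 - p_), 1e-12) / max(n_, 1)))


def operating_point_check(df: pd.DataFrame, params: GeneratorParams,
                          *, n_se: float = 3.0) -> pd.DataFrame:
    """Realised-vs-target diagnostics for a generated cohort.

    One row per check (prevalence, each reader's sensitivity/specificity,
    raw inter-reader agreement, arbitrator accuracy, AI AUC), flagging any
    deviation beyond ``n_se`` binomial standard errors of the target (AUC
    is flagged if the classes fail to separate, i.e. AUC <= 0.5).
    """
    truth = truth_vector(df)
    n = len(df)
    r1 = df["reader1"].to_numpy(dtype=bool)
    r2 = df["reader2"].to_numpy(dtype=bool)
    pos, neg = truth, ~truth
    rows = []

    def add(name, realised, target, n_basis):
        se = _binom_se(target, n_basis)
        rows.append({
            "check": name, "realised": realised, "target": target,
            "n": n_basis, "se": se,
            "ok": abs(realised - target) <= n_se * se,
        })

    add("prevalence", truth.mean(), params.prevalence, n)
    add("reader1_sensitivity", r1[pos].mean(), params.reader1_sensitivity, int(pos.sum()))
    add("reader1_specificity", (~r1[neg]).mean(), params.reader1_specificity, int(neg.sum()))
    add("reader2_sensitivity", r2[pos].mean(), params.reader2_sensitivity, int(pos.sum()))
    add("reader2_specificity", (~r2[neg]).mean(), params.reader2_specificity, int(neg.sum()))
    add("agreement", (r1 == r2).mean(), params.agreement_target, n)

    has_arb = df["arbitration"].notna().to_numpy()
    arb = df["arbitration"].fillna(0).to_numpy(dtype=bool)
    ap, an = has_arb & pos, has_arb & neg
    if ap.any():
        add("arbitrator_sensitivity", arb[ap].mean(), params.arbitrator_sensitivity, int(ap.sum()))
    if an.any():
        add("arbitrator_specificity", (~arb[an]).mean(), params.arbitrator_specificity, int(an.sum()))

    if pos.any() and neg.any():
        score = df["ai_score"].to_numpy()
        auc = sps.mannwhitneyu(score[pos], score[neg]).statistic / (pos.sum() * neg.sum())
        rows.append({"check": "ai_auc", "realised": float(auc), "target": np.nan,
                     "n": n, "se": np.nan, "ok": bool(auc > 0.5)})
    return pd.DataFrame(rows)
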