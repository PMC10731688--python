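"""Screening-scenario engine.

Produces per-exam final decisions for four screening workflows over the
same cohort:

* ``first_reader`` — the first reader's recorded decision alone.
* ``combined_reading`` — recorded double reading with arbitration (the
  historical outcome, reproduced exactly).
* ``standalone_ai`` — the thresholded AI score replaces all readers; no
  arbitration exists in this pathway.
* ``integrated_ai`` — the AI replaces the first reader inside double
  reading: AI/second-reader concordance decides directly; disagreement goes
  to the recorded arbitration when one exists, otherwise to a *simulated*
  arbitrator drawn once per exam at the historical arbitrator's accuracy
  (sensitivity on true cancers, specificity on non-cancers), conditioned on
  truth only.

Simulated draws are Bernoulli in ``exam_id`` order from a named seed, so a
(cohort, calibration, arbitrator, seed) tuple reproduces every decision
bit-for-bit. By default each scenario variant derives its own sub-seed from
the base seed to avoid artefactual coupling between threshold modes;
passing ``share_draws=True`` reuses the base stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationResult, dichotomize
from .cohort import IncompleteRecordError, combined_reading_outcomes

FIRST_READER = "first_reader"
COMBINED_READING = "combined_reading"
STANDALONE_AI = "standalone_ai"
INTEGRATED_AI = "integrated_ai"
SCENARIOS = (FIRST_READER, COMBINED_READING, STANDALONE_AI, INTEGRATED_AI)

PROV_NONE = "none"
PROV_OBSERVED = "observed"
PROV_SIMULATED = "simulated"


class ScenarioError(ValueError):
    """Scenario preconditions violated."""


@dataclass(frozen=True)
class ArbitratorModel:
    """Operating point of the (simulated) decisive third reader.

    ``sensitivity`` is the probability the arbitrator recalls a true
    cancer, ``specificity`` the probability it clears a non-cancer; the
    counts record how many arbitrated exams of each class informed the
    estimate.
    """

    sensitivity: float
    specificity: float
    n_cancer_arbitrated: int = 0
    n_noncancer_arbitrated: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ScenarioError(f"{name} {v} outside [0, 1]")
        if self.n_cancer_arbitrated < 0 or self.n_noncancer_arbitrated < 0:
            raise ScenarioError("arbitrated counts must be >= 0")


def estimate_arbitrator(df: pd.DataFrame, truth: np.ndarray, *, seed: int = 0) -> ArbitratorModel:
    """Estimate the historical arbitrator's operating point from recorded arbitrations.

    Sensitivity is the recall fraction among arbitrated exams with positive
    truth; specificity the normal fraction among arbitrated negatives.
    """
    truth = np.asarray(truth, dtype=bool)
    if len(truth) != len(df):
        raise ScenarioError("truth vector length does not match cohort")
    has_arb = df["arbitration"].notna().to_numpy()
    arb = df["arbitration"].fillna(0).to_numpy(dtype=np.int8)
    pos = has_arb & truth
    neg = has_arb & ~truth
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ScenarioError(
            "cannot estimate the arbitrator operating point: "
            f"{n_pos} arbitrated cancers and {n_neg} arbitrated non-cancers; "
            "supply an ArbitratorModel explicitly"
        )
    return ArbitratorModel(
        sensitivity=float(arb[pos].sum() / n_pos),
        specificity=float((arb[neg] == 0).sum() / n_neg),
        n_cancer_arbitrated=n_pos,
        n_noncancer_arbitrated=n_neg,
        seed=seed,
    )


def simulate_arbitration(truth, model: ArbitratorModel, rng: np.random.Generator):
    """One Bernoulli arbitration decision per exam, conditioned on truth only.

    ``P(recall | cancer) = sensitivity``; ``P(normal | non-cancer) =
    specificity``. Accepts a scalar or boolean array; draws are consumed in
    input order, so a fixed (seed, exam order) reproduces the decisions.
    """
    t = np.asarray(truth, dtype=bool)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    u = rng.random(len(t))
    p_recall = np.where(t, model.sensitivity, 1.0 - model.specificity)
    out = (u < p_recall).astype(np.int8)
    return int(out[0]) if scalar else out


def standalone_decision(ai_score, threshold: float):
    """Standalone pathway: the thresholded AI score is the final decision."""
    arr = np.asarray(ai_score, dtype=float)
    if np.isnan(arr).any():
        raise ScenarioError("missing ai_score in standalone scenario")
    return dichotomize(ai_score, threshold)


def integrated_decision(
    ai_decision: int,
    reader2: int,
    recorded_arbitration: int | None,
    truth: bool,
    model: ArbitratorModel,
    rng: np.random.Generator,
) -> tuple[int, bool, str]:
    """Reader-replacement rule for one exam.

    Returns ``(decision, arbitrated, provenance)`` where provenance is
    ``none`` (AI and second reader agree), ``observed`` (recorded
    arbitration applied) or ``simulated`` (fresh arbitrator draw).
    """
    if ai_decision == reader2:
        return int(ai_decision), False, PROV_NONE
    if recorded_arbitration is not None:
        return int(recorded_arbitration), True, PROV_OBSERVED
    return int(simulate_arbitration(truth, model, rng)), True, PROV_SIMULATED


@dataclass
class ScenarioResult:
    """Per-exam final decisions plus tallies for one scenario run."""

    scenario: str
    threshold_mode: str  # {"ai_sens", "ai_spec", "none"} — reporting label only
    exam_ids: np.ndarray
    decisions: np.ndarray
    arbitrated: np.ndarray
    provenance: np.ndarray  # {"none", "observed", "simulated"} per exam
    threshold: float | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.exam_ids)
        if not (len(self.decisions) == len(self.arbitrated) == len(self.provenance) == n):
            raise ScenarioError("per-exam fields must be aligned")
        if (self.provenance == PROV_SIMULATED).any() and self.scenario != INTEGRATED_AI:
            raise ScenarioError("simulated arbitration can occur only in integrated_ai")

    @property
    def n_exams(self) -> int:
        return len(self.exam_ids)

    @property
    def n_recalls(self) -> int:
        return int(self.decisions.sum())

    @property
    def n_arbitrations(self) -> int:
        return int(self.arbitrated.sum())

    @property
    def n_simulated_arbitrations(self) -> int:
        return int((self.provenance == PROV_SIMULATED).sum())

    @property
    def recall_rate(self) -> float:
        return self.n_recalls / self.n_exams

    @property
    def arbitration_rate(self) -> float:
        return self.n_arbitrations / self.n_exams

    @property
    def human_reads(self) -> int:
        """Human screen reads consumed: 2/exam for double reading, 1/exam when
        the AI replaces the first reader, 0 for standalone AI; plus one read
        per arbitration (first-reader-alone likewise 1/exam, no arbitration)."""
        per_exam = {FIRST_READER: 1, COMBINED_READING: 2,
                    STANDALONE_AI: 0, INTEGRATED_AI: 1}[self.scenario]
        return per_exam * self.n_exams + self.n_arbitrations

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exam_id": self.exam_ids,
                "scenario": self.scenario,
                "threshold_mode": self.threshold_mode,
                "decision": self.decisions,
                "arbitrated": self.arbitrated,
                "provenance": self.provenance,
            }
        )

    def tallies(self) -> dict:
        return {
            "scenario": self.scenario,
            "threshold_mode": self.threshold_mode,
            "threshold": self.threshold,
            "seed": self.seed,
            "n_exams": self.n_exams,
            "n_recalls": self.n_recalls,
            "n_arbitrations": self.n_arbitrations,
            "n_simulated_arbitrations": self.n_simulated_arbitrations,
            "human_reads": self.human_reads,
        }


def _subseed(seed: int, scenario: str, threshold_mode: str) -> np.random.Generator:
    # Distinct, stable sub-stream per scenario variant.
    return np.random.default_rng([seed, _stable_key(scenario, threshold_mode)])


def _stable_key(scenario: str, threshold_mode: str) -> int:
    # hash() is salted per process; use a deterministic digest instead.
    import zlib

    return zlib.crc32(f"{scenario}:{threshold_mode}".encode()) & 0x7FFFFFFF


def run_scenario(
    df: pd.DataFrame,
    scenario: str,
    *,
    truth: np.ndarray | None = None,
    calibration: CalibrationResult | None = None,
    threshold: float | None = None,
    threshold_mode: str = "none",
    arbitrator: ArbitratorModel | None = None,
    seed: int = 0,
    share_draws: bool = False,
    arbitrate_overlap: bool = False,
) -> ScenarioResult:
    """Apply one scenario's per-exam rule over the whole cohort.

    Parameters
    ----------
    df
        Validated cohort frame.
    scenario
        One of :data:`SCENARIOS`.
    truth
        Boolean reference-standard vector; required for ``integrated_ai``
        (it feeds the simulated arbitrator only — decisions never peek at
        truth otherwise).
    calibration, threshold
        The AI recall threshold for the AI scenarios, either as a
        :class:`~screeneval.calibration.CalibrationResult` or a bare float.
    arbitrator
        Simulated-arbitrator operating point (``integrated_ai``).
    seed, share_draws
        Base seed for the simulated draws; by default a distinct sub-seed
        is derived per (scenario, threshold_mode) so threshold variants use
        independent draws.
    arbitrate_overlap
        Sensitivity-analysis flag: when AI and second reader agree but a
        historical arbitration exists (the recorded-overlap studies), count
        and apply that arbitration instead of the concordant decision.
    """
    if scenario not in SCENARIOS:
        raise ScenarioError(f"unknown scenario {scenario!r}")
    exam_ids = df["exam_id"].to_numpy()
    n = len(df)

    if scenario in (STANDALONE_AI, INTEGRATED_AI):
        if threshold is None:
            if calibration is None:
                raise ScenarioError(f"{scenario} requires a calibration/threshold")
            threshold = calibration.threshold

    if scenario == FIRST_READER:
        decisions = df["reader1"].to_numpy(dtype=np.int8)
        arbitrated = np.zeros(n, dtype=bool)
        provenance = np.full(n, PROV_NONE, dtype=object)
    elif scenario == COMBINED_READING:
        decisions, arbitrated = combined_reading_outcomes(df)
        provenance = np.where(arbitrated, PROV_OBSERVED, PROV_NONE).astype(object)
    elif scenario == STANDALONE_AI:
        decisions = standalone_decision(df["ai_score"].to_numpy(dtype=float), threshold)
        arbitrated = np.zeros(n, dtype=bool)
        provenance = np.full(n, PROV_NONE, dtype=object)
    else:  # INTEGRATED_AI
        if truth is None:
            raise ScenarioError("integrated_ai requires a truth vector for the simulated arbitrator")
        if arbitrator is None:
            raise ScenarioError("integrated_ai requires an ArbitratorModel")
        truth = np.asarray(truth, dtype=bool)
        if len(truth) != n:
            raise ScenarioError("truth vector length does not match cohort")
        ai = dichotomize(df["ai_score"].to_numpy(dtype=float), threshold)
        r2 = df["reader2"].to_numpy(dtype=np.int8)
        has_arb = df["arbitration"].notna().to_numpy()
        rec_arb = df["arbitration"].fillna(0).to_numpy(dtype=np.int8)

        disagree = ai != r2
        use_observed = disagree & has_arb
        use_simulated = disagree & ~has_arb
        decisions = ai.copy()
        decisions[use_observed] = rec_arb[use_observed]
        arbitrated = disagree.copy()
        provenance = np.full(n, PROV_NONE, dtype=object)
        provenance[use_observed] = PROV_OBSERVED
        provenance[use_simulated] = PROV_SIMULATED
        if arbitrate_overlap:
            overlap = ~disagree & has_arb
            decisions[overlap] = rec_arb[overlap]
            arbitrated |= overlap
            provenance[overlap] = PROV_OBSERVED

        rng = (np.random.default_rng(seed) if share_draws
               else _subseed(seed, scenario, threshold_mode))
        sim_idx = np.flatnonzero(use_simulated)
        # Draws consumed in exam_id order for reproducibility.
        sim_idx = sim_idx[np.argsort(exam_ids[sim_idx], kind="stable")]
        decisions[sim_idx] = simulate_arbitration(truth[sim_idx], arbitrator, rng)

    return ScenarioResult(
        scenario=scenario,
        threshold_mode=threshold_mode,
        exam_ids=exam_ids,
        decisions=np.asarray(decisions, dtype=np.int8),
        arbitrated=arbitrated,
        provenance=provenance,
        threshold=None if threshold is None else float(threshold),
        seed=seed,
        meta={"share_draws": share_draws, "arbitrate_overlap": arbitrate_overlap},
    )


def workload_delta(new: int, ref: int) -> float:
    """Relative workload change (e.g. recalls or arbitrations) vs a reference count."""
    if ref <= 0:
        raise ScenarioError("reference count must be positive")
    return (new - ref) / ref
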