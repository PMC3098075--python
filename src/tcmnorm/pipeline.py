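"""Normalization pipeline: hybrid scoring, decision rule, evaluation, sweeps.

A clinical symptom name is normalized to the standard name it scores
highest against, provided that best score clears a threshold; ties at the
maximum are broken uniformly at random with a seeded generator so runs are
reproducible.  Evaluation against an expert gold mapping reports

    precision = |CNS| / |NS|,   recall = |CNS| / |CSN|,

the counts being correctly-normalized, normalized, and to-be-normalized
clinical names (gold-NONE names never count as correct and are excluded
from the recall denominator), with F-Measure their harmonic mean.

The hybrid score is alpha * literal + beta * remedy-based with
alpha + beta = 1, capturing the observation that two names for the same
symptom are both literally similar and prescribed similar remedies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import Corpus, GoldMapping, Role, build_remedy_bags
from .literal_metrics import AlignmentScoring, JaroWinklerConfig, literal_scorer
from .remedy_metrics import RemedyContext, remedy_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "HybridWeights",
    "NormalizationResult",
    "EvalReport",
    "hybrid_similarity",
    "score_matrix",
    "literal_matrix",
    "remedy_matrix",
    "normalize_scores",
    "normalize_corpus",
    "evaluate",
    "threshold_sweep",
    "sweep_scores",
    "weight_grid_search",
    "DEFAULT_THRESHOLDS",
]

#: Default threshold grid 0.0, 0.1, ..., 0.9.
DEFAULT_THRESHOLDS = tuple(round(0.1 * i, 1) for i in range(10))

SimilarityFunction = Callable[[str, str], float]


@dataclass(frozen=True)
class HybridWeights:
    """Weights of the literal (alpha) and remedy-based (beta) components."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValueError("weights must satisfy alpha + beta = 1")


def hybrid_similarity(
    s: str,
    s2: str,
    weights: HybridWeights,
    literal: SimilarityFunction,
    remedy: SimilarityFunction,
) -> float:
    """alpha * literal(s, s') + beta * remedy(s, s')."""
    return weights.alpha * literal(s, s2) + weights.beta * remedy(s, s2)


@dataclass
class NormalizationResult:
    """Outcome of normalizing every clinical name in a corpus."""

    assignments: dict[str, tuple[str, float]]
    unassigned: set[str]
    threshold: float
    seed: int


@dataclass
class EvalReport:
    """Counts |CNS|, |NS|, |CSN| and derived precision/recall/F-Measure."""

    n_correct: int
    n_normalized: int
    n_total: int

    @property
    def precision(self) -> float:
        return self.n_correct / self.n_normalized if self.n_normalized else 0.0

    @property
    def recall(self) -> float:
        return self.n_correct / self.n_total if self.n_total else 0.0

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0


def score_matrix(
    standards: Sequence[str],
    clinicals: Sequence[str],
    scorer: SimilarityFunction,
) -> np.ndarray:
    """Dense score matrix, rows = standards, columns = clinicals."""
    out = np.empty((len(standards), len(clinicals)))
    for i, s in enumerate(standards):
        for j, c in enumerate(clinicals):
            out[i, j] = scorer(s, c)
    return out


def literal_matrix(
    standards: Sequence[str],
    clinicals: Sequence[str],
    metric: str,
    jw_cfg: JaroWinklerConfig | None = None,
    scoring: AlignmentScoring | None = None,
) -> np.ndarray:
    fn = literal_scorer(
        metric,
        jw_cfg or JaroWinklerConfig(),
        scoring or AlignmentScoring(),
    )
    return score_matrix(standards, clinicals, fn)


def remedy_matrix(
    standards: Sequence[str],
    clinicals: Sequence[str],
    method: str,
    context: RemedyContext,
) -> np.ndarray:
    """Score matrix for a remedy-based method; keys are (name, role) pairs."""
    out = np.empty((len(standards), len(clinicals)))
    for i, s in enumerate(standards):
        for j, c in enumerate(clinicals):
            out[i, j] = remedy_similarity(
                (s, Role.STANDARD), (c, Role.CLINICAL), method, context
            )
    return out


def normalize_scores(
    scores: np.ndarray,
    standards: Sequence[str],
    clinicals: Sequence[str],
    threshold: float,
    seed: int = 0,
) -> NormalizationResult:
    """Apply the argmax-with-threshold decision rule to a score matrix.

    Clinical names are processed in sorted order and each consumes exactly
    one draw from the tie-break generator whether or not it is gated, so a
    name's tie-break does not depend on input row order or on the
    threshold; with a unique argmax the draw is inert and the outcome is
    seed-independent.
    """
    if len(standards) == 0:
        raise ValueError("cannot normalize against an empty standard vocabulary")
    order = np.argsort(np.asarray(clinicals, dtype=object))
    rng = np.random.default_rng(seed)
    std = np.asarray(standards, dtype=object)
    std_order = np.argsort(std)
    assignments: dict[str, tuple[str, float]] = {}
    unassigned: set[str] = set()
    for j in order:
        col = scores[:, j]
        best = col.max()
        tied = std_order[col[std_order] == best]
        pick = tied[int(rng.integers(len(tied)))]
        if best >= threshold:
            assignments[clinicals[j]] = (std[pick], float(best))
        else:
            unassigned.add(clinicals[j])
    return NormalizationResult(
        assignments=assignments, unassigned=unassigned, threshold=threshold, seed=seed
    )


def normalize_corpus(
    corpus: Corpus,
    scorer: SimilarityFunction,
    threshold: float,
    seed: int = 0,
) -> NormalizationResult:
    """Score every (standard, clinical) pair and apply the decision rule."""
    standards = sorted(corpus.standard_names)
    clinicals = sorted(corpus.clinical_names)
    if not standards:
        raise ValueError("corpus has no standard names")
    scores = score_matrix(standards, clinicals, scorer)
    return normalize_scores(scores, standards, clinicals, threshold, seed)


def evaluate(result: NormalizationResult, gold: GoldMapping) -> EvalReport:
    """Compare a normalization outcome against the expert gold mapping."""
    missing = (set(result.assignments) | result.unassigned) - set(gold.pairs)
    if missing:
        raise ValueError(f"clinical names missing from gold mapping: {sorted(missing)[:5]}")
    n_correct = sum(
        1
        for clinical, (standard, _) in result.assignments.items()
        if gold.pairs[clinical] == standard
    )
    n_normalized = len(result.assignments)
    n_total = sum(1 for target in gold.pairs.values() if target is not None)
    if n_normalized == 0:
        logger.warning("no clinical name cleared threshold %.2f", result.threshold)
    return EvalReport(n_correct=n_correct, n_normalized=n_normalized, n_total=n_total)


def sweep_scores(
    scores: np.ndarray,
    standards: Sequence[str],
    clinicals: Sequence[str],
    gold: GoldMapping,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate one precomputed score matrix across a threshold grid."""
    rows = []
    for threshold in thresholds:
        result = normalize_scores(scores, standards, clinicals, threshold, seed)
        report = evaluate(result, gold)
        rows.append(
            {
                "threshold": threshold,
                "n_correct": report.n_correct,
                "n_normalized": report.n_normalized,
                "n_total": report.n_total,
                "precision": report.precision,
                "recall": report.recall,
                "f_measure": report.f_measure,
            }
        )
    return pd.DataFrame(rows)


def threshold_sweep(
    corpus: Corpus,
    gold: GoldMapping,
    scorer: SimilarityFunction,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    seed: int = 0,
) -> pd.DataFrame:
    """Precision/recall/F across thresholds; scores computed once and reused."""
    standards = sorted(corpus.standard_names)
    clinicals = sorted(corpus.clinical_names)
    scores = score_matrix(standards, clinicals, scorer)
    return sweep_scores(scores, standards, clinicals, gold, thresholds, seed)


def weight_grid_search(
    corpus: Corpus,
    gold: GoldMapping,
    literal_metric: str,
    remedy_method: str,
    grid_step: float = 0.1,
    threshold: float = 0.5,
    seed: int = 0,
    context: RemedyContext | None = None,
    jw_cfg: JaroWinklerConfig | None = None,
    scoring: AlignmentScoring | None = None,
) -> tuple[pd.DataFrame, list[tuple[float, float]]]:
    """Evaluate every (alpha, beta = 1 - alpha) pair on the grid.

    Returns the full results table and the set of weight pairs attaining
    the maximal F-Measure (ties reported together).
    """
    n_steps = round(1.0 / grid_step)
    if abs(n_steps * grid_step - 1.0) > 1e-9:
        raise ValueError("grid_step must divide 1 evenly")
    standards = sorted(corpus.standard_names)
    clinicals = sorted(corpus.clinical_names)
    lit = literal_matrix(standards, clinicals, literal_metric, jw_cfg, scoring)
    if context is None:
        context = RemedyContext.fit(build_remedy_bags(corpus), methods=(remedy_method,))
    rem = remedy_matrix(standards, clinicals, remedy_method, context)
    rows = []
    for step in range(n_steps + 1):
        alpha = round(step * grid_step, 10)
        beta = round(1.0 - alpha, 10)
        hybrid = alpha * lit + beta * rem
        result = normalize_scores(hybrid, standards, clinicals, threshold, seed)
        report = evaluate(result, gold)
        rows.append(
            {
                "alpha": alpha,
                "beta": beta,
                "precision": report.precision,
                "recall": report.recall,
                "f_measure": report.f_measure,
            }
        )
    table = pd.DataFrame(rows)
    best = table["f_measure"].max()
    argmax = [
        (row.alpha, row.beta)
        for row in table.itertuples()
        if row.f_measure == best
    ]
    return table, argmax
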