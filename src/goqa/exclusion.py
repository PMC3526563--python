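"""Iterative Chauvenet outlier exclusion over the four yGA voting metrics.

yGA scores inherit raw DALI Z-scores, so a model whose neighbor search
landed in an unrelated structural neighborhood can dominate a target's
ranking with an absurdly high score.  Chauvenet's criterion flags a value
as an outlier when, under a normal model of the sample, its exceedance
probability falls below p = 1/(2n).  Only the upper tail is tested (the
lower quality bound is simply zero), and the criterion is recomputed and
reapplied until no model is flagged, so a gross outlier cannot shield a
smaller one.  A model is excluded when ANY of yGA_468, yGA_567, yGA_579,
yGA_678 flags it; excluded models keep their scores and are only marked,
because exclusion can also hit a lone good model above a poor ensemble and
deserves manual review.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .scoring import EXCLUSION_METRICS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChauvenetState:
    """Normal-model summary of one metric's sample and its upper cutoff."""

    n: int
    p: float
    mean: float
    sd: float
    upper_cutoff: float


@dataclass(frozen=True)
class ExclusionRecord:
    model_id: str
    metrics: tuple[str, ...]  # voting metrics that flagged the model
    iteration: int


@dataclass(frozen=True)
class ExclusionResult:
    retained: tuple[str, ...]
    excluded: tuple[ExclusionRecord, ...]

    @property
    def excluded_ids(self) -> frozenset[str]:
        return frozenset(rec.model_id for rec in self.excluded)


def chauvenet_cutoff(values: Sequence[float]) -> ChauvenetState:
    """Upper Chauvenet cutoff mean + sd * Phi^-1(1 - 1/(2n)).

    Samples of fewer than three values, or with zero spread, yield an
    infinite cutoff (no exclusion is attempted): the criterion is
    meaningless on degenerate ensembles.  The standard deviation uses the
    n-1 sample estimator.
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 3:
        logger.info("Chauvenet skipped: only %d value(s)", n)
        return ChauvenetState(n, 1 / (2 * n) if n else 0.5,
                              float(arr.mean()) if n else math.nan,
                              0.0, math.inf)
    p = 1.0 / (2 * n)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        return ChauvenetState(n, p, mean, sd, math.inf)
    cutoff = mean + sd * float(norm.ppf(1.0 - p))
    return ChauvenetState(n, p, mean, sd, cutoff)


def exclude_outliers(
    scores: Mapping[str, Mapping[str, float]],
    metrics: Sequence[str] = EXCLUSION_METRICS,
) -> ExclusionResult:
    """Iteratively remove models that exceed any metric's Chauvenet cutoff.

    ``scores`` maps metric name -> {model id -> value}; all listed metrics
    must cover the same model set.  Per iteration the cutoffs of every
    metric are recomputed over the currently retained models and every
    model strictly above any cutoff is removed simultaneously; iteration
    stops at a fixed point.
    """
    missing = [m for m in metrics if m not in scores]
    if missing:
        raise ValueError(f"missing exclusion metrics: {missing}")
    model_sets = {frozenset(scores[m]) for m in metrics}
    if len(model_sets) != 1:
        raise ValueError("exclusion metrics cover different model sets")

    retained = sorted(next(iter(model_sets)))
    excluded: list[ExclusionRecord] = []
    iteration = 0
    while len(retained) >= 3:
        iteration += 1
        cutoffs = {
            metric: chauvenet_cutoff([scores[metric][m] for m in retained]).upper_cutoff
            for metric in metrics
        }
        flagged: dict[str, list[str]] = {}
        for model in retained:
            triggers = [
                metric for metric in metrics
                if scores[metric][model] > cutoffs[metric]
            ]
            if triggers:
                flagged[model] = triggers
        if not flagged:
            break
        for model in sorted(flagged):
            excluded.append(ExclusionRecord(model, tuple(flagged[model]), iteration))
        retained = [m for m in retained if m not in flagged]
    return ExclusionResult(tuple(retained), tuple(excluded))


def apply_exclusion(table, metrics: Sequence[str] = EXCLUSION_METRICS):
    """Flag outlier models in a long-format score table.

    Returns (table copy with the ``excluded`` column set, ExclusionResult).
    The table must contain every voting metric for every model.
    """
    present = set(table["metric"])
    missing = [m for m in metrics if m not in present]
    if missing:
        raise ValueError(f"score table lacks exclusion metrics: {missing}")
    wide = table.pivot_table(index="model_id", columns="metric", values="value")
    scores = {m: wide[m].to_dict() for m in metrics}
    result = exclude_outliers(scores, metrics)
    flagged = table.copy()
    flagged["excluded"] = flagged["model_id"].isin(result.excluded_ids)
    return flagged, result
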