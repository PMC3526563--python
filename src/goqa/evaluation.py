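"""Benchmark-style validation against observed model quality (GDT-TS).

Predicted scores are compared with GDT-TS, the standard observed-quality
measure for protein structure predictions (0-100; higher is better), the
way quality-assessment benchmarks do it: a Pearson correlation pooled over
all models ("overall"), per-target correlations summarised as mean +/- SD,
and the ability to pick each target's best model measured by

    deltaGDT = GDT(objectively best model) - GDT(top-scored model)

binned into <1, [1,2), [2,10), >=10 GDT units.  yGA-family scores are
relative (they carry raw Z-scores), so only per-target statistics are
defined for them and the overall correlation is refused.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DELTA_GDT_BIN_LABELS = ("<1", "[1,2)", "[2,10)", ">=10")
_DELTA_GDT_EDGES = (1.0, 2.0, 10.0)


class EvaluationError(ValueError):
    pass


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Requires at least three points and nonzero variance on both sides;
    a degenerate input raises so callers can log and skip it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise EvaluationError("pearson needs two equal-length vectors")
    if x.size < 3:
        raise EvaluationError(f"pearson needs >= 3 points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise EvaluationError("pearson undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def delta_gdt(scores: Mapping[str, float], gdt: Mapping[str, float]) -> float:
    """GDT gap between a target's objectively best and top-scored models.

    Ties on the predicted score break by model id ascending, so the result
    is deterministic.  Always >= 0; 0 iff the top-scored model attains the
    maximum GDT.
    """
    if not scores:
        raise EvaluationError("delta_gdt needs at least one scored model")
    missing = sorted(set(scores) - set(gdt))
    if missing:
        raise EvaluationError(f"models missing from GDT table: {missing}")
    predicted_best = min(scores, key=lambda m: (-scores[m], m))
    best_gdt = max(gdt[m] for m in scores)
    return best_gdt - gdt[predicted_best]


def bin_delta_gdt(values) -> tuple[float, float, float, float]:
    """Percentages of deltaGDT values in <1, [1,2), [2,10), >=10.

    Bin edges are half-open on the right, so a gap of exactly 10 GDT units
    falls in the top bin.  Percentages are over the input count and sum to
    100 for non-empty input.
    """
    values = list(values)
    if not values:
        return (0.0, 0.0, 0.0, 0.0)
    counts = [0, 0, 0, 0]
    for v in values:
        if v < _DELTA_GDT_EDGES[0]:
            counts[0] += 1
        elif v < _DELTA_GDT_EDGES[1]:
            counts[1] += 1
        elif v < _DELTA_GDT_EDGES[2]:
            counts[2] += 1
        else:
            counts[3] += 1
    return tuple(100.0 * c / len(values) for c in counts)


@dataclass(frozen=True)
class EvaluationReport:
    """Correlation and model-selection summary for one metric."""

    metric: str
    overall_r: float | None  # None for relative (yGA-family) metrics
    per_target_r: dict[str, float]
    per_target_mean: float
    per_target_sd: float
    delta_gdt: dict[str, float]
    bins: tuple[float, float, float, float]
    n_models: int
    skipped_targets: tuple[str, ...] = ()

    def summary(self) -> str:
        lines = [f"metric: {self.metric} ({self.n_models} models)"]
        if self.overall_r is not None:
            lines.append(f"overall r: {self.overall_r:.3f}")
        else:
            lines.append("overall r: n/a (relative metric)")
        lines.append(
            f"per-target r: {self.per_target_mean:.3f} +/- {self.per_target_sd:.3f}"
            f" over {len(self.per_target_r)} targets"
        )
        bins = ", ".join(
            f"{label}: {pct:.1f}%" for label, pct in zip(DELTA_GDT_BIN_LABELS, self.bins)
        )
        lines.append(f"deltaGDT bins: {bins}")
        if self.skipped_targets:
            lines.append(f"skipped targets: {', '.join(self.skipped_targets)}")
        return "\n".join(lines)


def _is_relative(metric: str) -> bool:
    return metric.startswith("yGA")


def evaluate(
    table: pd.DataFrame,
    gdt: Mapping[str, float],
    grouping: Mapping[str, str],
    metric: str,
    post_exclusion: bool = False,
) -> EvaluationReport:
    """Build an :class:`EvaluationReport` for one metric.

    ``table`` is the long-format score table (model_id, metric, value,
    excluded); ``grouping`` maps model id -> target id.  In post-exclusion
    mode, models flagged by the outlier step are omitted.  Targets with
    fewer than three usable models, or degenerate variance, are skipped
    from the correlation average with a log entry; deltaGDT is still
    computed for any target with at least one model.
    """
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise EvaluationError(f"no rows for metric {metric!r}")
    if post_exclusion and "excluded" in sub:
        sub = sub[~sub["excluded"]]
    models = sub["model_id"].tolist()
    missing = sorted(set(models) - set(gdt))
    if missing:
        raise EvaluationError(f"models missing from GDT table: {missing}")
    unmapped = sorted(set(models) - set(grouping))
    if unmapped:
        raise EvaluationError(f"models missing from target grouping: {unmapped}")

    values = dict(zip(sub["model_id"], sub["value"]))
    by_target: dict[str, list[str]] = {}
    for model in models:
        by_target.setdefault(grouping[model], []).append(model)

    per_target_r: dict[str, float] = {}
    skipped: list[str] = []
    deltas: dict[str, float] = {}
    for target in sorted(by_target):
        group = by_target[target]
        deltas[target] = delta_gdt(
            {m: values[m] for m in group}, {m: gdt[m] for m in group}
        )
        try:
            per_target_r[target] = pearson(
                [values[m] for m in group], [gdt[m] for m in group]
            )
        except EvaluationError as err:
            logger.info("target %s skipped from correlation: %s", target, err)
            skipped.append(target)

    if per_target_r:
        r_values = np.array(list(per_target_r.values()))
        mean_r = float(r_values.mean())
        sd_r = float(r_values.std(ddof=1)) if r_values.size > 1 else 0.0
    else:
        mean_r, sd_r = math.nan, math.nan

    overall: float | None = None
    if not _is_relative(metric):
        overall = pearson([values[m] for m in models], [gdt[m] for m in models])

    return EvaluationReport(
        metric=metric,
        overall_r=overall,
        per_target_r=per_target_r,
        per_target_mean=mean_r,
        per_target_sd=sd_r,
        delta_gdt=deltas,
        bins=bin_delta_gdt(deltas.values()),
        n_models=len(models),
        skipped_targets=tuple(skipped),
    )


def read_gdt_table(source) -> dict[str, float]:
    """Read a TSV of (model id, GDT-TS); values must lie in [0, 100]."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    frame = pd.read_csv(
        source, sep="\t", header=None, names=["model_id", "gdt_ts"], comment="#"
    )
    if frame["model_id"].iloc[0] == "model_id":  # optional header row
        frame = frame.iloc[1:]
    gdt = {str(m): float(v) for m, v in zip(frame["model_id"], frame["gdt_ts"])}
    bad = {m: v for m, v in gdt.items() if not 0.0 <= v <= 100.0}
    if bad:
        raise EvaluationError(f"GDT-TS values outside [0, 100]: {bad}")
    return gdt


def write_gdt_table(gdt: Mapping[str, float], stream) -> None:
    for model in sorted(gdt):
        stream.write(f"{model}\t{gdt[model]:.4f}\n")
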