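"""ROC-area quality scores over an Slist: GA, yGA, combined, metaGA.

Records are labelled positive when their FS strictly exceeds an
FS-threshold.  Scanning the Z-ranked Slist top to bottom draws a
sensitivity-vs-specificity curve; its area is the GA score

    GA(t) = sum_{i=1..TN} dx * sum_{j=1..n(i)} dy,   dx = 1/TN, dy = 1/TP

where n(i) counts positives above the i-th negative — equivalently, the
fraction of (positive, negative) pairs ranked positive-first.  yGA weights
every positive step by that neighbor's Z-score, rewarding models whose
functionally similar neighbors are also the structurally closest; yGA
values are only comparable among models of one target.  Combined scores
average a few thresholds (GA_579 = mean of GA at 0.5/0.7/0.9) and metaGA
averages all hundred thresholds 0.01..1.00.

A model whose neighbor search finds fewer than five significant neighbors
(Z >= 2) is scored 0 outright: a structure that resembles no real protein
is presumed wrong.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

from .neighbors import Slist, count_significant

#: The four yGA variants the outlier-exclusion step votes over.
EXCLUSION_METRICS = ("yGA_468", "yGA_567", "yGA_579", "yGA_678")

_NAME_RE = re.compile(r"^(y?GA)_([1-9]{1,9})$")


@dataclass(frozen=True)
class MetricSpec:
    """A named score: family GA/yGA plus an FS-threshold digit set, or metaGA.

    Threshold digits f in {1..9} denote thresholds f/10, so ``GA_579``
    averages GA at 0.5, 0.7 and 0.9.  metaGA takes no threshold set.
    """

    family: str  # "GA" | "yGA" | "metaGA"
    thresholds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.family == "metaGA":
            if self.thresholds:
                raise ValueError("metaGA takes no threshold set")
        elif self.family in ("GA", "yGA"):
            if not self.thresholds:
                raise ValueError(f"{self.family} requires at least one threshold")
            if any(f not in range(1, 10) for f in self.thresholds):
                raise ValueError("threshold digits must be in 1..9")
        else:
            raise ValueError(f"unknown score family {self.family!r}")

    @property
    def name(self) -> str:
        if self.family == "metaGA":
            return "metaGA"
        return f"{self.family}_{''.join(str(f) for f in self.thresholds)}"

    @classmethod
    def parse(cls, name: str) -> "MetricSpec":
        if name == "metaGA":
            return cls("metaGA")
        match = _NAME_RE.match(name)
        if match is None:
            raise ValueError(
                f"unrecognised metric name {name!r}; expected 'metaGA', "
                "'GA_<digits>' or 'yGA_<digits>' with digits in 1..9"
            )
        family, digits = match.groups()
        return cls(family, tuple(int(d) for d in digits))


DEFAULT_METRICS = tuple(
    MetricSpec.parse(n) for n in ("metaGA", "GA_468", "GA_579", "yGA_468", "yGA_579")
)


@dataclass(frozen=True)
class QualityScore:
    model_id: str
    metric: str
    value: float
    zero_rule_applied: bool = False
    excluded: bool = False


def classify(slist: Slist, fs_threshold) -> list[bool]:
    """Positive/negative labels for each record, in Slist order.

    A record is positive iff its FS strictly exceeds the threshold.
    Thresholds may be given as exact rationals (``Fraction(7, 100)``); they
    are compared through their nearest float so that an FS read from text
    as ``0.07`` is *not* a positive at threshold 0.07.
    """
    t = float(fs_threshold)
    return [r.fs > t for r in slist.records]


def ga_score(slist: Slist, fs_threshold) -> float:
    """Area under the stepwise ROC curve at one FS-threshold, in [0, 1].

    Degenerate labelings: no positives scores 0; no negatives scores 1
    (the curve rises fully before its single terminal step).
    """
    labels = classify(slist, fs_threshold)
    tp = sum(labels)
    tn = len(labels) - tp
    if tp == 0:
        return 0.0
    if tn == 0:
        return 1.0
    pairs_before = 0
    n_above = 0
    for positive in labels:
        if positive:
            n_above += 1
        else:
            pairs_before += n_above
    return pairs_before / (tp * tn)


def yga_score(slist: Slist, fs_threshold) -> float:
    """Z-weighted ROC area: each positive step has height dy * Z, >= 0."""
    labels = classify(slist, fs_threshold)
    tp = sum(labels)
    tn = len(labels) - tp
    if tp == 0:
        return 0.0
    z_positive_sum = sum(
        r.z_score for r, positive in zip(slist.records, labels) if positive
    )
    if tn == 0:
        return z_positive_sum / tp
    total = 0.0
    cum_z = 0.0
    for record, positive in zip(slist.records, labels):
        if positive:
            cum_z += record.z_score
        else:
            total += cum_z
    return total / (tp * tn)


def combined_score(slist: Slist, spec: MetricSpec) -> float:
    """Mean of single-threshold scores at thresholds {f/10 : f in spec}."""
    if spec.family not in ("GA", "yGA"):
        raise ValueError(f"combined_score is defined for GA/yGA, not {spec.family}")
    single = ga_score if spec.family == "GA" else yga_score
    values = [single(slist, Fraction(f, 10)) for f in spec.thresholds]
    return sum(values) / len(values)


def meta_ga(slist: Slist) -> float:
    """Mean GA over the hundred FS-thresholds i/100, i = 1..100."""
    return sum(ga_score(slist, Fraction(i, 100)) for i in range(1, 101)) / 100


def evaluate_metric(slist: Slist, spec: MetricSpec) -> float:
    if spec.family == "metaGA":
        return meta_ga(slist)
    return combined_score(slist, spec)


def score_model(
    slist: Slist,
    specs: Sequence[MetricSpec] = DEFAULT_METRICS,
    z_min: float = 2.0,
    min_significant: int = 5,
) -> list[QualityScore]:
    """All requested scores for one model, applying the zero rule.

    With fewer than ``min_significant`` neighbors at Z >= ``z_min`` the
    model is assumed to resemble no known protein and every score is 0.
    """
    if count_significant(slist, z_min) < min_significant:
        return [
            QualityScore(slist.model_id, spec.name, 0.0, zero_rule_applied=True)
            for spec in specs
        ]
    return [
        QualityScore(slist.model_id, spec.name, evaluate_metric(slist, spec))
        for spec in specs
    ]


def score_table(
    slists: Iterable[Slist],
    specs: Sequence[MetricSpec] = DEFAULT_METRICS,
    z_min: float = 2.0,
    min_significant: int = 5,
) -> pd.DataFrame:
    """Long-format score table: model_id, metric, value, zero_rule, excluded."""
    rows = [
        {
            "model_id": qs.model_id,
            "metric": qs.metric,
            "value": qs.value,
            "zero_rule": qs.zero_rule_applied,
            "excluded": qs.excluded,
        }
        for slist in slists
        for qs in score_model(slist, specs, z_min, min_significant)
    ]
    return pd.DataFrame(rows, columns=["model_id", "metric", "value", "zero_rule", "excluded"])


def write_score_table(table: pd.DataFrame, path_or_stream) -> None:
    table.to_csv(path_or_stream, sep="\t", index=False)


def read_score_table(path_or_stream) -> pd.DataFrame:
    table = pd.read_csv(path_or_stream, sep="\t")
    for flag in ("zero_rule", "excluded"):
        if flag in table:
            table[flag] = table[flag].astype(bool)
    return table
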