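"""Interpretability of the stage-attention scores.

After training, every subject carries 11 stage-attention scores.  Two
summaries turn them into a picture of *when* the discriminative behaviour
happens:

* the cohort-wide mean percent score per stage, and
* per class, the distribution rate of the top-3 stages: for each subject
  the 3 highest-scoring stages are found, and rate(stage) is the percent of
  all (subject x top-3-slot) assignments in the class that land on that
  stage.  Each subject contributes exactly 3 slots, so each class row sums
  to 100.

The clinically interesting signature is an at-risk class whose top-3 mass
concentrates on the later wait/game pairs (the child loses interest as the
game repeats) while the normal and ADHD rows stay roughly uniform.
``risk_localization_report`` tests exactly that as a late/early rate ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import EARLY_STAGES, LATE_STAGES, N_STAGES, STAGES, Label
from .model import AttentionProfile

__all__ = [
    "StageAttentionSummary",
    "average_attention",
    "top3_distribution",
    "summarize_attention",
    "risk_localization_report",
    "RiskLocalizationReport",
]

_EARLY = [int(s) for s in EARLY_STAGES]
_LATE = [int(s) for s in LATE_STAGES]


@dataclass(frozen=True)
class StageAttentionSummary:
    """Cohort attention summary: mean percents and per-class top-3 rates."""

    mean_percent: np.ndarray                 # (11,), sums to 100
    distribution_rates: dict[Label, np.ndarray]  # each (11,), sums to 100
    class_sizes: dict[Label, int]

    def mean_table(self) -> dict[str, float]:
        return {s.name: float(v) for s, v in zip(STAGES, self.mean_percent)}

    def rates_table(self) -> dict[str, dict[str, float]]:
        return {
            lab.value: {
                s.name: float(v) for s, v in zip(STAGES, rates)
            }
            for lab, rates in self.distribution_rates.items()
        }


def average_attention(
    profiles: Sequence[AttentionProfile],
) -> np.ndarray:
    """Arithmetic mean of the percent-normalised scores per stage."""
    if len(profiles) == 0:
        raise ValueError("no attention profiles given")
    return np.mean([p.percent_scores for p in profiles], axis=0)


def top3_distribution(
    profiles: Sequence[AttentionProfile],
    labels: Sequence[Label],
    k: int = 3,
) -> dict[Label, np.ndarray]:
    """Per-class top-k stage distribution rates in percent.

    Ties are broken earliest-stage-first (a documented convention; scores
    are continuous so exact ties essentially never occur in practice).
    Classes with no subjects are omitted with a warning.
    """
    if len(profiles) != len(labels):
        raise ValueError("profiles and labels length mismatch")
    if len(profiles) == 0:
        raise ValueError("no attention profiles given")
    slot_counts: dict[Label, np.ndarray] = {
        lab: np.zeros(N_STAGES) for lab in Label
    }
    sizes: dict[Label, int] = {lab: 0 for lab in Label}
    for profile, lab in zip(profiles, labels):
        sizes[lab] += 1
        for stage in profile.top_stages(k):
            slot_counts[lab][int(stage)] += 1
    rates: dict[Label, np.ndarray] = {}
    for lab in Label:
        if sizes[lab] == 0:
            warnings.warn(
                f"class {lab.value} has no subjects; omitted from "
                "top-3 distribution",
                stacklevel=2,
            )
            continue
        rates[lab] = 100.0 * slot_counts[lab] / (k * sizes[lab])
    return rates


def summarize_attention(
    profiles: Sequence[AttentionProfile],
    labels: Sequence[Label],
) -> StageAttentionSummary:
    rates = top3_distribution(profiles, labels)
    sizes = {lab: sum(1 for l in labels if l is lab) for lab in rates}
    return StageAttentionSummary(
        mean_percent=average_attention(profiles),
        distribution_rates=rates,
        class_sizes=sizes,
    )


@dataclass(frozen=True)
class RiskLocalizationReport:
    """Late-vs-early concentration of top-3 attention mass, per class.

    ``early`` averages the rates over wait/game pairs 1-2, ``late`` over
    pairs 3-5 (the explanation stage belongs to neither).  A class is
    flagged when late/early exceeds ``threshold``; an all-zero early mean
    with nonzero late mass gives an infinite ratio and a flag.
    """

    early_mean: dict[Label, float]
    late_mean: dict[Label, float]
    ratio: dict[Label, float]
    flagged: dict[Label, bool]
    threshold: float

    def to_dict(self) -> dict:
        return {
            lab.value: {
                "early_mean": self.early_mean[lab],
                "late_mean": self.late_mean[lab],
                "late_early_ratio": self.ratio[lab],
                "flagged": self.flagged[lab],
            }
            for lab in self.ratio
        }


def risk_localization_report(
    summary: StageAttentionSummary | Mapping[Label, np.ndarray],
    threshold: float = 2.0,
) -> RiskLocalizationReport:
    """Compare each class's top-3 rates before and after the 3rd-pair break."""
    rates = (
        summary.distribution_rates
        if isinstance(summary, StageAttentionSummary)
        else summary
    )
    early_mean: dict[Label, float] = {}
    late_mean: dict[Label, float] = {}
    ratio: dict[Label, float] = {}
    flagged: dict[Label, bool] = {}
    for lab, row in rates.items():
        row = np.asarray(row, dtype=float)
        e = float(row[_EARLY].mean())
        l = float(row[_LATE].mean())
        early_mean[lab] = e
        late_mean[lab] = l
        if e == 0.0:
            r = np.inf if l > 0.0 else 1.0
        else:
            r = l / e
        ratio[lab] = float(r)
        flagged[lab] = bool(r > threshold)
    return RiskLocalizationReport(
        early_mean=early_mean,
        late_mean=late_mean,
        ratio=ratio,
        flagged=flagged,
        threshold=threshold,
    )
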