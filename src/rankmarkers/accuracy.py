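"""Threshold-classifier diagnostic accuracy.

For each candidate gene a fixed RNA-quantity threshold is set at ``fold``
times the maximum value observed among control samples (fold = 5 by
default). A tumor sample counts as a true positive when its value strictly
exceeds the threshold; a control counts as a true negative when its value
is at or below it. Sensitivity = (TP/P) x 100, specificity = (TN/N) x 100.
With fold > 1 the threshold exceeds every control value whenever the
control maximum is positive, so specificity is 100% by construction and
the single reported operating point characterizes each gene by its
sensitivity alone, binned to the nearest 5%.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass

import pandas as pd

from .validation import NormalizedRun


@dataclass(frozen=True)
class ThresholdConfig:
    fold: float = 5.0

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError(f"fold must be positive, got {self.fold}")


@dataclass(frozen=True)
class AccuracyReport:
    gene_id: str
    threshold: float
    TP: int
    P: int
    TN: int
    N: int
    sensitivity: float  # percent
    specificity: float  # percent
    tier: str  # nearest-5% sensitivity label, e.g. "95%"
    degenerate_controls: bool  # all controls exactly zero


def gene_threshold(control_values: list[float], cfg: ThresholdConfig | None = None) -> float:
    """fold x max(control values); errors on an empty control list."""
    cfg = cfg or ThresholdConfig()
    values = list(control_values)
    if not values:
        raise ValueError("cannot set a threshold from an empty control list")
    return cfg.fold * max(values)


def sensitivity_tier(sensitivity: float) -> str:
    """Nearest-5% label with half-up rounding (95.238% -> \"95%\")."""
    return f"{int(math.floor(sensitivity / 5.0 + 0.5)) * 5}%"


def accuracy_report(
    gene_id: str,
    values: pd.Series,
    labels: dict[str, str],
    cfg: ThresholdConfig | None = None,
    tumor_label: str = "tumor",
    control_label: str = "normal",
) -> AccuracyReport:
    """Single-gene threshold classification of tumor vs control samples.

    ``values`` is the gene's per-sample vector indexed by sample id. Strict
    ``>`` decides positives and ``<=`` negatives, so a value exactly at the
    threshold counts negative. All-zero controls give the degenerate
    threshold 0 (flagged in the report); a control at exactly 0 then still
    counts as a true negative.
    """
    cfg = cfg or ThresholdConfig()
    tumor = [s for s in values.index if labels[s] == tumor_label]
    control = [s for s in values.index if labels[s] == control_label]
    if not tumor or not control:
        raise ValueError(
            f"need non-empty tumor ({len(tumor)}) and control ({len(control)}) cohorts"
        )
    control_values = values.loc[control].astype(float)
    threshold = gene_threshold(list(control_values), cfg)
    tumor_values = values.loc[tumor].astype(float)
    tp = int((tumor_values > threshold).sum())
    tn = int((control_values <= threshold).sum())
    p, n = len(tumor), len(control)
    sens = 100.0 * tp / p
    spec = 100.0 * tn / n
    return AccuracyReport(
        gene_id=gene_id,
        threshold=threshold,
        TP=tp,
        P=p,
        TN=tn,
        N=n,
        sensitivity=sens,
        specificity=spec,
        tier=sensitivity_tier(sens),
        degenerate_controls=float(control_values.max()) == 0.0,
    )


def panel_accuracy(
    run: NormalizedRun,
    labels: dict[str, str] | None = None,
    cfg: ThresholdConfig | None = None,
    genes: list[str] | None = None,
    tumor_label: str = "tumor",
    control_label: str = "normal",
) -> list[AccuracyReport]:
    """Accuracy reports for every panel (non-housekeeping) gene of a run."""
    matrix = run.matrix
    labels = labels if labels is not None else matrix.sample_labels
    if labels is None:
        raise ValueError("no sample labels available")
    genes = genes if genes is not None else [
        g for g in matrix.gene_ids if g not in run.hk_genes
    ]
    return [
        accuracy_report(g, matrix.values.loc[g], labels, cfg, tumor_label, control_label)
        for g in genes
    ]


def tier_summary(reports: list[AccuracyReport]) -> "OrderedDict[str, list[str]]":
    """Map sensitivity tier -> gene ids, highest tier first.

    Tiers with no genes are absent from the map rather than zero-valued.
    """
    if not reports:
        raise ValueError("no accuracy reports to summarize")
    tiers: dict[str, list[str]] = {}
    for r in reports:
        tiers.setdefault(r.tier, []).append(r.gene_id)
    ordered = OrderedDict(
        sorted(tiers.items(), key=lambda kv: -int(kv[0].rstrip("%")))
    )
    return ordered


def tier_counts(reports: list[AccuracyReport]) -> "OrderedDict[str, int]":
    """Gene count per sensitivity tier, highest tier first."""
    return OrderedDict((t, len(g)) for t, g in tier_summary(reports).items())
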