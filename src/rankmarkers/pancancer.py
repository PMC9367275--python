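"""Pan-cancer interval non-overlap discrimination.

Given a pan-cancer expression matrix (one cohort per tumor type), each
(type, gene) pair gets an expression interval [lo, hi] -- the full
min-max range by default, or a trimmed quantile range. A gene
discriminates the target type from another type when their intervals are
disjoint (closed intervals: touching endpoints count as overlap, the
conservative reading). A panel of genes covers, in combination, the union
of the types each member discriminates; the residual is the set of types
no panel gene separates from the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


def expression_interval(values, trim_quantile: float = 0.0) -> tuple[float, float]:
    """Empirical (quantile(q), quantile(1-q)) interval of a value list.

    ``trim_quantile`` = 0 gives the plain (min, max) range; larger values
    trim extremes symmetrically. Quantiles use linear interpolation between
    order statistics.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot form an interval from no values")
    if not 0 <= trim_quantile < 0.5:
        raise ValueError(f"trim_quantile must be in [0, 0.5), got {trim_quantile}")
    if trim_quantile == 0:
        return float(arr.min()), float(arr.max())
    lo = float(np.quantile(arr, trim_quantile, method="linear"))
    hi = float(np.quantile(arr, 1 - trim_quantile, method="linear"))
    return lo, hi


@dataclass
class IntervalTable:
    """Per (tumor type, gene) expression intervals."""

    intervals: pd.DataFrame  # MultiIndex (type, gene); columns lo, hi
    trim_quantile: float = 0.0

    @property
    def types(self) -> list[str]:
        return sorted(self.intervals.index.get_level_values(0).unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.intervals.index.get_level_values(1).unique())

    def interval(self, type_name: str, gene: str) -> tuple[float, float]:
        if (type_name, gene) not in self.intervals.index:
            raise KeyError(f"no interval for type {type_name!r}, gene {gene!r}")
        row = self.intervals.loc[(type_name, gene)]
        return float(row["lo"]), float(row["hi"])


def build_interval_table(
    matrix: ExpressionMatrix,
    type_labels: dict[str, str] | None = None,
    trim_quantile: float = 0.0,
    genes: list[str] | None = None,
) -> IntervalTable:
    """Expression intervals for every (type, gene) with >= 1 sample."""
    type_labels = type_labels if type_labels is not None else matrix.sample_labels
    if type_labels is None:
        raise ValueError("no tumor-type labels available")
    genes = genes if genes is not None else matrix.gene_ids
    by_type: dict[str, list[str]] = {}
    for s in matrix.sample_ids:
        by_type.setdefault(type_labels[s], []).append(s)
    rows, index = [], []
    for type_name, samples in sorted(by_type.items()):
        sub = matrix.values.loc[genes, samples]
        for gene in genes:
            lo, hi = expression_interval(sub.loc[gene].to_numpy(), trim_quantile)
            rows.append((lo, hi))
            index.append((type_name, gene))
    table = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["type", "gene"]),
        columns=["lo", "hi"],
    )
    return IntervalTable(intervals=table, trim_quantile=trim_quantile)


def intervals_disjoint(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """Closed-interval disjointness: shared endpoints count as overlap."""
    return a[1] < b[0] or b[1] < a[0]


def non_overlap_verdicts(table: IntervalTable, target_type: str, gene: str) -> set[str]:
    """Types whose interval for ``gene`` is disjoint from the target's."""
    if target_type not in table.types:
        raise KeyError(f"unknown tumor type {target_type!r}")
    if gene not in table.genes:
        raise KeyError(f"unknown gene {gene!r}")
    target = table.interval(target_type, gene)
    result = set()
    for t in table.types:
        if t == target_type:
            continue
        if intervals_disjoint(target, table.interval(t, gene)):
            result.add(t)
    return result


@dataclass
class DiscriminationResult:
    """Combined discrimination coverage of a gene panel against one type."""

    target_type: str
    per_gene: dict[str, set[str]] = field(default_factory=dict)
    covered: set[str] = field(default_factory=set)
    residual: set[str] = field(default_factory=set)


def combine_panel(
    table: IntervalTable, target_type: str, genes: list[str]
) -> DiscriminationResult:
    """Union the per-gene non-overlap verdicts; residual = uncovered types."""
    if not genes:
        raise ValueError("gene panel is empty")
    per_gene = {g: non_overlap_verdicts(table, target_type, g) for g in genes}
    covered: set[str] = set()
    for verdict in per_gene.values():
        covered |= verdict
    others = {t for t in table.types if t != target_type}
    return DiscriminationResult(
        target_type=target_type,
        per_gene=per_gene,
        covered=covered,
        residual=others - covered,
    )
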