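"""Rank-based cross-platform biomarker discovery.

Two bulk transcriptome cohorts quantified on incompatible scales (e.g. a
TPM-quantified tumor cohort and an RPKM-quantified normal cohort with
different annotation universes) cannot be compared value-for-value. This
module implements the rank-tier workaround: intersect the two gene
universes, rank genes within each cohort by mean expression, and nominate
as putative over-expressed biomarkers the genes that sit in the top
``top_fraction`` of the tumor ranking and simultaneously in the bottom
``bottom_fraction`` of the normal ranking. Because ranking is invariant to
any positive rescaling of a cohort's values, the selection is well defined
across quantification schemes.

Tier boundaries use the ceiling: with 18,734 shared genes the top-5% tier
holds ceil(0.05 x 18734) = 937 genes and the bottom-50% tier holds 9,367.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import pandas as pd

from .matrix import ExpressionMatrix

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def normalize_gene_id(gene_id: str) -> str:
    """Canonicalize a gene identifier for cross-annotation matching.

    Strips surrounding whitespace and a trailing dot-version suffix
    (``ENSG000001.5`` -> ``ENSG000001``) and upper-cases the result, so
    identifiers that differ only in case or annotation version collide.
    """
    return _VERSION_SUFFIX.sub("", gene_id.strip()).upper()


def harmonize_gene_universe(ids_a: list[str], ids_b: list[str]) -> list[str]:
    """Sorted intersection of two gene universes after id normalization.

    Raises ``ValueError`` if normalization makes two ids within one list
    collide (e.g. ``TP53`` and ``tp53`` in the same cohort), naming the
    colliding identifiers.
    """
    normed = []
    for name, ids in (("first", ids_a), ("second", ids_b)):
        mapping: dict[str, str] = {}
        collisions = []
        for gid in ids:
            key = normalize_gene_id(gid)
            if key in mapping and mapping[key] != gid:
                collisions.append((mapping[key], gid))
            mapping[key] = gid
        if collisions:
            raise ValueError(
                f"duplicate gene ids after normalization in {name} list: {collisions}"
            )
        normed.append(set(mapping))
    return sorted(normed[0] & normed[1])


def mean_expression(matrix: ExpressionMatrix, genes: list[str] | None = None) -> pd.Series:
    """Per-gene arithmetic mean over all samples, on the raw linear scale.

    ``genes`` restricts (and orders) the output; ids absent from the matrix
    raise ``KeyError`` listing every missing id. Zeros are included in the
    mean -- no expression floor is applied.
    """
    if genes is not None:
        missing = [g for g in genes if g not in matrix.values.index]
        if missing:
            raise KeyError(f"gene ids not in matrix: {missing}")
        values = matrix.values.loc[genes]
    else:
        values = matrix.values
    return values.mean(axis=1)


def rank_genes(means: pd.Series) -> pd.DataFrame:
    """Rank genes by mean expression, highest first.

    Returns a DataFrame indexed by gene id with columns ``mean_expression``,
    ``rank`` (1 = highest mean) and ``rank_percentile`` (= 100 * rank / G).
    Ties in mean expression are broken lexicographically by gene id so the
    ranking is deterministic across runs and platforms.
    """
    if means.empty:
        raise ValueError("cannot rank an empty mean-expression table")
    order = sorted(means.index, key=lambda g: (-means[g], g))
    g_total = len(order)
    table = pd.DataFrame(
        {
            "mean_expression": means.loc[order].to_numpy(),
            "rank": range(1, g_total + 1),
        },
        index=pd.Index(order, name="gene_id"),
    )
    table["rank_percentile"] = 100.0 * table["rank"] / g_total
    return table


@dataclass(frozen=True)
class SelectionConfig:
    """Dual rank-tier selection fractions.

    ``top_fraction`` is the tumor tier (highest mean expression) and
    ``bottom_fraction`` the normal tier (lowest mean expression); both must
    lie in (0, 1].
    """

    top_fraction: float = 0.05
    bottom_fraction: float = 0.50

    def __post_init__(self) -> None:
        for name in ("top_fraction", "bottom_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class BiomarkerPanel:
    """Genes passing both rank-tier criteria, with provenance."""

    genes: list[str]
    table: pd.DataFrame  # index gene_id; tumor_rank_percentile, normal_rank_percentile
    top_tier_size: int
    bottom_tier_size: int
    universe_size: int
    config: SelectionConfig = field(default_factory=SelectionConfig)


def select_biomarkers(
    tumor_ranks: pd.DataFrame,
    normal_ranks: pd.DataFrame,
    cfg: SelectionConfig | None = None,
) -> BiomarkerPanel:
    """Intersect the tumor top tier with the normal bottom tier.

    Both rank tables must cover the same gene universe of size G. The top
    tier is ranks <= ceil(G * top_fraction) in the tumor table; the bottom
    tier is ranks >= G - ceil(G * bottom_fraction) + 1 in the normal table.
    """
    cfg = cfg or SelectionConfig()
    tumor_universe = set(tumor_ranks.index)
    normal_universe = set(normal_ranks.index)
    if tumor_universe != normal_universe:
        only_t = sorted(tumor_universe - normal_universe)[:10]
        only_n = sorted(normal_universe - tumor_universe)[:10]
        raise ValueError(
            "rank tables cover different gene universes; "
            f"tumor-only (first 10): {only_t}; normal-only (first 10): {only_n}"
        )
    g_total = len(tumor_universe)
    top_size = math.ceil(g_total * cfg.top_fraction)
    bottom_size = math.ceil(g_total * cfg.bottom_fraction)
    bottom_min_rank = g_total - bottom_size + 1

    top_tier = set(tumor_ranks.index[tumor_ranks["rank"] <= top_size])
    bottom_tier = set(normal_ranks.index[normal_ranks["rank"] >= bottom_min_rank])
    panel_genes = sorted(top_tier & bottom_tier)

    table = pd.DataFrame(
        {
            "tumor_rank_percentile": tumor_ranks.loc[panel_genes, "rank_percentile"],
            "normal_rank_percentile": normal_ranks.loc[panel_genes, "rank_percentile"],
        },
        index=pd.Index(panel_genes, name="gene_id"),
    )
    return BiomarkerPanel(
        genes=panel_genes,
        table=table,
        top_tier_size=top_size,
        bottom_tier_size=bottom_size,
        universe_size=g_total,
        config=cfg,
    )


def discover_panel(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    cfg: SelectionConfig | None = None,
) -> BiomarkerPanel:
    """End-to-end discovery: harmonize universes, rank each cohort, select.

    Gene ids are canonicalized before intersection, so cohorts annotated
    with differing case or version suffixes line up. Rank tables are built
    on the harmonized universe only.
    """
    common = harmonize_gene_universe(tumor.gene_ids, normal.gene_ids)
    if not common:
        raise ValueError("cohorts share no genes after identifier normalization")

    def restrict(matrix: ExpressionMatrix) -> pd.Series:
        renamed = matrix.values.copy()
        renamed.index = [normalize_gene_id(g) for g in renamed.index]
        means = renamed.loc[common].mean(axis=1)
        return means

    tumor_ranks = rank_genes(restrict(tumor))
    normal_ranks = rank_genes(restrict(normal))
    return select_biomarkers(tumor_ranks, normal_ranks, cfg)
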