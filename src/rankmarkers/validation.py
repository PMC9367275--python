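"""Digital-count panel validation: normalization, testing, PCA, clustering.

A custom nCounter-style code set measures a few dozen candidate genes plus
a handful of housekeeping genes as raw digital counts. Per-sample technical
scale (lane) differences are removed by geometric-mean housekeeping
normalization; each candidate gene is then screened for a tumor-vs-normal
expression shift with a two-sided Wilcoxon rank-sum test, and the samples
are visualized via PCA (ln-transform, per-gene unit-variance scaling, SVD)
with per-cohort 95% concentration ellipses, and via hierarchical clustering
with Chebyshev distance and complete linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

SIGNIFICANCE_CUTPOINTS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class NormalizedRun:
    """Housekeeping-normalized panel run.

    After normalization the geometric mean of the housekeeping genes is the
    same constant in every sample (to 1e-9 relative tolerance), so any
    remaining between-sample differences in panel genes are biological.
    """

    matrix: ExpressionMatrix  # unit_label == "normalized-count"
    scale_factors: dict[str, float]
    hk_genes: list[str]


def normalize_housekeeping(raw: ExpressionMatrix, hk_genes: list[str]) -> NormalizedRun:
    """Scale each sample so housekeeping geometric means agree.

    The per-sample factor is (arithmetic mean across samples of the
    per-sample housekeeping geometric means) divided by this sample's
    housekeeping geometric mean; every gene in the sample is multiplied by
    it. This is the standard digital-count convention for housekeeping
    content normalization.

    Raises ``ValueError`` on an empty housekeeping list, on housekeeping
    ids missing from the matrix, or on a zero housekeeping count (the
    geometric mean would vanish), naming the offending gene and sample.
    """
    if not hk_genes:
        raise ValueError("housekeeping gene list is empty")
    missing = [g for g in hk_genes if g not in raw.values.index]
    if missing:
        raise ValueError(f"housekeeping genes not in matrix: {missing}")
    hk = raw.values.loc[hk_genes]
    zero = np.argwhere(hk.to_numpy() <= 0)
    if zero.size:
        gi, si = zero[0]
        raise ValueError(
            f"housekeeping gene {hk.index[gi]!r} has non-positive count in "
            f"sample {hk.columns[si]!r}; cannot normalize"
        )
    geo_means = np.exp(np.log(hk).mean(axis=0))  # per sample
    target = geo_means.mean()
    factors = target / geo_means
    normalized = raw.values * factors
    return NormalizedRun(
        matrix=raw.with_values(normalized, unit_label="normalized-count"),
        scale_factors=factors.to_dict(),
        hk_genes=list(hk_genes),
    )


@dataclass(frozen=True)
class GeneTestResult:
    gene_id: str
    p_value: float
    significance_band: str  # ns / * / ** / ***
    bh_fdr: float


def _significance_band(p: float) -> str:
    for cut, band in SIGNIFICANCE_CUTPOINTS:
        if p < cut:
            return band
    return "ns"


def _wilcoxon_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution when the smaller group has <= 10
    observations and the pooled values are tie-free; otherwise the normal
    approximation with tie correction and continuity correction. A pooled
    sample with zero rank variance (all values tied) carries no evidence
    and returns p = 1.
    """
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        return 1.0
    if min(len(x), len(y)) <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    p = float(res.pvalue)
    if np.isnan(p):  # tie-corrected variance collapsed
        return 1.0
    return min(p, 1.0)


def wilcoxon_screen(
    run: NormalizedRun,
    labels: dict[str, str] | None = None,
    genes: list[str] | None = None,
) -> list[GeneTestResult]:
    """Per-gene two-sided Wilcoxon rank-sum screen between two cohorts.

    ``labels`` defaults to the run's attached sample labels and must define
    exactly two cohorts, each with at least one sample. Star bands use raw
    p-values with cut-points 0.05 / 0.01 / 0.001 (no multiple-testing
    adjustment); a Benjamini-Hochberg FDR column is reported alongside but
    does not drive the banding.
    """
    matrix = run.matrix
    labels = labels if labels is not None else matrix.sample_labels
    if labels is None:
        raise ValueError("no sample labels available for the screen")
    groups: dict[str, list[str]] = {}
    for s in matrix.sample_ids:
        groups.setdefault(labels[s], []).append(s)
    if len(groups) != 2:
        raise ValueError(f"screen needs exactly two cohorts, got {sorted(groups)}")
    for name, members in groups.items():
        if not members:
            raise ValueError(f"cohort {name!r} has no samples")
    (ga, sa), (gb, sb) = groups.items()

    genes = genes if genes is not None else [
        g for g in matrix.gene_ids if g not in run.hk_genes
    ]
    pvals = []
    for g in genes:
        x = matrix.values.loc[g, sa].to_numpy(dtype=float)
        y = matrix.values.loc[g, sb].to_numpy(dtype=float)
        pvals.append(_wilcoxon_p(x, y))
    fdr = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    return [
        GeneTestResult(g, p, _significance_band(p), float(q))
        for g, p, q in zip(genes, pvals, fdr)
    ]


# -- PCA ---------------------------------------------------------------------


@dataclass
class ConfidenceEllipse:
    """95% concentration ellipse of a 2-D Gaussian fitted to group scores."""

    center: np.ndarray  # (2,)
    axes: np.ndarray  # semi-axis lengths, descending
    orientation: np.ndarray  # 2x2 rotation, columns = axis directions
    _cov_inv: np.ndarray
    _chi2_q: float

    def contains(self, point: np.ndarray) -> bool:
        d = np.asarray(point, dtype=float) - self.center
        return float(d @ self._cov_inv @ d) <= self._chi2_q


def _fit_ellipse(scores_2d: np.ndarray, coverage: float = 0.95) -> ConfidenceEllipse:
    chi2_q = stats.chi2.ppf(coverage, df=2)
    center = scores_2d.mean(axis=0)
    if scores_2d.shape[0] > 1:
        cov = np.cov(scores_2d, rowvar=False)
    else:
        cov = np.zeros((2, 2))
    eigval, eigvec = np.linalg.eigh(cov)
    # floor near-zero eigenvalues so a degenerate point-cluster yields a
    # point-like ellipse instead of a pseudo-inverse that contains everything
    floor = 1e-12 * max(eigval.max(), 1.0)
    eigval = np.clip(eigval, floor, None)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    cov_inv = eigvec @ np.diag(1.0 / eigval) @ eigvec.T
    return ConfidenceEllipse(
        center=center,
        axes=np.sqrt(eigval * chi2_q),
        orientation=eigvec,
        _cov_inv=cov_inv,
        _chi2_q=chi2_q,
    )


@dataclass
class PcaResult:
    """Sample scores, explained variance and per-group 95% ellipses."""

    scores: pd.DataFrame  # samples x components, columns PC1..PCk
    explained_variance_pct: np.ndarray
    loadings: pd.DataFrame  # genes x components
    ellipses: dict[str, ConfidenceEllipse]
    transformed: pd.DataFrame  # the standardized ln-matrix the SVD ran on
    dropped_genes: list[str]


def transform_for_pca(
    matrix: ExpressionMatrix, pseudocount: float = 1.0
) -> tuple[pd.DataFrame, list[str]]:
    """ln(x + pseudocount) then per-gene centering and unit-variance scaling.

    Genes with zero variance after the transform cannot be scaled and are
    dropped with a warning. Returns (standardized genes x samples matrix,
    dropped gene ids).
    """
    logged = np.log(matrix.values + pseudocount)
    sd = logged.std(axis=1, ddof=1)
    dropped = list(logged.index[sd == 0])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance gene(s) before scaling: {dropped}",
            stacklevel=2,
        )
    kept = logged.loc[sd > 0]
    standardized = kept.sub(kept.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    return standardized, dropped


def pca_samples(
    run: NormalizedRun,
    labels: dict[str, str] | None = None,
    pseudocount: float = 1.0,
    ellipse_coverage: float = 0.95,
) -> PcaResult:
    """PCA of samples from the ln-transformed, row-standardized matrix.

    The SVD runs on the genes x samples matrix after per-gene
    standardization; sample scores on component k are the k-th right
    singular vector scaled by its singular value, and explained-variance
    percentages are the squared singular values as a share of their total
    (they sum to 100 when every component is kept). Per-group 95%
    concentration ellipses are fitted to the (PC1, PC2) scores using the
    chi-square(2) quantile.
    """
    matrix = run.matrix
    if matrix.n_samples < 3 or matrix.n_genes < 2:
        raise ValueError("PCA needs at least 3 samples and 2 genes")
    standardized, dropped = transform_for_pca(matrix, pseudocount)
    X = standardized.to_numpy()
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = S.size
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(
        (Vt.T * S), index=matrix.sample_ids, columns=comp_names
    )
    loadings = pd.DataFrame(U, index=standardized.index, columns=comp_names)
    total = float((S**2).sum())
    explained = 100.0 * S**2 / total if total > 0 else np.zeros(k)

    labels = labels if labels is not None else matrix.sample_labels
    ellipses: dict[str, ConfidenceEllipse] = {}
    if labels is not None and k >= 2:
        by_group: dict[str, list[str]] = {}
        for s in matrix.sample_ids:
            by_group.setdefault(labels[s], []).append(s)
        for group, members in by_group.items():
            pts = scores.loc[members, ["PC1", "PC2"]].to_numpy()
            ellipses[group] = _fit_ellipse(pts, ellipse_coverage)

    return PcaResult(
        scores=scores,
        explained_variance_pct=explained,
        loadings=loadings,
        ellipses=ellipses,
        transformed=standardized,
        dropped_genes=dropped,
    )


# -- heatmap ordering --------------------------------------------------------


@dataclass
class HeatmapOrder:
    gene_order: list[str]
    sample_order: list[str]
    gene_linkage: np.ndarray
    sample_linkage: np.ndarray


def heatmap_order(run: NormalizedRun, pseudocount: float = 1.0) -> HeatmapOrder:
    """Leaf orders from complete-linkage clustering with Chebyshev distance.

    Both axes are clustered on the same ln-transformed, row-standardized
    matrix used for PCA: genes on the rows, samples on the columns.
    """
    matrix = run.matrix
    if matrix.n_genes < 2 or matrix.n_samples < 2:
        raise ValueError("clustering needs at least 2 genes and 2 samples")
    standardized, _ = transform_for_pca(matrix, pseudocount)
    X = standardized.to_numpy()
    gene_link = linkage(pdist(X, metric="chebyshev"), method="complete")
    sample_link = linkage(pdist(X.T, metric="chebyshev"), method="complete")
    gene_order = [standardized.index[i] for i in leaves_list(gene_link)]
    sample_order = [standardized.columns[i] for i in leaves_list(sample_link)]
    return HeatmapOrder(
        gene_order=gene_order,
        sample_order=sample_order,
        gene_linkage=gene_link,
        sample_linkage=sample_link,
    )
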