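"""Housekeeping normalization, Wilcoxon screen, PCA and clustering order."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

import rankmarkers as rm
from rankmarkers.validation import _wilcoxon_p, transform_for_pca

from conftest import make_matrix


def exact_ranksum_p(x, y):
    """Exhaustive two-sided rank-sum p-value over all label assignments.

    Enumerates every way to choose which pooled observations belong to the
    first group and counts assignments whose U statistic is at least as far
    from its null mean as the observed one. Independent of any library
    routine; only valid for tie-free data.
    """
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1, n2 = len(x), len(y)
    rank_of = {v: r for r, v in enumerate(pooled, start=1)}
    u_obs = sum(rank_of[v] for v in x) - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = sum(r + 1 for r in combo) - n1 * (n1 + 1) / 2
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestNormalizeHousekeeping:
    def test_identical_hk_counts_identity(self):
        m = make_matrix([[5, 5], [8, 8], [100, 200]], genes=["h1", "h2", "g"])
        run = rm.normalize_housekeeping(m, ["h1", "h2"])
        assert np.allclose(run.matrix.values.to_numpy(), m.values.to_numpy())
        assert all(abs(f - 1) < 1e-12 for f in run.scale_factors.values())

    def test_pure_scale_nuisance_removed(self):
        base = np.array([[5.0], [8.0], [40.0], [3.0]])
        vals = np.hstack([base, base * 2])  # sample B is exactly 2x sample A
        m = make_matrix(vals, genes=["h1", "h2", "g1", "g2"], samples=["A", "B"])
        run = rm.normalize_housekeeping(m, ["h1", "h2"])
        out = run.matrix.values
        assert np.allclose(out["A"], out["B"])

    def test_hk_geometric_means_equalized_on_simulated_run(self, panel_run):
        run = rm.normalize_housekeeping(panel_run.raw_counts, panel_run.hk_genes)
        hk = run.matrix.values.loc[run.hk_genes]
        geo = np.exp(np.log(hk).mean(axis=0)).to_numpy()
        assert np.ptp(geo) / geo.mean() < 1e-9

    def test_idempotence(self, normalized_run):
        again = rm.normalize_housekeeping(normalized_run.matrix, normalized_run.hk_genes)
        assert all(abs(f - 1) < 1e-9 for f in again.scale_factors.values())

    def test_zero_hk_count_errors_with_names(self):
        m = make_matrix([[0, 5], [10, 10]], genes=["h1", "g"], samples=["sA", "sB"])
        with pytest.raises(ValueError, match="h1.*sA"):
            rm.normalize_housekeeping(m, ["h1"])

    def test_empty_hk_list_errors(self):
        m = make_matrix([[1.0]])
        with pytest.raises(ValueError, match="empty"):
            rm.normalize_housekeeping(m, [])


class TestWilcoxonScreen:
    def test_fully_separated_3_vs_42_exact(self):
        # all 3 controls below all 42 tumors: exact two-sided p = 2/C(45,3)
        x = np.arange(1.0, 4.0)          # controls
        y = np.arange(10.0, 52.0)        # tumors
        p = _wilcoxon_p(x, y)
        assert p == pytest.approx(2 / math.comb(45, 3), abs=1e-15)

    def test_identical_single_samples_tie(self):
        assert _wilcoxon_p(np.array([4.0]), np.array([4.0])) == 1.0

    @pytest.mark.parametrize("n1,n2,seed", [(5, 5, 0), (3, 9, 1), (4, 6, 2),
                                            (2, 10, 3), (6, 6, 4), (1, 11, 5)])
    def test_matches_enumeration_oracle(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(1.0, n1 + n2 + 1) * 1.37)
        x, y = vals[:n1], vals[n1:]
        assert _wilcoxon_p(x, y) == pytest.approx(exact_ranksum_p(x, y), abs=1e-12)

    def test_bands_and_fdr_on_simulated_run(self, normalized_run):
        results = rm.wilcoxon_screen(normalized_run)
        assert len(results) == 41
        for r in results:
            if r.p_value < 0.001:
                assert r.significance_band == "***"
            elif r.p_value < 0.01:
                assert r.significance_band == "**"
            elif r.p_value < 0.05:
                assert r.significance_band == "*"
            else:
                assert r.significance_band == "ns"
            assert r.bh_fdr >= r.p_value - 1e-15

    def test_all_planted_genes_reach_three_stars(self):
        """Structural analogue of the all-significant validation screen.

        At the default over-expression fold (>= 5) and without the outlier
        every panel gene separates tumors from controls decisively.
        """
        run = rm.generate_nanostring_run(
            rm.PanelSimConfig(include_outlier=False, seed=21)
        )
        norm = rm.normalize_housekeeping(run.raw_counts, run.hk_genes)
        results = rm.wilcoxon_screen(norm)
        assert all(r.significance_band == "***" for r in results)

    def test_requires_two_cohorts(self, normalized_run):
        labels = {s: "tumor" for s in normalized_run.matrix.sample_ids}
        with pytest.raises(ValueError, match="two cohorts"):
            rm.wilcoxon_screen(normalized_run, labels=labels)


class TestPca:
    def test_explained_variance_sums_to_100(self, normalized_run):
        pca = rm.pca_samples(normalized_run)
        ev = pca.explained_variance_pct
        assert (ev >= 0).all()
        assert (np.diff(ev) <= 1e-9).all()
        assert ev.sum() == pytest.approx(100.0, abs=1e-6)

    def test_two_point_clusters(self):
        # two tight clusters separated along one direction
        rng = np.random.default_rng(0)
        a = rng.normal(10, 0.01, size=(6, 5))
        b = rng.normal(10, 0.01, size=(6, 5)) + 50
        m = make_matrix(np.hstack([a, b]),
                        samples=[f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)],
                        labels={**{f"a{i}": "A" for i in range(5)},
                                **{f"b{i}": "B" for i in range(5)}})
        run = rm.NormalizedRun(matrix=m, scale_factors={}, hk_genes=[])
        pca = rm.pca_samples(run)
        assert pca.explained_variance_pct[0] > 99.0
        ea, eb = pca.ellipses["A"], pca.ellipses["B"]
        assert not ea.contains(eb.center)
        assert not eb.contains(ea.center)

    def test_reconstruction_with_all_components(self, normalized_run):
        pca = rm.pca_samples(normalized_run)
        recon = pca.loadings.to_numpy() @ pca.scores.to_numpy().T
        assert np.allclose(recon, pca.transformed.to_numpy(), atol=1e-8)

    def test_zero_variance_gene_dropped_with_warning(self):
        vals = np.vstack([np.full(5, 7.0), np.arange(5.0), np.arange(5.0) * 2])
        m = make_matrix(vals, genes=["flat", "g1", "g2"])
        run = rm.NormalizedRun(matrix=m, scale_factors={}, hk_genes=[])
        with pytest.warns(UserWarning, match="flat"):
            pca = rm.pca_samples(run)
        assert pca.dropped_genes == ["flat"]

    def test_outlier_outside_tumor_ellipse(self, panel_run, normalized_run):
        pca = rm.pca_samples(normalized_run)
        point = pca.scores.loc[panel_run.outlier_sample, ["PC1", "PC2"]].to_numpy()
        assert not pca.ellipses["tumor"].contains(point)

    def test_too_few_samples_rejected(self):
        m = make_matrix([[1.0, 2.0], [3.0, 4.0]])
        run = rm.NormalizedRun(matrix=m, scale_factors={}, hk_genes=[])
        with pytest.raises(ValueError, match="at least 3 samples"):
            rm.pca_samples(run)


class TestHeatmapOrder:
    def test_identical_rows_merge_first(self):
        vals = np.array([[1.0, 2, 3, 9], [1.0, 2, 3, 9], [50, 1, 7, 2], [0, 40, 2, 6]])
        m = make_matrix(vals, genes=["a", "b", "c", "d"])
        run = rm.NormalizedRun(matrix=m, scale_factors={}, hk_genes=[])
        order = rm.heatmap_order(run)
        # identical rows remain identical after row standardization: the
        # first merge in the gene dendrogram is at height 0 between a and b
        first = order.gene_linkage[0]
        assert first[2] == pytest.approx(0.0, abs=1e-12)
        assert {int(first[0]), int(first[1])} == {0, 1}

    def test_hand_traced_complete_linkage_chebyshev(self):
        # 4 samples in 2-gene space; work on the standardized matrix the
        # implementation clusters, and trace complete linkage by hand
        vals = np.array([[0.0, 1.0, 10.0, 11.0], [0.0, 2.0, 9.0, 12.0]])
        m = make_matrix(vals, genes=["g1", "g2"], samples=["s1", "s2", "s3", "s4"])
        run = rm.NormalizedRun(matrix=m, scale_factors={}, hk_genes=[])
        std, _ = transform_for_pca(m)
        pts = std.to_numpy().T  # samples x genes

        def cheb(i, j):
            return np.abs(pts[i] - pts[j]).max()

        # pairwise distances
        d = {(i, j): cheb(i, j) for i in range(4) for j in range(i + 1, 4)}
        # complete linkage trace: closest pair merges first, then clusters
        # join at the max pairwise distance between members
        first_pair = min(d, key=d.get)
        order = rm.heatmap_order(run)
        link = order.sample_linkage
        assert {int(link[0][0]), int(link[0][1])} == set(first_pair)
        assert link[0][2] == pytest.approx(d[first_pair], abs=1e-12)
        # final merge height = max over all cross-cluster pairs = max distance
        assert link[-1][2] == pytest.approx(max(d.values()), abs=1e-12)

    def test_sample_permutation_preserves_merge_heights(self, normalized_run):
        order = rm.heatmap_order(normalized_run)
        rng = np.random.default_rng(13)
        perm = rng.permutation(normalized_run.matrix.sample_ids)
        shuffled = rm.NormalizedRun(
            matrix=normalized_run.matrix.with_values(
                normalized_run.matrix.values[list(perm)]
            ),
            scale_factors={},
            hk_genes=normalized_run.hk_genes,
        )
        order2 = rm.heatmap_order(shuffled)
        assert np.allclose(
            np.sort(order.sample_linkage[:, 2]), np.sort(order2.sample_linkage[:, 2])
        )
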