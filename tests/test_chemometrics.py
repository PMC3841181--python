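from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from chemoflock.chemometrics import (
    ChemometricsError, SimilarityMatrix, build_dendrogram, correlation_matrix,
    cut_groups, group_separation, pca, PCAResult,
)
from chemoflock.tcm import TCMSpectrum


def spec(values, individual_id="x"):
    vals = np.zeros(300)
    vals[: len(values)] = values
    return TCMSpectrum(individual_id=individual_id, values=vals)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

class TestCorrelation:
    def test_identical_spectra_have_r_one(self):
        s = [spec([1, 2, 3], "a"), spec([1, 2, 3], "b")]
        assert correlation_matrix(s).r[0, 1] == pytest.approx(1.0)

    def test_size_independence(self):
        # a scaled copy of a fingerprint is perfectly correlated with it
        s = [spec([1, 5, 2, 8], "a"), spec([3.7, 18.5, 7.4, 29.6], "b")]
        assert correlation_matrix(s).r[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_longhand_formula(self, rng):
        x = np.zeros(300)
        x[:50] = np.arange(1, 51)
        y = x.copy()
        rng.shuffle(y)
        s = [TCMSpectrum(individual_id="a", values=x),
             TCMSpectrum(individual_id="b", values=y)]
        r = correlation_matrix(s).r[0, 1]
        # independent longhand evaluation: cov / (sd * sd)
        longhand = (np.mean((x - x.mean()) * (y - y.mean()))
                    / (x.std() * y.std()))
        assert r == pytest.approx(longhand, abs=1e-12)

    def test_zero_variance_names_individual(self):
        s = [spec([1, 2, 3], "ok"), spec([0.0], "flatliner")]
        s[1].values[:] = 4.2
        with pytest.raises(ChemometricsError, match="flatliner"):
            correlation_matrix(s)

    def test_symmetry_unit_diagonal_bounds(self, rng):
        s = [TCMSpectrum(individual_id=f"i{k}", values=rng.random(300))
             for k in range(6)]
        m = correlation_matrix(s)
        assert np.allclose(m.r, m.r.T)
        assert np.allclose(np.diag(m.r), 1.0)
        assert np.all(m.r >= -1.0 - 1e-12) and np.all(m.r <= 1.0 + 1e-12)

    def test_per_individual_rescaling_changes_nothing(self, rng):
        s = [TCMSpectrum(individual_id=f"i{k}", values=rng.random(300) * 10)
             for k in range(5)]
        scales = rng.uniform(0.1, 50, size=5)
        scaled = [TCMSpectrum(individual_id=x.individual_id,
                              values=x.values * c)
                  for x, c in zip(s, scales)]
        np.testing.assert_allclose(correlation_matrix(s).r,
                                   correlation_matrix(scaled).r, atol=1e-12)


# ---------------------------------------------------------------------------
# dendrogram + cut
# ---------------------------------------------------------------------------

def sim_from(r, ids=None):
    r = np.asarray(r, float)
    ids = ids or [chr(ord("A") + i) for i in range(r.shape[0])]
    return SimilarityMatrix(ids=ids, r=r)


def oracle_average_linkage(r, ids):
    """Brute-force agglomeration: cluster distances recomputed from the
    original matrix as the mean over cross pairs at every step."""
    d = 1.0 - np.asarray(r, float)
    clusters = [frozenset([i]) for i in range(len(ids))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            pairs = [(i, j) for i in clusters[a] for j in clusters[b]]
            dist = float(np.mean([d[i, j] for i, j in pairs]))
            rep = tuple(sorted((min(ids[i] for i in clusters[a]),
                                min(ids[i] for i in clusters[b]))))
            key = (dist, *rep)
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        heights.append(best[0][0])
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return heights


class TestDendrogram:
    def test_two_individuals_single_merge(self):
        dend = build_dendrogram(sim_from([[1.0, 0.4], [0.4, 1.0]]))
        assert len(dend.merges) == 1
        assert dend.merges[0][2] == pytest.approx(0.6)

    def test_three_individual_average_linkage_by_hand(self):
        # r(A,B)=0.95, r(A,C)=r(B,C)=0.1: merge {A,B} at d=0.05, then C at 0.9
        r = [[1.0, 0.95, 0.1], [0.95, 1.0, 0.1], [0.1, 0.1, 1.0]]
        dend = build_dendrogram(sim_from(r), linkage="average")
        assert [m[2] for m in dend.merges] == pytest.approx([0.05, 0.9])
        groups = cut_groups(dend, threshold=0.3)
        parts = sorted(sorted(v) for v in groups.groups().values())
        assert parts == [["A", "B"], ["C"]]

    def test_input_order_invariance(self, rng):
        n = 6
        base = rng.random((n, n))
        r = (base + base.T) / 2
        np.fill_diagonal(r, 1.0)
        ids = [f"s{i}" for i in range(n)]
        dend1 = build_dendrogram(sim_from(r, ids))
        perm = rng.permutation(n)
        dend2 = build_dendrogram(
            sim_from(r[np.ix_(perm, perm)], [ids[i] for i in perm]))
        assert [m[2] for m in dend1.merges] == [m[2] for m in dend2.merges]
        g1 = cut_groups(dend1, 0.5).groups()
        g2 = cut_groups(dend2, 0.5).groups()
        assert (sorted(sorted(v) for v in g1.values())
                == sorted(sorted(v) for v in g2.values()))

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(min_value=3, max_value=8), st.integers(0, 10_000))
    def test_average_linkage_matches_bruteforce_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        base = rng.uniform(-1, 1, (n, n))
        r = (base + base.T) / 2
        np.fill_diagonal(r, 1.0)
        ids = [chr(ord("A") + i) for i in range(n)]
        dend = build_dendrogram(sim_from(r, ids), linkage="average")
        got = [m[2] for m in dend.merges]
        expected = oracle_average_linkage(r, ids)
        assert got == pytest.approx(expected, abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(min_value=3, max_value=8), st.integers(0, 10_000),
           st.sampled_from(["average", "complete", "single"]))
    def test_merge_heights_match_scipy(self, n, seed, method):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0, 1, (n, n))
        r = (base + base.T) / 2
        np.fill_diagonal(r, 1.0)
        dend = build_dendrogram(sim_from(r), linkage=method)
        Z = scipy_linkage(squareform(1.0 - r, checks=False), method=method)
        assert sorted(m[2] for m in dend.merges) == pytest.approx(
            sorted(Z[:, 2]), abs=1e-10)

    def test_newick_export_parses(self):
        import dendropy

        r = [[1.0, 0.95, 0.1], [0.95, 1.0, 0.1], [0.1, 0.1, 1.0]]
        nwk = build_dendrogram(sim_from(r)).to_newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {t.label for t in tree.taxon_namespace} == {"A", "B", "C"}


class TestCut:
    def r3(self):
        return sim_from([[1.0, 0.95, 0.1], [0.95, 1.0, 0.1], [0.1, 0.1, 1.0]])

    def test_cut_above_root_one_group(self):
        groups = cut_groups(build_dendrogram(self.r3()), threshold=-1.0)
        assert len(groups.labels) == 1

    def test_cut_below_first_merge_all_singletons(self):
        groups = cut_groups(build_dendrogram(self.r3()), threshold=0.99)
        assert len(groups.labels) == 3

    def test_threshold_monotonicity(self, rng):
        n = 10
        base = rng.random((n, n))
        r = (base + base.T) / 2
        np.fill_diagonal(r, 1.0)
        dend = build_dendrogram(sim_from(r, [f"s{i}" for i in range(n)]))
        counts = [len(cut_groups(dend, t).labels)
                  for t in np.linspace(-1, 1, 41)]
        assert counts == sorted(counts)

    def test_labels_in_first_appearance_order(self):
        groups = cut_groups(build_dendrogram(self.r3()), threshold=0.3)
        assert groups.assignment["A"] == "CG1"
        assert groups.assignment["C"] == "CG2"


# ---------------------------------------------------------------------------
# PCA + separation
# ---------------------------------------------------------------------------

class TestPCA:
    def test_identical_spectra_degenerate(self):
        s = [spec([1, 2, 3], f"i{k}") for k in range(4)]
        res = pca(s, n_components=2)
        np.testing.assert_allclose(res.scores, 0.0, atol=1e-9)
        np.testing.assert_allclose(res.explained_variance, 0.0, atol=1e-9)

    def test_pc1_matches_eigendecomposition(self, rng):
        n = 20
        vals = np.zeros((n, 300))
        cov = np.array([[4.0, 1.5], [1.5, 1.0]])
        vals[:, :2] = rng.multivariate_normal([10, 10], cov, size=n)
        s = [TCMSpectrum(individual_id=f"i{k}", values=np.abs(vals[k]))
             for k in range(n)]
        res = pca(s, n_components=2)
        X = np.vstack([x.values for x in s])
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (n - 1))
        dominant = evecs[:, -1]
        cosine = abs(float(res.loadings[0] @ dominant))
        assert cosine == pytest.approx(1.0, abs=1e-8)
        assert res.explained_variance[0] == pytest.approx(evals[-1], rel=1e-8)

    def test_variance_conservation_and_ordering(self, rng):
        n = 12
        s = [TCMSpectrum(individual_id=f"i{k}", values=rng.random(300))
             for k in range(n)]
        res = pca(s, n_components=n - 1)
        assert float(res.explained_variance.sum()) == pytest.approx(
            res.total_variance, rel=1e-9)
        assert np.all(np.diff(res.explained_variance) <= 1e-9)

    def test_full_rank_reconstruction(self, rng):
        n = 8
        s = [TCMSpectrum(individual_id=f"i{k}", values=rng.random(300))
             for k in range(n)]
        res = pca(s, n_components=n)
        X = np.vstack([x.values for x in s])
        Xc = X - X.mean(axis=0)
        recon = res.scores @ res.loadings
        assert float(np.abs(recon - Xc).max()) <= 1e-8 * max(1.0, np.abs(Xc).max())

    def test_excess_components_truncated_with_warning(self, rng):
        s = [TCMSpectrum(individual_id=f"i{k}", values=rng.random(300))
             for k in range(3)]
        with pytest.warns(RuntimeWarning, match="truncating"):
            res = pca(s, n_components=50)
        assert res.scores.shape[1] == 3


class TestGroupSeparation:
    def make_result(self, scores, ids=None):
        scores = np.asarray(scores, float)
        ids = ids or [f"i{k}" for k in range(scores.shape[0])]
        return PCAResult(ids=ids, scores=scores,
                         loadings=np.zeros((scores.shape[1], 300)),
                         explained_variance=np.ones(scores.shape[1]),
                         total_variance=1.0)

    def test_coincident_singletons_overlap(self):
        res = self.make_result([[1.0, 2.0], [1.0, 2.0]])
        rep = group_separation(res, {"i0": "g1", "i1": "g2"})[0]
        assert rep.ratio == 0.0 and rep.call == "overlapping"

    def test_tight_clusters_ten_apart(self, rng):
        a = rng.normal(0, 1, (30, 2))
        b = rng.normal(0, 1, (30, 2)) + [10.0, 0.0]
        res = self.make_result(np.vstack([a, b]))
        labels = {f"i{k}": ("A" if k < 30 else "B") for k in range(60)}
        rep = group_separation(res, labels)[0]
        # direct geometry: centroid distance ~10, mean within-distance ~1.25
        dist = float(np.linalg.norm(a.mean(0) - b.mean(0)))
        within = np.concatenate([
            np.linalg.norm(a - a.mean(0), axis=1),
            np.linalg.norm(b - b.mean(0), axis=1),
        ])
        assert rep.ratio == pytest.approx(dist / within.mean(), rel=1e-9)
        assert rep.call == "separated"

    def test_empty_group_rejected(self):
        res = self.make_result([[0.0, 0.0]])
        with pytest.raises(ChemometricsError, match="missing from PCA"):
            group_separation(res, {"ghost": "g1"})
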