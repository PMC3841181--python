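"""Chemo-group delimitation from TCM fingerprints.

Individuals are compared by the correlation coefficient of their TCM
vectors (shape similarity, invariant to overall extract concentration),
clustered agglomeratively on distance d = 1 - r, and partitioned into
chemo-groups by cutting the dendrogram at a similarity threshold
(default 0.3, i.e. cut height 0.7). Principal component analysis of the
centered fingerprint matrix provides the second, geometry-based view
used to adjudicate apparent exceptions: groups merged by correlation
but well separated in PC space, or split by correlation but overlapping.

The agglomeration is implemented here rather than delegated so that
ties in merge height are broken deterministically (by the
lexicographically smallest pair of cluster representative ids), which
makes every downstream output invariant to input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA as _SKPCA

from .tcm import TCMSpectrum, tcm_table


class ChemometricsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        self.r = r
        n = len(self.ids)
        if r.shape != (n, n):
            raise ChemometricsError(f"similarity matrix shape {r.shape} != ({n},{n})")
        if not np.all(np.isfinite(r)):
            raise ChemometricsError("similarity matrix has non-finite entries")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ChemometricsError("similarity matrix is not symmetric")
        # exact symmetry and unit diagonal, so downstream never sees drift
        self.r = (r + r.T) / 2.0
        np.fill_diagonal(self.r, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.ids, columns=self.ids)


def correlation_matrix(specs: list[TCMSpectrum], kind: str = "pearson") -> SimilarityMatrix:
    """Pairwise correlation of TCM fingerprints.

    ``kind="pearson"`` (default) is the product-moment correlation of
    the raw bin vectors; ``"spearman"`` ranks bins first. A fingerprint
    with zero variance across bins has no defined correlation and is
    rejected by name.
    """
    if len(specs) < 2:
        raise ChemometricsError("need at least 2 spectra")
    table = tcm_table(specs)
    X = table.to_numpy(float)
    sd = X.std(axis=1)
    flat = np.where(sd == 0)[0]
    if flat.size:
        raise ChemometricsError(
            "zero-variance fingerprint(s), correlation undefined: "
            + ", ".join(table.index[i] for i in flat)
        )
    if kind == "spearman":
        X = np.apply_along_axis(rankdata, 1, X)
    elif kind != "pearson":
        raise ChemometricsError(f"unknown correlation kind {kind!r}")
    r = np.corrcoef(X)
    return SimilarityMatrix(ids=list(table.index), r=r)


# ---------------------------------------------------------------------------
# agglomerative dendrogram on d = 1 - r
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Merge tree over individuals; heights are distances d = 1 - r.

    ``merges`` is a scipy-style list: row k merges clusters ``a`` and
    ``b`` (indices < n are leaves in ``ids`` order, >= n refer to prior
    merges) at the given height into new cluster ``n + k``.
    """

    ids: list[str]
    merges: list[tuple[int, int, float, int]]  # (a, b, height, size)
    linkage: str

    def __post_init__(self) -> None:
        heights = [m[2] for m in self.merges]
        if any(h2 + 1e-12 < h1 for h1, h2 in zip(heights, heights[1:])):
            raise ChemometricsError("merge heights are not monotone")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_newick(self) -> str:
        """Ultrametric Newick string; leaf-to-node depth = height / 2."""
        n = self.n
        depth = {i: 0.0 for i in range(n)}
        node = {i: self.ids[i] for i in range(n)}
        for k, (a, b, h, _size) in enumerate(self.merges):
            d = h / 2.0
            left = f"{node[a]}:{d - depth[a]:.10g}"
            right = f"{node[b]}:{d - depth[b]:.10g}"
            node[n + k] = f"({left},{right})"
            depth[n + k] = d
        root = n + len(self.merges) - 1 if self.merges else 0
        return node[root] + ";"


def _linkage_update(linkage: str, d_ak: float, d_bk: float,
                    n_a: int, n_b: int) -> float:
    if linkage == "average":
        return (n_a * d_ak + n_b * d_bk) / (n_a + n_b)
    if linkage == "complete":
        return max(d_ak, d_bk)
    if linkage == "single":
        return min(d_ak, d_bk)
    raise ChemometricsError(f"unknown linkage {linkage!r}")


def build_dendrogram(sim: SimilarityMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerate individuals on d = 1 - r under the chosen linkage.

    Equal-height ties are broken by the lexicographically smallest pair
    of cluster representatives (a cluster's representative is its
    smallest member id), so the result does not depend on input order.
    Internally individuals are processed in sorted-id order, which makes
    the invariance exact down to floating-point summation order.
    """
    if linkage not in ("average", "complete", "single"):
        raise ChemometricsError(f"unknown linkage {linkage!r}")
    order = sorted(range(len(sim.ids)), key=lambda i: sim.ids[i])
    ids_sorted = [sim.ids[i] for i in order]
    D = 1.0 - sim.r[np.ix_(order, order)]
    n = len(ids_sorted)
    if n < 2:
        raise ChemometricsError("need at least 2 individuals")

    # active clusters: index -> (representative id, size)
    rep = {i: ids_sorted[i] for i in range(n)}
    size = {i: 1 for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active = set(range(n))
    merges_sorted: list[tuple[int, int, float, int]] = []
    next_idx = n
    while len(active) > 1:
        best = None
        for i, j in combinations(sorted(active), 2):
            d = dist[(i, j) if i < j else (j, i)]
            key = (d, *sorted((rep[i], rep[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, a, b = best
        h = dist[(a, b) if a < b else (b, a)]
        new = next_idx
        next_idx += 1
        merges_sorted.append((a, b, h, size[a] + size[b]))
        for k in active:
            if k in (a, b):
                continue
            d_ak = dist[(a, k) if a < k else (k, a)]
            d_bk = dist[(b, k) if b < k else (k, b)]
            dist[(k, new)] = _linkage_update(linkage, d_ak, d_bk, size[a], size[b])
        rep[new] = min(rep[a], rep[b])
        size[new] = size[a] + size[b]
        active.discard(a)
        active.discard(b)
        active.add(new)

    # remap leaf indices back to the caller's id order
    back = {i_sorted: sim.ids.index(ids_sorted[i_sorted]) for i_sorted in range(n)}
    remap = {i: back[i] for i in range(n)}
    merges = []
    for k, (a, b, h, sz) in enumerate(merges_sorted):
        merges.append((remap[a], remap[b], h, sz))
        remap[n + k] = n + k
    return Dendrogram(ids=list(sim.ids), merges=merges, linkage=linkage)


@dataclass
class ChemoGroups:
    threshold: float
    assignment: dict[str, str]
    labels: list[str] = field(default_factory=list)  # palette order

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {lab: [] for lab in self.labels}
        for ind, lab in self.assignment.items():
            out[lab].append(ind)
        return out


def cut_groups(dend: Dendrogram, threshold: float = 0.3) -> ChemoGroups:
    """Cut the dendrogram at similarity ``threshold`` (distance 1 - threshold).

    Chemo-groups are the maximal subtrees whose internal merge heights
    all stay at or below the cut height. Group labels ``CG1, CG2, ...``
    are assigned in order of each group's first member in the id list.
    """
    if not (-1.0 <= threshold <= 1.0):
        raise ChemometricsError(f"threshold {threshold} outside [-1, 1]")
    cut = 1.0 - threshold
    n = dend.n
    parent = list(range(n + len(dend.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (a, b, h, _sz) in enumerate(dend.merges):
        if h <= cut + 1e-12:
            for child in (a, b):
                parent[find(child)] = find(n + k)
        else:
            break  # heights are monotone
    roots: dict[int, str] = {}
    assignment: dict[str, str] = {}
    labels: list[str] = []
    for i, ind in enumerate(dend.ids):
        r = find(i)
        if r not in roots:
            lab = f"CG{len(roots) + 1}"
            roots[r] = lab
            labels.append(lab)
        assignment[ind] = roots[r]
    return ChemoGroups(threshold=threshold, assignment=assignment, labels=labels)


# ---------------------------------------------------------------------------
# PCA and group separation
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    ids: list[str]
    scores: np.ndarray            # (n, k)
    loadings: np.ndarray          # (k, bins)
    explained_variance: np.ndarray
    total_variance: float

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.ids, columns=cols)


def pca(specs: list[TCMSpectrum], n_components: int = 2) -> PCAResult:
    """Centering-only PCA of the fingerprint matrix (no variance scaling).

    Requests beyond the achievable rank are truncated with a warning.
    Explained variances are the (n-1)-denominator component variances
    and sum to the total variance of the centered matrix when all
    components are retained.
    """
    if len(specs) < 2:
        raise ChemometricsError("need at least 2 spectra for PCA")
    table = tcm_table(specs)
    X = table.to_numpy(float)
    max_k = min(X.shape)
    if n_components > max_k:
        warnings.warn(
            f"n_components={n_components} exceeds max rank {max_k}; truncating",
            RuntimeWarning, stacklevel=2,
        )
        n_components = max_k
    model = _SKPCA(n_components=n_components, svd_solver="full")
    with np.errstate(invalid="ignore"):  # zero-variance input is legal here
        scores = model.fit_transform(X)
    Xc = X - X.mean(axis=0)
    total_var = float(np.sum(Xc ** 2) / (X.shape[0] - 1))
    return PCAResult(
        ids=list(table.index),
        scores=scores,
        loadings=model.components_,
        explained_variance=model.explained_variance_,
        total_variance=total_var,
    )


@dataclass
class SeparationReport:
    group_a: str
    group_b: str
    ratio: float
    call: str  # "separated" | "overlapping" | "indeterminate"


def group_separation(pca_result: PCAResult, labels: dict[str, str],
                     dims: int = 2, s_sep: float = 2.0,
                     s_overlap: float = 1.0) -> list[SeparationReport]:
    """Pairwise separation of labelled groups in the leading PC plane.

    For each pair of groups the separation ratio is the distance between
    group centroids in the first ``dims`` PCs divided by the pooled mean
    member-to-own-centroid distance. Ratios >= ``s_sep`` are called
    "separated", <= ``s_overlap`` "overlapping", in between
    "indeterminate". Coincident groups (zero centroid distance) are
    overlapping by definition.
    """
    if s_overlap > s_sep:
        raise ChemometricsError("s_overlap must be <= s_sep")
    dims = min(dims, pca_result.scores.shape[1])
    pos = {ind: pca_result.scores[i, :dims] for i, ind in enumerate(pca_result.ids)}
    missing = [ind for ind in labels if ind not in pos]
    if missing:
        raise ChemometricsError(f"individuals missing from PCA result: {missing}")
    members: dict[str, list[str]] = {}
    for ind, lab in labels.items():
        members.setdefault(lab, []).append(ind)
    for lab, mem in members.items():
        if not mem:
            raise ChemometricsError(f"group {lab!r} has no members")
    centroids = {lab: np.mean([pos[m] for m in mem], axis=0)
                 for lab, mem in members.items()}
    spread = {lab: [float(np.linalg.norm(pos[m] - centroids[lab])) for m in mem]
              for lab, mem in members.items()}
    reports = []
    for a, b in combinations(sorted(members), 2):
        dist = float(np.linalg.norm(centroids[a] - centroids[b]))
        within = spread[a] + spread[b]
        pooled = float(np.mean(within))
        if dist == 0.0:
            ratio = 0.0
        elif pooled == 0.0:
            ratio = np.inf
        else:
            ratio = dist / pooled
        if ratio >= s_sep:
            call = "separated"
        elif ratio <= s_overlap:
            call = "overlapping"
        else:
            call = "indeterminate"
        reports.append(SeparationReport(group_a=a, group_b=b, ratio=ratio, call=call))
    return reports


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_similarity_tsv(sim: SimilarityMatrix, path: str | Path) -> Path:
    path = Path(path)
    sim.to_frame().to_csv(path, sep="\t", float_format="%.12g",
                          index_label="individual_id")
    return path


def write_groups_tsv(groups: ChemoGroups, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("individual_id\tchemo_group\n")
        for ind in groups.assignment:
            fh.write(f"{ind}\t{groups.assignment[ind]}\n")
    return path


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
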