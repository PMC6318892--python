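"""Neighbor-joining tree construction and genotype PCA.

The neighbor-joining implementation follows the classical Saitou–Nei
agglomeration: repeatedly pick the pair minimizing the Q criterion, assign
branch lengths, and collapse the pair into a new node.  Ties in Q are broken
lexicographically on the (sorted) pair of subtree labels so runs are
deterministic across platforms.  On an additive distance matrix the
reconstructed tree reproduces the input path metric exactly.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import GenotypeMatrix
from .popgen import DistanceMatrix

_NEWICK_UNSAFE = re.compile(r"[\s(),:;'\[\]]")


@dataclass
class TreeNode:
    """Node of an unrooted tree; children carry branch lengths to this node."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label or ""]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def leaf_distances(self) -> pd.DataFrame:
        """Path-length metric between all leaf pairs."""
        # brute-force traversal from each leaf; fine at the sizes trees
        # are inspected at (tests, reports)
        labels = self.leaves()
        n = len(labels)
        mat = np.zeros((n, n))
        # build adjacency
        adj: dict[int, list[tuple[int, float]]] = {}
        ids: dict[int, TreeNode] = {}

        def index(node: TreeNode) -> int:
            nid = len(ids)
            ids[nid] = node
            adj.setdefault(nid, [])
            for child, length in node.children:
                cid = index(child)
                adj[nid].append((cid, length))
                adj[cid].append((nid, length))
            return nid

        index(self)
        leaf_ids = {ids[k].label: k for k in ids if ids[k].is_leaf}
        for i, la in enumerate(labels):
            # BFS/DFS accumulating path lengths
            start = leaf_ids[la]
            dist = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for j, lb in enumerate(labels):
                mat[i, j] = dist[leaf_ids[lb]]
        return pd.DataFrame(mat, index=labels, columns=labels)


def neighbor_joining(d: DistanceMatrix, allow_negative_branches: bool = False) -> TreeNode:
    """Build an unrooted neighbor-joining tree from a distance matrix.

    Negative branch lengths are clamped to zero with the deficit shifted to
    the sister branch unless ``allow_negative_branches`` is set.  Requires at
    least three taxa and finite distances.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if not np.isfinite(d.values).all():
        raise ValueError("distance matrix contains non-finite entries")

    dm = d.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=l) for l in d.labels]
    # sort key per active node: smallest leaf label in its subtree
    keys: list[str] = list(d.labels)

    def clamp(a: float, b: float) -> tuple[float, float]:
        if allow_negative_branches:
            return a, b
        if a < 0:
            b += a
            a = 0.0
        if b < 0:
            a += b
            b = 0.0
        return max(a, 0.0), max(b, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = dm.sum(axis=1)
        q = (m - 2) * dm - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # deterministic tie-break: lexicographically smallest sorted key pair
        ties = np.argwhere(np.isclose(q, qmin, rtol=0.0, atol=1e-12))
        best = min(
            (tuple(sorted((keys[i], keys[j]))), (i, j))
            for i, j in ties if i < j
        )[1]
        i, j = best
        dij = dm[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_key = min(keys[i], keys[j])
        # distances from the new node to the rest
        dnew = 0.5 * (dm[i] + dm[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        dm = np.pad(dm[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        dm[-1, :-1] = dm[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [new_key]

    # final three-way join onto one internal node
    (d01, d02, d12) = (dm[0, 1], dm[0, 2], dm[1, 2])
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    if not allow_negative_branches:
        l0, l1, l2 = (max(v, 0.0) for v in (l0, l1, l2))
    order = sorted(range(3), key=lambda k: keys[k])
    root = TreeNode(children=[(nodes[k], (l0, l1, l2)[k]) for k in order])
    return root


def _quote(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def newick_string(t: TreeNode) -> str:
    """Newick serialization with 6-decimal branch lengths."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return _quote(node.label or "")
        inner = ",".join(
            f"{render(child)}:{length:.6f}" for child, length in node.children
        )
        return f"({inner})" + (_quote(node.label) if node.label else "")

    return render(t) + ";"


def write_newick(t: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(t) + "\n")


@dataclass
class PcaResult:
    """Principal-component scores and explained-variance fractions."""

    coordinates: pd.DataFrame          # accession × component scores
    explained_fraction: np.ndarray     # nonincreasing, sums to ≤ 1


def genotype_pca(
    g: GenotypeMatrix,
    catalog: pd.DataFrame,
    n_components: int = 2,
) -> PcaResult:
    """PCA of favorable-allele dosage (1 / 0.5 / 0 coding, mean-imputed).

    Missing calls are imputed with the locus mean dosage before centering, so
    they contribute nothing to the covariance.  Components beyond the matrix
    rank are truncated with a warning.
    """
    fav = dict(zip(catalog["locus_id"], catalog["favorable_allele"]))
    X = g.dosage(fav).to_numpy(dtype=float)
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    k = min(n_components, rank, *Xc.shape)
    if k < n_components:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; returning {k}",
            stacklevel=2,
        )
    if k == 0:
        coords = pd.DataFrame(
            np.zeros((g.n_accessions, 0)), index=g.accession_ids
        )
        return PcaResult(coords, np.array([]))
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Xc)
    cols = [f"PC{i + 1}" for i in range(k)]
    coords = pd.DataFrame(scores, index=g.accession_ids, columns=cols)
    return PcaResult(coords, pca.explained_variance_ratio_.copy())


def write_pca_scores(r: PcaResult, path) -> None:
    """PC scores as TSV; explained fractions on leading comment lines."""
    with open(path, "w") as fh:
        for i, frac in enumerate(r.explained_fraction):
            fh.write(f"# PC{i + 1} explained_fraction {frac:.6f}\n")
        out = r.coordinates.copy()
        out.index.name = "accession_id"
        out.to_csv(fh, sep="\t", float_format="%.6f")
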