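"""Connectivity-style similarity scoring and hierarchical clustering.

Similarity between two perturbation profiles is the Spearman rank
correlation of their per-probe log2 fold changes, computed either genome-wide
or restricted to a signature ("signature-restricted" scoring). Clustering of
treatments and probes uses average linkage (UPGMA) on the correlation
distance 1 - r, with r the centred Pearson correlation — the CLUSTER/TREEVIEW
convention — and deterministic lexicographic tie-breaking so dendrograms are
reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SimilarityResult:
    """Spearman similarity between two contrasts on a stated probe universe."""

    name_a: str
    name_b: str
    universe: str
    n_probes: int
    rho: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "contrast_a": self.name_a,
            "contrast_b": self.name_b,
            "universe": self.universe,
            "n_probes": self.n_probes,
            "spearman_rho": self.rho,
            "p_value": self.p_value,
        }


def _as_series(fc: Mapping[str, float] | pd.Series) -> pd.Series:
    if isinstance(fc, pd.Series):
        return fc
    return pd.Series(dict(fc))


def spearman_similarity(
    fc_a: Mapping[str, float] | pd.Series,
    fc_b: Mapping[str, float] | pd.Series,
    universe: Iterable[str] | None = None,
    name_a: str = "a",
    name_b: str = "b",
    universe_name: str | None = None,
) -> SimilarityResult:
    """Spearman rank correlation between two log2 fold-change profiles.

    ``universe`` restricts the comparison to a probe subset (e.g. a
    signature); by default all probes shared by both profiles are used.
    Ties receive average ranks; the two-sided p-value uses the t
    approximation, adequate for the signature sizes (>= ~40 probes) this
    score is used with.
    """
    a = _as_series(fc_a)
    b = _as_series(fc_b)
    if universe is None:
        probes = a.index.intersection(b.index)
        uname = universe_name or "all"
    else:
        probes = pd.Index(list(universe))
        missing = probes.difference(a.index.intersection(b.index))
        if len(missing):
            raise ValidationError(f"universe probes missing from profiles: {missing[:10].tolist()}")
        uname = universe_name or "custom"
    if len(probes) < 3:
        raise ValidationError(f"need at least 3 shared probes, got {len(probes)}")
    rho, p = stats.spearmanr(a.loc[probes], b.loc[probes])
    return SimilarityResult(name_a, name_b, uname, len(probes), float(rho), float(p))


def similarity_matrix(
    contrasts: Mapping[str, Mapping[str, float] | pd.Series],
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise Spearman rho between named contrasts."""
    names = list(contrasts)
    if len(names) < 2:
        raise ValidationError("similarity_matrix requires at least two contrasts")
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            res = spearman_similarity(contrasts[na], contrasts[nb], universe, na, nb)
            mat.loc[na, nb] = mat.loc[nb, na] = res.rho
    return mat


# ---------------------------------------------------------------------------
# UPGMA clustering with correlation distance
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    label: str                       # lexicographically smallest leaf beneath
    height: float
    children: tuple["_Node", "_Node"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class ClusterTree:
    """Result of average-linkage agglomeration.

    ``merges`` lists (label_left, label_right, height, new_size) in merge
    order, where a cluster's label is its lexicographically smallest leaf.
    Heights are nondecreasing (UPGMA on a proper dissimilarity is reducible,
    hence ultrametric).
    """

    leaves: list[str]
    merges: list[tuple[str, str, float, int]]
    root: _Node
    linkage: str = "average"
    distance: str = "correlation"

    @property
    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def leaf_order(self) -> list[str]:
        """Depth-first leaf order (children visited label-first) for heatmaps."""
        order: list[str] = []

        def visit(node: _Node) -> None:
            if node.is_leaf:
                order.append(node.label)
                return
            for child in sorted(node.children, key=lambda c: c.label):
                visit(child)

        visit(self.root)
        return order

    def to_newick(self) -> str:
        """Ultrametric Newick string; branch lengths in correlation-distance units.

        A node at merge height h sits h/2 above its leaves, so the branch to
        a child at height h_c has length (h - h_c) / 2.
        """

        def render(node: _Node) -> str:
            if node.is_leaf:
                return node.label
            parts = []
            for child in sorted(node.children, key=lambda c: c.label):
                length = (node.height - child.height) / 2.0
                parts.append(f"{render(child)}:{length:.6g}")
            return "(" + ",".join(parts) + ")"

        return render(self.root) + ";"


def correlation_distance_matrix(profiles: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise 1 - centred-Pearson distances between profiles.

    A constant (zero-variance) profile has no defined correlation; such
    items are assigned distance 1 to every other item, with a warning.
    """
    names = sorted(profiles)
    arr = np.asarray([np.asarray(profiles[n], dtype=float) for n in names])
    if arr.ndim != 2:
        raise ValidationError("profiles must share a common length")
    sd = arr.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("constant profiles assigned distance 1 to all others: %s",
                       [n for n, c in zip(names, constant) if c])
    centered = arr - arr.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    dist = 1.0 - corr
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=names, columns=names)


def average_linkage_cluster(
    profiles: Mapping[str, Sequence[float]] | None = None,
    distance_matrix: pd.DataFrame | None = None,
) -> ClusterTree:
    """UPGMA tree on correlation distance with deterministic tie-breaking.

    Either raw ``profiles`` (distance computed as 1 - centred Pearson) or a
    precomputed symmetric ``distance_matrix`` may be given. At every step the
    closest pair of clusters is merged; between-cluster distance is the mean
    of all leaf-pair distances (maintained by the weighted UPGMA update).
    Ties are broken by the lexicographically smallest (label, label) pair,
    so identical inputs always produce the identical tree.
    """
    if (profiles is None) == (distance_matrix is None):
        raise ValidationError("provide exactly one of profiles or distance_matrix")
    if distance_matrix is None:
        distance_matrix = correlation_distance_matrix(profiles)
    names = list(distance_matrix.index)
    if len(names) < 2:
        raise ValidationError("clustering requires at least two items")
    if len(set(names)) != len(names):
        raise ValidationError("duplicate item ids")

    dist: dict[frozenset[str], float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            dist[frozenset((a, b))] = float(distance_matrix.loc[a, b])

    nodes: dict[str, _Node] = {n: _Node(n, 0.0) for n in sorted(names)}
    sizes: dict[str, int] = {n: 1 for n in names}
    merges: list[tuple[str, str, float, int]] = []

    while len(nodes) > 1:
        labels = sorted(nodes)
        best = min(
            ((dist[frozenset((a, b))], a, b)
             for i, a in enumerate(labels) for b in labels[i + 1:]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        d, a, b = best
        new_label = min(a, b)
        new_node = _Node(new_label, d, (nodes[a], nodes[b]))
        new_size = sizes[a] + sizes[b]
        for other in labels:
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((new_label, other))] = (sizes[a] * da + sizes[b] * db) / new_size
        dist.pop(frozenset((a, b)))
        for lab in (a, b):
            del nodes[lab], sizes[lab]
        nodes[new_label] = new_node
        sizes[new_label] = new_size
        merges.append((a, b, d, new_size))

    root = next(iter(nodes.values()))
    return ClusterTree(sorted(names), merges, root)


def median_center_rows(
    values: pd.DataFrame,
    probes: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Median-centre each probe row and order rows/columns by two-way UPGMA.

    Subtracting each row's median puts intensities on an above/below-median
    scale (the red/green convention of expression heatmaps). Row and column
    orders come from average-linkage trees on the correlation distance over
    the centred sub-matrix. Returns ``(centred matrix, row order, column
    order)``.
    """
    sub = values if probes is None else values.loc[list(probes)]
    if sub.empty:
        raise ValidationError("median_center_rows requires a nonempty probe subset")
    centered = sub.sub(sub.median(axis=1), axis=0)
    row_order = list(centered.index)
    col_order = list(centered.columns)
    if len(centered) >= 2:
        row_tree = average_linkage_cluster({str(p): centered.loc[p].to_numpy() for p in centered.index})
        row_order = row_tree.leaf_order()
    if centered.shape[1] >= 2:
        col_tree = average_linkage_cluster({str(s): centered[s].to_numpy() for s in centered.columns})
        col_order = col_tree.leaf_order()
    return centered, row_order, col_order


def write_similarity_json(results: Sequence[SimilarityResult], path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=2)
        fh.write("\n")
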