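"""Downstream analysis: gene-set enrichment and hierarchical clustering.

Enrichment is the exact hypergeometric upper tail P(X >= k) of the
overlap between a query gene list and each gene set, computed against a
declared background universe (e.g. the genes on the array platform),
with Benjamini–Hochberg control across all tested sets.  This is a
plain over-representation test: the modified one-tail scores and
annotation clustering of dedicated enrichment servers are deliberately
not replicated.

Clustering is agglomerative with Euclidean distance and centroid
linkage (UPGMC).  Centroids are recomputed exactly as size-weighted
means at every merge — no Lance–Williams update — so the merge sequence
can be checked verbatim against a naive re-computation.  Centroid
linkage can produce height inversions; they are flagged, not hidden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datastore import NA, Snapshot


@dataclass
class GeneSetCollection:
    """Gene sets restricted to a declared background universe.

    Membership outside the universe is discarded at construction;
    sets left empty are dropped with a warning.
    """

    universe: frozenset
    sets: dict[str, tuple[str, frozenset]] = field(default_factory=dict)

    @classmethod
    def build(
        cls, universe, raw_sets: dict[str, tuple[str, set]]
    ) -> "GeneSetCollection":
        uni = frozenset(universe)
        if not uni:
            raise ValueError("background universe must not be empty")
        kept: dict[str, tuple[str, frozenset]] = {}
        dropped = []
        for term_id in sorted(raw_sets):
            name, members = raw_sets[term_id]
            inter = frozenset(members) & uni
            if inter:
                kept[term_id] = (name, inter)
            else:
                dropped.append(term_id)
        if dropped:
            warnings.warn(
                f"{len(dropped)} gene set(s) empty after universe restriction", UserWarning
            )
        return cls(universe=uni, sets=kept)

    @classmethod
    def from_annotations(
        cls,
        s: Snapshot,
        species: str,
        source: str = "go",
        category: str | None = None,
        universe=None,
    ) -> "GeneSetCollection":
        """Build sets from the snapshot's annotation table.

        With ``universe=None``, the background is every distinct gene
        symbol of the species in the cross-reference table (i.e. the
        whole platform the snapshot knows about).
        """
        table_name = {"go": "annotations_go", "kegg": "annotations_kegg"}[source]
        ann = s.table(table_name)
        ann = ann[ann["species"] == species]
        if category is not None:
            ann = ann[ann["category"] == category]
        if universe is None:
            xt = s.table("xref")
            xt = xt[(xt["species"] == species) & (xt["namespace"] == "gene_symbol")]
            universe = set(xt["value"])
        raw: dict[str, tuple[str, set]] = {}
        for row in ann.itertuples(index=False):
            name, members = raw.setdefault(row.term_id, (row.term_name, set()))
            members.add(row.gene_symbol)
        return cls.build(universe, raw)

    @classmethod
    def from_gmt(cls, path: str | Path, universe) -> "GeneSetCollection":
        raw: dict[str, tuple[str, set]] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                raw[parts[0]] = (parts[1], set(parts[2:]))
        return cls.build(universe, raw)


ENRICH_COLUMNS = [
    "term_id",
    "term_name",
    "N",
    "K",
    "n",
    "k",
    "p_value",
    "q_value",
    "significant_raw",
    "significant_fdr",
]


def enrich(query, gsc: GeneSetCollection, alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in *query*.

    Query genes outside the universe are dropped (count logged in
    ``attrs["n_outside_universe"]``).  p is the exact upper tail
    P(X >= k) drawing n genes from a universe of N containing K set
    members; q is the BH adjustment across all tested sets.
    ``significant_raw`` flags p <= alpha (the conventional report);
    ``significant_fdr`` flags q <= alpha (recommended).
    """
    query_set = set(query)
    inside = query_set & gsc.universe
    n_outside = len(query_set) - len(inside)
    if n_outside:
        warnings.warn(
            f"{n_outside} query gene(s) outside the background universe were dropped",
            UserWarning,
        )
    result = pd.DataFrame(columns=ENRICH_COLUMNS)
    result.attrs["n_outside_universe"] = n_outside
    if not inside:
        warnings.warn("query is empty after universe restriction", UserWarning)
        return result

    N = len(gsc.universe)
    n = len(inside)
    rows = []
    for term_id in sorted(gsc.sets):
        name, members = gsc.sets[term_id]
        K = len(members)
        k = len(inside & members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, name, N, K, n, k, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:7])
    _, q, _, _ = multipletests(df["p_value"], method="fdr_bh")
    df["q_value"] = q
    df["significant_raw"] = df["p_value"] <= alpha
    df["significant_fdr"] = df["q_value"] <= alpha
    df = df.sort_values(["p_value", "term_id"]).reset_index(drop=True)
    df.attrs["n_outside_universe"] = n_outside
    return df


@dataclass(frozen=True)
class Merge:
    node_a: int
    node_b: int
    height: float
    new_node: int
    size: int


@dataclass
class Dendrogram:
    """Result of agglomerative clustering: n-1 merges over n leaves.

    Leaves are numbered 0..n-1 in input row order; internal nodes
    continue from n in merge order.  ``node_a < node_b`` in every merge.
    """

    merges: list[Merge]
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def has_inversions(self) -> bool:
        heights = [m.height for m in self.merges]
        return any(b < a - 1e-12 for a, b in zip(heights, heights[1:]))

    def leaf_order(self) -> list[str]:
        """Leaf labels by recursive left-first traversal from the root."""
        children = {m.new_node: (m.node_a, m.node_b) for m in self.merges}

        def walk(node: int):
            if node < self.n_leaves:
                yield node
            else:
                a, b = children[node]
                yield from walk(a)
                yield from walk(b)

        root = self.merges[-1].new_node
        return [self.labels[i] for i in walk(root)]

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "node_a": m.node_a,
                    "node_b": m.node_b,
                    "height": m.height,
                    "new_node": m.new_node,
                    "size": m.size,
                }
                for m in self.merges
            ],
            columns=["node_a", "node_b", "height", "new_node", "size"],
        )

    def to_newick(self) -> str:
        """Newick with branch lengths = height differences.

        Inversions make some internal branch lengths negative; they are
        emitted as-is rather than clamped.
        """
        children = {m.new_node: (m.node_a, m.node_b) for m in self.merges}
        height = {m.new_node: m.height for m in self.merges}

        def render(node: int, parent_height: float) -> str:
            if node < self.n_leaves:
                label = str(self.labels[node]).replace(" ", "_")
                for ch in "():,;":
                    label = label.replace(ch, "_")
                return f"{label}:{parent_height:.6g}"
            a, b = children[node]
            h = height[node]
            return f"({render(a, h)},{render(b, h)}):{parent_height - h:.6g}"

        root = self.merges[-1].new_node
        a, b = children[root]
        h = height[root]
        return f"({render(a, h)},{render(b, h)});"


def hcluster(
    matrix: pd.DataFrame | np.ndarray,
    labels: list[str] | None = None,
    distance: str = "euclidean",
    linkage: str = "centroid",
) -> Dendrogram:
    """Agglomerative clustering with exact centroid linkage.

    At each step the two clusters whose centroids are nearest in
    Euclidean distance are merged; the new centroid is the size-weighted
    mean of the members.  Ties break on the lexicographically smallest
    (node_a, node_b) pair, making the merge sequence deterministic.
    """
    if distance != "euclidean" or linkage != "centroid":
        raise ValueError("only euclidean distance with centroid linkage is supported")
    if isinstance(matrix, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in matrix.index]
        values = matrix.to_numpy()
    else:
        values = np.asarray(matrix)
        if labels is None:
            labels = [str(i) for i in range(len(values))]
    values = np.atleast_2d(values)
    if len(values) < 2:
        raise ValueError("clustering needs at least 2 rows")
    try:
        data = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in clustering input: {exc}") from exc
    bad = np.where(~np.isfinite(data))
    if bad[0].size:
        raise ValueError(f"missing/non-finite value at row {labels[bad[0][0]]}")

    n = len(data)
    active: dict[int, tuple[np.ndarray, int]] = {i: (data[i].copy(), 1) for i in range(n)}
    merges: list[Merge] = []
    next_id = n
    while len(active) > 1:
        best: tuple[float, int, int] | None = None
        ids = sorted(active)
        for i, a in enumerate(ids):
            ca, _ = active[a]
            for b in ids[i + 1 :]:
                cb, _ = active[b]
                d = float(np.linalg.norm(ca - cb))
                cand = (d, a, b)
                if best is None or cand < best:
                    best = cand
        d, a, b = best
        ca, sa = active.pop(a)
        cb, sb = active.pop(b)
        centroid = (sa * ca + sb * cb) / (sa + sb)
        active[next_id] = (centroid, sa + sb)
        merges.append(Merge(a, b, d, next_id, sa + sb))
        next_id += 1
    return Dendrogram(merges=merges, labels=list(labels))
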