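"""Gene co-occurrence statistics across final CIS loci.

From the binary gene x locus presence matrix the module computes the
conditional co-occurrence probability P(j|i) — the fraction of loci
containing gene i that also contain gene j — the per-gene presence
counts, and the bidirectional network whose edges connect pairs with
both directed probabilities strictly above a threshold (0.8 by default).
Count matrices are column-clustered with Ward's minimum variance method
in its classical "Ward.D" form (Lance–Williams update applied to raw
Euclidean distances) for heatmap-style ordering.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .cgf_profile import CGFProfile, UNKNOWN_ROLE, role_sort_key
from .classification import STATUS_CIS, LocusResult
from .io_ingest import HomologyHit

__all__ = [
    "CooccurrenceResult",
    "ColumnClustering",
    "build_presence_matrix",
    "gene_count_scores",
    "conditional_probability",
    "bidirectional_network",
    "ward_column_order",
    "network_to_graphml",
    "write_probability_tsv",
    "write_edge_list_tsv",
]


@dataclass(frozen=True)
class CooccurrenceResult:
    """Conditional probabilities P(j|i) (rows = i), presence counts, and
    the symmetric co-occurrence counts they derive from.  Rows for genes
    present in zero loci are NaN (undefined), never zero-filled."""

    probabilities: pd.DataFrame
    presence_counts: pd.Series
    cooccurrence_counts: pd.DataFrame


@dataclass(frozen=True)
class ColumnClustering:
    """Ward column clustering: deterministic leaf order, merge list
    (cluster indices as in scipy linkage rows), heights, and the merge
    tree in Newick."""

    order: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]
    newick: str
    method: str


def build_presence_matrix(
    loci: Sequence[LocusResult], level: str = "role"
) -> pd.DataFrame:
    """Binary gene x locus matrix over loci with final status CIS.

    ``level`` selects row labels: curated roles (``role``; unknown-role
    families are ignored) or individual families (``family``).
    """
    if level not in ("role", "family"):
        raise ValueError(f"unknown level {level!r}")
    cis = [l for l in loci if l.status == STATUS_CIS]
    if not cis:
        raise ValueError("no loci with status CIS")
    columns = [l.locus_id for l in cis]
    if len(set(columns)) != len(columns):
        raise ValueError("duplicate locus ids")
    labels: set[str] = set()
    per_locus: list[set[str]] = []
    for l in cis:
        genes = set(l.roles_present) if level == "role" else set(l.families_hit)
        genes.discard(UNKNOWN_ROLE)
        labels |= genes
        per_locus.append(genes)
    rows = sorted(labels, key=role_sort_key) if level == "role" else sorted(labels)
    data = np.zeros((len(rows), len(columns)), dtype=np.int8)
    row_idx = {g: i for i, g in enumerate(rows)}
    for j, genes in enumerate(per_locus):
        for g in genes:
            data[row_idx[g], j] = 1
    return pd.DataFrame(data, index=rows, columns=columns)


def gene_count_scores(
    hits_by_locus: Mapping[str, Sequence[HomologyHit]],
    profile: CGFProfile,
    level: str = "role",
) -> pd.DataFrame:
    """Non-mutually-exclusive hit-count matrix (gene x locus).

    Each cell is the number of accepted hits of that gene (role or
    family) in that locus; when tied best hits were retained upstream
    (``keep_ties``), one query gene may increment several rows.
    """
    if level not in ("role", "family"):
        raise ValueError(f"unknown level {level!r}")
    by_id = profile.by_id
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for locus, hits in hits_by_locus.items():
        counts[locus]  # materialize all-zero columns for hit-free loci
        for h in hits:
            family = by_id.get(h.family_id)
            if family is None:
                raise ValueError(f"unknown family {h.family_id!r}")
            label = family.role if level == "role" else family.family_id
            if label == UNKNOWN_ROLE:
                continue
            counts[locus][label] += 1
    columns = sorted(counts)
    labels = sorted(
        {g for per in counts.values() for g in per},
        key=role_sort_key if level == "role" else None,
    )
    data = np.array(
        [[counts[c].get(g, 0) for c in columns] for g in labels], dtype=int
    )
    if not labels:
        data = data.reshape(0, len(columns))
    return pd.DataFrame(data, index=labels, columns=columns)


def conditional_probability(presence: pd.DataFrame) -> CooccurrenceResult:
    """P(j|i) = |loci with i and j| / |loci with i|.

    Rows for genes with zero presence are NaN (undefined).  The
    co-occurrence count matrix is symmetric; asymmetry of P arises only
    through the row denominators.
    """
    values = presence.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    co = values @ values.T  # co[i, j] = #loci containing both
    counts = np.diag(co).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        probs = np.where(counts[:, None] > 0, co / counts[:, None], np.nan)
    genes = presence.index
    return CooccurrenceResult(
        probabilities=pd.DataFrame(probs, index=genes, columns=genes),
        presence_counts=pd.Series(counts.astype(int), index=genes, name="n_loci"),
        cooccurrence_counts=pd.DataFrame(co, index=genes, columns=genes),
    )


def bidirectional_network(
    result: CooccurrenceResult, tau: float = 0.8
) -> set[tuple[str, str]]:
    """Unordered pairs {i, j} with P(j|i) > tau and P(i|j) > tau
    (strict); undefined probabilities never form edges."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau {tau} outside [0, 1]")
    p = result.probabilities
    genes = list(p.index)
    edges: set[tuple[str, str]] = set()
    arr = p.to_numpy()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            pij, pji = arr[i, j], arr[j, i]
            if np.isnan(pij) or np.isnan(pji):
                continue
            if pij > tau and pji > tau:
                edges.add((genes[i], genes[j]))
    return edges


def network_to_graphml(
    result: CooccurrenceResult,
    edges: Iterable[tuple[str, str]],
    path: str | Path,
) -> nx.Graph:
    """Export the bidirectional network as GraphML (nodes carry presence
    counts; edges carry both directed probabilities)."""
    g = nx.Graph()
    for gene, count in result.presence_counts.items():
        g.add_node(gene, n_loci=int(count))
    p = result.probabilities
    for i, j in sorted(edges):
        g.add_edge(i, j, p_j_given_i=float(p.loc[i, j]), p_i_given_j=float(p.loc[j, i]))
    nx.write_graphml(g, str(path))
    return g


# ---------------------------------------------------------------------------
# Ward column clustering
# ---------------------------------------------------------------------------


def _lw_ward(d_ik: float, d_jk: float, d_ij: float, ni: int, nj: int, nk: int) -> float:
    # Lance-Williams update for Ward's minimum variance criterion.
    return ((ni + nk) * d_ik + (nj + nk) * d_jk - nk * d_ij) / (ni + nj + nk)


def ward_column_order(matrix: pd.DataFrame, method: str = "ward_d") -> ColumnClustering:
    """Agglomerative Ward clustering of matrix columns.

    ``ward_d`` applies the Lance–Williams Ward update directly to raw
    Euclidean distances (the classical hclust "Ward.D" behaviour);
    ``ward_d2`` applies it to squared distances and reports square-root
    heights.  Merges are deterministic: distance ties are broken by the
    smallest original column index.  Columns of identical profile merge
    first (zero distance).
    """
    if method not in ("ward_d", "ward_d2"):
        raise ValueError(f"unknown method {method!r}")
    cols = [str(c) for c in matrix.columns]
    n = len(cols)
    if n == 0:
        raise ValueError("ward_column_order needs >= 1 column")
    if n == 1:
        return ColumnClustering(
            order=(cols[0],), merges=(), newick=f"{_nw_label(cols[0])};", method=method
        )
    x = matrix.to_numpy(dtype=float).T
    dist = squareform(pdist(x, metric="euclidean"))
    if method == "ward_d2":
        dist = dist**2

    # active cluster id -> (size, min original column index)
    size = {i: 1 for i in range(n)}
    min_leaf = {i: i for i in range(n)}
    d: dict[tuple[int, int], float] = {
        (i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active = set(range(n))
    children: dict[int, tuple[int, int]] = {}
    heights: dict[int, float] = {}
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                dij = d[(i, j)]
                key = (dij, min(min_leaf[i], min_leaf[j]), max(min_leaf[i], min_leaf[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, a, b = best
        dab = d[(a, b)]
        height = float(np.sqrt(dab)) if method == "ward_d2" else dab
        new = next_id
        next_id += 1
        for k in sorted(active):
            if k in (a, b):
                continue
            dik = d[(min(a, k), max(a, k))]
            djk = d[(min(b, k), max(b, k))]
            d[(k, new)] = _lw_ward(dik, djk, dab, size[a], size[b], size[k])
        active -= {a, b}
        size[new] = size[a] + size[b]
        min_leaf[new] = min(min_leaf[a], min_leaf[b])
        children[new] = (a, b)
        heights[new] = height
        merges.append((a, b, height, size[new]))
        active.add(new)

    root = next_id - 1

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        # left = subtree containing the smaller original column index
        if min_leaf[a] > min_leaf[b]:
            a, b = b, a
        return leaves(a) + leaves(b)

    def newick(node: int, parent_height: float) -> str:
        h = 0.0 if node < n else heights[node]
        branch = max(parent_height - h, 0.0)
        if node < n:
            return f"{_nw_label(cols[node])}:{branch:g}"
        a, b = children[node]
        if min_leaf[a] > min_leaf[b]:
            a, b = b, a
        return f"({newick(a, h)},{newick(b, h)}):{branch:g}"

    order = tuple(cols[i] for i in leaves(root))
    return ColumnClustering(
        order=order,
        merges=tuple(merges),
        newick=newick(root, heights[root]) + ";",
        method=method,
    )


def _nw_label(label: str) -> str:
    if any(c in label for c in "(),:;' \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_probability_tsv(result: CooccurrenceResult, path: str | Path) -> None:
    """Probability matrix TSV; undefined entries are written as empty
    cells, not zeros."""
    result.probabilities.to_csv(path, sep="\t", na_rep="", index_label="gene")


def write_edge_list_tsv(
    result: CooccurrenceResult,
    edges: Iterable[tuple[str, str]],
    path: str | Path,
) -> None:
    p = result.probabilities
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_i\tgene_j\tp_j_given_i\tp_i_given_j\n")
        for i, j in sorted(edges):
            fh.write(f"{i}\t{j}\t{p.loc[i, j]!r}\t{p.loc[j, i]!r}\n")
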