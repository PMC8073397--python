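"""Mitotype phylogenetics: Cavalli-Sforza & Edwards chord distance on the
MSS presence/absence matrix, and a UPGMA dendrogram.

Each MSS is treated as a biallelic locus whose allele frequency in a genome
is 0 or 1 (absent/present).  The chord distance for one locus is
``(2/pi) * sqrt(2 * (1 - cos(theta)))`` with ``cos(theta) = 1`` when the two
genomes agree and 0 otherwise, and the genome-pair distance is the mean over
loci — i.e. ``(2*sqrt(2)/pi)`` times the Hamming fraction (~0.9003 at
complete disagreement).  Any chord-distance variant on binary profiles is a
monotone transform of Hamming fraction, so the UPGMA topology does not
depend on the convention.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TreeNode", "cse_distance", "upgma", "to_newick", "write_newick",
           "CSE_MAX"]

CSE_MAX = 2.0 * math.sqrt(2.0) / math.pi  # distance at complete disagreement


def cse_distance(presence: pd.DataFrame) -> pd.DataFrame:
    """Cavalli-Sforza & Edwards chord distance matrix between the genomes
    (columns) of a presence/absence matrix (rows = loci)."""
    if presence.shape[0] < 1:
        raise ValueError("need at least one MSS locus")
    if presence.shape[1] < 2:
        raise ValueError("need at least two genomes")
    X = presence.to_numpy(dtype=bool)
    labels = list(presence.columns)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            hamming = float(np.mean(X[:, i] != X[:, j]))
            d[i, j] = d[j, i] = CSE_MAX * hamming
    return pd.DataFrame(d, index=labels, columns=labels)


@dataclass
class TreeNode:
    """Rooted ultrametric tree node: leaves have height 0, internal node
    height = half the merge distance."""

    name: str | None = None
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [n for c in self.children for n in c.leaf_names()]


def upgma(dm: pd.DataFrame) -> TreeNode:
    """UPGMA with proportional (size-weighted) averaging.

    Merge heights are d/2; ties broken by the lexicographically lowest pair
    of cluster keys, where a cluster's key is its smallest leaf label.
    """
    labels = list(dm.index)
    if len(labels) < 2:
        raise ValueError("need at least two taxa")
    if not np.allclose(dm.to_numpy(), dm.to_numpy().T):
        raise ValueError("distance matrix must be symmetric")
    clusters: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    sizes = {lab: 1 for lab in labels}
    dist = {frozenset((a, b)): float(dm.loc[a, b])
            for i, a in enumerate(labels) for b in labels[i + 1:]}

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                d = dist[frozenset((a, b))]
                cand = (d, a, b)
                if best is None or cand < best:
                    best = cand
        d, a, b = best
        node = TreeNode(height=d / 2.0, children=[clusters[a], clusters[b]])
        na, nb = sizes[a], sizes[b]
        new_key = min(a, b)
        fresh = {}
        for other in keys:
            if other in (a, b):
                continue
            fresh[frozenset((new_key, other))] = (
                na * dist[frozenset((a, other))]
                + nb * dist[frozenset((b, other))]) / (na + nb)
        for other in keys:
            dist.pop(frozenset((a, other)), None)
            dist.pop(frozenset((b, other)), None)
        dist.update(fresh)
        del clusters[a], clusters[b], sizes[a], sizes[b]
        clusters[new_key] = node
        sizes[new_key] = na + nb
    return next(iter(clusters.values()))


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.\-|]+$")


def _fmt_label(name: str) -> str:
    if _SAFE_LABEL.match(name):
        return name
    return "'" + name.replace("'", "''") + "'"


def to_newick(tree: TreeNode, _parent_height: float | None = None) -> str:
    if tree.is_leaf:
        body = _fmt_label(tree.name)
    else:
        body = "(" + ",".join(to_newick(c, tree.height) for c in tree.children) + ")"
    if _parent_height is None:
        return body + ";"
    return f"{body}:{_parent_height - tree.height:g}"


def write_newick(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")
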