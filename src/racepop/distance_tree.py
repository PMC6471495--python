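"""Identity-by-state distance matrix, UPGMA clustering, Newick export.

Per-locus IBS similarity between unordered biallelic genotypes is the shared
allele fraction: identical genotypes score 1, genotypes sharing one of two
alleles score 0.5, opposite homozygotes score 0. Distance is one minus the
mean similarity over loci typed in both samples. UPGMA uses size-weighted
average linkage with lexicographic tie-breaking, yielding an ultrametric
rooted tree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_genotypes import MISSING, GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "UpgmaTree",
    "ibs_distance",
    "upgma",
    "write_newick",
    "newick_string",
    "write_distance_tsv",
    "read_distance_tsv",
]


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < 0).any():
            raise ValueError("distances must be nonnegative")

    def get(self, a: str, b: str) -> float:
        i = self.sample_ids.index(a)
        j = self.sample_ids.index(b)
        return float(self.d[i, j])


def ibs_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """1 - mean IBS similarity over loci co-typed in each sample pair."""
    if gm.n_samples < 2:
        raise ValueError("need >= 2 samples for a distance matrix")
    D = gm.dosage.astype(float)
    typed = gm.dosage != MISSING
    n = gm.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        both = typed[i] & typed  # (n, L)
        n_co = both.sum(axis=1)
        zero = np.flatnonzero(n_co == 0)
        for j in zero:
            if j != i:
                raise ValueError(
                    f"samples {gm.sample_ids[i]!r} and {gm.sample_ids[j]!r} "
                    "share no co-typed loci"
                )
        diff = np.abs(D[i] - D) / 2.0  # per-locus dissimilarity in {0, .5, 1}
        diff[~both] = 0.0
        with np.errstate(invalid="ignore"):
            out[i] = diff.sum(axis=1) / n_co
    np.fill_diagonal(out, 0.0)
    out = (out + out.T) / 2.0  # symmetrize away float noise
    return DistanceMatrix(list(gm.sample_ids), out)


@dataclass
class TreeNode:
    """Rooted tree node; leaves carry a name, internal nodes a merge height."""

    height: float
    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out


@dataclass
class UpgmaTree:
    root: TreeNode
    sample_ids: list[str]

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths (all equal for an ultrametric tree)."""
        depths: dict[str, float] = {}

        def walk(node: TreeNode, acc: float) -> None:
            if node.is_leaf:
                depths[node.name] = acc  # type: ignore[index]
                return
            for c in node.children:
                walk(c, acc + (node.height - c.height))

        walk(self.root, 0.0)
        return depths

    def merge_heights(self) -> list[float]:
        heights: list[float] = []

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                heights.append(node.height)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return sorted(heights)

    def bipartitions(self) -> list[frozenset[str]]:
        """Leaf sets of every internal edge (clades below each internal node)."""
        out: list[frozenset[str]] = []

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                out.append(frozenset(node.leaf_names()))
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out


def upgma(dm: DistanceMatrix) -> UpgmaTree:
    """Classical UPGMA (size-weighted average linkage).

    Merge height is half the merging distance. Among equally close pairs the
    lexicographically smallest pair of cluster keys is merged, where a
    cluster's key is its smallest member leaf name.
    """
    if np.isnan(dm.d).any():
        raise ValueError("distance matrix contains NaN")
    n = len(dm.sample_ids)
    if n < 2:
        raise ValueError("need >= 2 samples")

    nodes: dict[str, TreeNode] = {
        s: TreeNode(height=0.0, name=s) for s in dm.sample_ids
    }
    sizes: dict[str, int] = {s: 1 for s in dm.sample_ids}
    dist: dict[frozenset[str], float] = {}
    keys = list(dm.sample_ids)
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((keys[i], keys[j]))] = float(dm.d[i, j])

    active = sorted(keys)
    while len(active) > 1:
        best: tuple[str, str] | None = None
        best_d = np.inf
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                d = dist[frozenset((a, b))]
                if d < best_d - 1e-15 or (
                    abs(d - best_d) <= 1e-15 and (best is None or (a, b) < best)
                ):
                    best_d = d
                    best = (a, b)
        a, b = best  # type: ignore[misc]
        merged = TreeNode(height=best_d / 2.0, children=[nodes[a], nodes[b]])
        key = min(a, b)
        other_key = max(a, b)
        na, nb = sizes[a], sizes[b]
        for c in active:
            if c in (a, b):
                continue
            dc = (na * dist[frozenset((a, c))] + nb * dist[frozenset((b, c))]) / (na + nb)
            dist[frozenset((key, c))] = dc
        nodes[key] = merged
        sizes[key] = na + nb
        del nodes[other_key]
        del sizes[other_key]
        active = sorted(k for k in active if k != other_key)
    return UpgmaTree(root=nodes[active[0]], sample_ids=list(dm.sample_ids))


_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}:;,'\"]")


def _label(name: str) -> str:
    if _NEEDS_QUOTE.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def newick_string(tree: UpgmaTree) -> str:
    def render(node: TreeNode, parent_height: float | None) -> str:
        if node.is_leaf:
            body = _label(node.name)  # type: ignore[arg-type]
        else:
            body = "(" + ",".join(render(c, node.height) for c in node.children) + ")"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - node.height:.10g}"

    return render(tree.root, None) + ";"


def write_newick(tree: UpgmaTree, path: str | Path) -> None:
    Path(path).write_text(newick_string(tree) + "\n")


def write_distance_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(dm.sample_ids) + "\n")
        for i, s in enumerate(dm.sample_ids):
            fh.write(s + "\t" + "\t".join(f"{x:.10g}" for x in dm.d[i]) + "\n")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    lines = Path(path).read_text().strip().splitlines()
    header = lines[0].split("\t")[1:]
    rows = []
    ids = []
    for line in lines[1:]:
        parts = line.split("\t")
        ids.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    if ids != header:
        raise ValueError("distance TSV row and column sample ids differ")
    return DistanceMatrix(ids, np.array(rows))
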