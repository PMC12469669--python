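"""Per-locus genetic distances and UPGMA dendrograms with Newick output.

Two distances are provided: Nei's standard genetic distance on population
allele-frequency spectra (breed-level trees), and the Dice band-sharing
distance on individuals' band sets (individual-level trees). Clustering is
classic UPGMA (cluster-size-weighted average linkage) with deterministic
lexicographic tie-breaking, yielding an ultrametric dendrogram serialized
to Newick with branch lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .genotype_io import AlleleFrequencySpectrum, GenotypeDataset, allele_frequencies

DEFAULT_DISTANCE_CAP = 10.0


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distance matrix over ordered labels."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.d, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "d", m)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])


@dataclass
class DendrogramNode:
    """Node of a rooted ultrametric dendrogram; leaves have height 0."""

    height: float
    label: str | None = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaf_labels(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [l for c in self.children for l in c.leaf_labels()]


def nei_standard_distance(
    a: AlleleFrequencySpectrum,
    b: AlleleFrequencySpectrum,
    cap: float = DEFAULT_DISTANCE_CAP,
) -> float:
    """Nei's standard genetic distance D = -ln(Jxy / sqrt(Jx * Jy)).

    Jxy = sum(p_i q_i) over shared alleles, Jx = sum(p_i^2), Jy = sum(q_i^2).
    Capped at ``cap`` when the populations share no alleles (Jxy = 0).
    """
    if a.locus != b.locus:
        raise ValueError(f"spectra are for different loci: {a.locus} vs {b.locus}")
    jx = sum(f * f for f in a.freqs.values())
    jy = sum(f * f for f in b.freqs.values())
    jxy = sum(a.freqs[al] * b.freqs[al] for al in set(a.freqs) & set(b.freqs))
    if jxy <= 0:
        return cap
    identity = jxy / math.sqrt(jx * jy)
    return min(cap, max(0.0, -math.log(min(identity, 1.0))))


def band_sharing_distance(bands_a: set[int], bands_b: set[int]) -> float:
    """1 - Dice similarity = 1 - 2|A & B| / (|A| + |B|)."""
    if not bands_a or not bands_b:
        raise ValueError("band sets must be non-empty")
    return 1.0 - 2.0 * len(bands_a & bands_b) / (len(bands_a) + len(bands_b))


def breed_distance_matrix(
    ds: GenotypeDataset, locus: str, cap: float = DEFAULT_DISTANCE_CAP
) -> DistanceMatrix:
    """Nei standard distances between all breeds at one locus."""
    specs = {pop: allele_frequencies(ds, pop, locus) for pop in ds.populations()}
    labels = tuple(specs)
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = nei_standard_distance(
                specs[labels[i]], specs[labels[j]], cap=cap
            )
    return DistanceMatrix(labels=labels, d=m)


def individual_distance_matrix(ds: GenotypeDataset, locus: str) -> DistanceMatrix:
    """Dice band-sharing distances between typed individuals at one locus."""
    bands = {
        ind.id: set(ds.calls[(ind.id, locus)].alleles())
        for ind in ds.individuals
        if not ds.calls[(ind.id, locus)].is_missing
    }
    labels = tuple(bands)
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = band_sharing_distance(bands[labels[i]], bands[labels[j]])
    return DistanceMatrix(labels=labels, d=m)


def upgma(matrix: DistanceMatrix) -> DendrogramNode:
    """UPGMA agglomeration: cluster-size-weighted average linkage.

    Ties in the minimum pairwise distance are broken by the lexicographically
    smallest (label_i, label_j) pair, where a cluster is identified by its
    smallest leaf label, so the result is deterministic.
    """
    if len(matrix.labels) < 2:
        raise ValueError("UPGMA needs at least 2 labels")
    clusters: dict[str, DendrogramNode] = {
        lab: DendrogramNode(height=0.0, label=lab) for lab in matrix.labels
    }
    sizes = {lab: 1 for lab in matrix.labels}
    dist: dict[frozenset[str], float] = {}
    for i, a in enumerate(matrix.labels):
        for j in range(i + 1, len(matrix.labels)):
            b = matrix.labels[j]
            dist[frozenset((a, b))] = float(matrix.d[i, j])

    while len(clusters) > 1:
        keys = sorted(clusters)
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                d = dist[frozenset((a, b))]
                cand = (d, a, b)
                if best is None or cand < best:
                    best = cand
        d, a, b = best
        merged = DendrogramNode(height=d / 2.0, children=(clusters[a], clusters[b]))
        new_key = min(a, b)
        na, nb = sizes[a], sizes[b]
        for other in keys:
            if other in (a, b):
                continue
            dn = (
                na * dist[frozenset((a, other))] + nb * dist[frozenset((b, other))]
            ) / (na + nb)
            dist[frozenset((new_key, other))] = dn
        del clusters[a], clusters[b], sizes[a], sizes[b]
        clusters[new_key] = merged
        sizes[new_key] = na + nb
    return next(iter(clusters.values()))


def write_newick(tree: DendrogramNode) -> str:
    """Serialize a dendrogram to Newick with branch lengths."""

    def render(node: DendrogramNode, parent_height: float) -> str:
        branch = parent_height - node.height
        if node.is_leaf:
            return f"{node.label}:{_fmt(branch)}"
        inner = ",".join(render(c, node.height) for c in node.children)
        return f"({inner}):{_fmt(branch)}"

    if tree.is_leaf:
        return f"{tree.label}:0.0;"
    inner = ",".join(render(c, tree.height) for c in tree.children)
    return f"({inner});"


def _fmt(x: float) -> str:
    s = f"{x:.10g}"
    return s if ("." in s or "e" in s) else s + ".0"


def read_newick(text: str) -> DendrogramNode:
    """Parse a Newick string (as written by :func:`write_newick`) back into a
    dendrogram, recovering node heights from the ultrametric branch lengths."""
    tree = dendropy.Tree.get(data=text, schema="newick")

    def convert(node) -> tuple[DendrogramNode, float]:
        if node.is_leaf():
            return DendrogramNode(height=0.0, label=node.taxon.label), 0.0
        converted = []
        for child in node.child_nodes():
            sub, sub_height = convert(child)
            converted.append((sub, sub_height + (child.edge.length or 0.0)))
        height = converted[0][1]
        if len(converted) != 2:
            raise ValueError("dendrogram must be binary")
        return DendrogramNode(
            height=height, children=(converted[0][0], converted[1][0])
        ), height

    root, _ = convert(tree.seed_node)
    return root


def cophenetic_distance(tree: DendrogramNode, a: str, b: str) -> float:
    """Tree distance between two leaves: 2 x the height of their LCA."""

    def find(node: DendrogramNode) -> DendrogramNode | None:
        leaves = set(node.leaf_labels())
        if a not in leaves or b not in leaves:
            return None
        if not node.is_leaf:
            for c in node.children:
                deeper = find(c)
                if deeper is not None:
                    return deeper
        return node

    lca = find(tree)
    if lca is None:
        raise KeyError(f"labels {a!r}, {b!r} not both in tree")
    return 2.0 * lca.height
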