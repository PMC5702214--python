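"""Clonal architecture as a minimal spanning tree over clone genotypes.

Each retained cluster is reduced to a consensus genotype (theta thresholded
at 0.5), an all-zero germline root is appended, and the MST of the complete
graph under genetic distance (Hamming by default, Jaccard optionally)
depicts the clonal architecture: edge length is the number of mutations
separating clones, and each node carries its cell count and the SNV/SV
composition of its consensus mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .em import MixtureModel

ROOT_LABEL = "germline"


@dataclass
class CloneNode:
    """A clone: consensus genotype plus size and mutation-class makeup."""

    label: str
    genotype: np.ndarray
    n_cells: int = 0
    n_snv: int = 0
    n_sv: int = 0

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype, dtype=np.int8)
        if not np.isin(self.genotype, (0, 1)).all():
            raise ValueError(f"clone {self.label!r}: genotype must be binary")
        if self.n_cells < 0:
            raise ValueError(f"clone {self.label!r}: n_cells must be >= 0")
        if self.n_snv + self.n_sv != int(self.genotype.sum()):
            raise ValueError(
                f"clone {self.label!r}: n_snv + n_sv must equal consensus 1s"
            )


@dataclass
class CloneTree:
    """MST over clone nodes; edges are (label_a, label_b, weight)."""

    nodes: list[CloneNode]
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(
                node.label,
                n_cells=int(node.n_cells),
                n_snv=int(node.n_snv),
                n_sv=int(node.n_sv),
                genotype="".join(map(str, node.genotype)),
            )
        for a, b, w in self.edges:
            g.add_edge(a, b, weight=float(w))
        return g


def consensus_genotypes(
    model: MixtureModel,
    assay_classes: Sequence[str] | Mapping[str, str] | None = None,
    assay_ids: Sequence[str] | None = None,
    clusters: Sequence[int] | None = None,
    labels: Sequence[str] | None = None,
    present_threshold: float = 0.5,
) -> list[CloneNode]:
    """Reduce a fitted mixture to clone nodes plus a germline root.

    genotype[j] = 1 iff theta[k, j] >= ``present_threshold`` (inclusive).
    ``clusters`` selects which components become clones (doublet and poor
    clusters should be excluded by the caller); ``assay_classes`` gives
    "snv"/"sv" per assay for the composition counts (unknown -> snv).
    The root has an all-zero genotype and zero cells (the unsequenced
    normal population).
    """
    ks = list(clusters) if clusters is not None else list(range(model.K))
    J = model.theta.shape[1]
    if isinstance(assay_classes, Mapping):
        ids = list(assay_ids) if assay_ids is not None else [str(j) for j in range(J)]
        classes = [assay_classes.get(a, "snv") for a in ids]
    elif assay_classes is not None:
        classes = list(assay_classes)
    else:
        classes = ["snv"] * J
    is_sv = np.array([c == "sv" for c in classes])
    hard = model.labels
    nodes = [CloneNode(ROOT_LABEL, np.zeros(J, dtype=np.int8))]
    for i, k in enumerate(ks):
        g = (model.theta[k] >= present_threshold).astype(np.int8)
        label = labels[i] if labels is not None else f"clone_{k}"
        nodes.append(
            CloneNode(
                label,
                g,
                n_cells=int((hard == k).sum()),
                n_snv=int(g[~is_sv].sum()),
                n_sv=int(g[is_sv].sum()),
            )
        )
    return nodes


def genetic_distance(a: np.ndarray, b: np.ndarray, metric: str = "hamming") -> float:
    """Distance between consensus genotypes.

    ``hamming`` is the count of discordant assays (an integer: the number
    of mutations separating the two genotypes); ``jaccard`` is
    1 - |intersection| / |union| of the present sets (0 for two all-zero
    genotypes).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if metric == "hamming":
        return float(np.sum(a != b))
    if metric == "jaccard":
        union = np.sum((a == 1) | (b == 1))
        if union == 0:
            return 0.0
        return 1.0 - float(np.sum((a == 1) & (b == 1))) / float(union)
    raise ValueError(f"unknown distance metric {metric!r}")


def build_mst(nodes: Sequence[CloneNode], metric: str = "hamming") -> CloneTree:
    """Minimal spanning tree of the complete clone graph.

    Kruskal's algorithm with edges ordered by (weight, label_a, label_b) so
    ties break lexicographically and the result is deterministic. Duplicate
    genotypes are legal (zero-weight edges).
    """
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes to build a tree")
    labels = [n.label for n in nodes]
    if len(set(labels)) != len(labels):
        raise ValueError("clone labels must be unique")
    candidates = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            a, b = sorted((nodes[i].label, nodes[j].label))
            w = genetic_distance(nodes[i].genotype, nodes[j].genotype, metric)
            candidates.append((w, a, b))
    candidates.sort()
    uf = nx.utils.UnionFind(labels)
    edges: list[tuple[str, str, float]] = []
    for w, a, b in candidates:
        if uf[a] != uf[b]:
            uf.union(a, b)
            edges.append((a, b, w))
        if len(edges) == len(nodes) - 1:
            break
    return CloneTree(list(nodes), edges)
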