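"""Distance matrices and neighbour-joining trees from Qscore similarities.

Qscore similarities are converted to distances as ``1 − Qscore`` (the
NO_SIMILARITY sentinel maps to the maximal distance 1.0), assembled into
a symmetric taxa-labelled matrix, and summarised as a neighbour-joining
tree.  The matrix is serialised in NEXUS format and the tree in Newick,
the standard inputs of downstream phylogenetic software.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


@dataclass
class DistanceMatrix:
    """Symmetric taxa-labelled distances in [0, 1] with zero diagonal."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match number of taxa")
        if len(set(self.taxa)) != n:
            raise ValueError("taxa must be unique")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        if self.values.min() < -1e-12 or self.values.max() > 1.0 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")


@dataclass
class TreeNode:
    """Node of an (unrooted, arbitrarily rooted for serialisation) tree."""

    name: str = ""
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def path_distances(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path-length sums (for additivity checks)."""
        dists: dict[tuple[str, str], float] = {}

        def below(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            acc: dict[str, float] = {}
            child_maps = []
            for c in node.children:
                m = {k: v + c.length for k, v in below(c).items()}
                child_maps.append(m)
            for i in range(len(child_maps)):
                for j in range(i + 1, len(child_maps)):
                    for na, da in child_maps[i].items():
                        for nb, db in child_maps[j].items():
                            key = (na, nb) if na < nb else (nb, na)
                            dists[key] = da + db
                acc.update(child_maps[i])
            return acc

        below(self)
        return dists


def build_distance_matrix(db, taxa: Sequence[str]) -> DistanceMatrix:
    """Assemble the 1−Qscore distance matrix over vetted centroids.

    ``db`` is a :class:`strucphy.pipeline.Database`; any pair missing
    from its score table is computed on demand.
    """
    from strucphy.pipeline import to_distance

    taxa = list(taxa)
    n = len(taxa)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            q = db.pair_qscore(taxa[i], taxa[j])
            values[i, j] = values[j, i] = to_distance(q)
    return DistanceMatrix(taxa, values)


def neighbor_joining(D: DistanceMatrix) -> TreeNode:
    """Classic neighbour-joining (Saitou–Nei) tree from a distance matrix.

    Iteratively joins the pair minimising the Q-criterion, with ties
    broken by the smallest (i, j) index pair; branch lengths follow the
    standard formulas with negatives clamped to zero.  The returned tree
    is unrooted, represented with a trifurcating root (a single edge
    split in half for 2 taxa).  NJ reconstructs additive matrices
    exactly.
    """
    n = len(D.taxa)
    if n < 2:
        raise ValueError("neighbour joining needs at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in D.taxa]
    dist = D.values.astype(float).copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        return max(float(x), 0.0)

    if n == 2:
        half = clamp(dist[0, 1] / 2.0)
        nodes[0].length = half
        nodes[1].length = half
        return TreeNode(children=[nodes[0], nodes[1]])

    idx = {k: k for k in active}  # active label -> row in dist
    current = {k: nodes[k] for k in active}

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_([idx[a] for a in active], [idx[a] for a in active])]
        r = sub.sum(axis=1)
        qmat = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(qmat, np.inf)
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                if best is None or qmat[ai, bi] < qmat[best[0], best[1]] - 1e-15:
                    best = (ai, bi)
        ai, bi = best
        a, b = active[ai], active[bi]
        d_ab = sub[ai, bi]
        la = clamp(0.5 * d_ab + (r[ai] - r[bi]) / (2.0 * (m - 2)))
        lb = clamp(0.5 * d_ab + (r[bi] - r[ai]) / (2.0 * (m - 2)))
        current[a].length = la
        current[b].length = lb
        parent = TreeNode(children=[current[a], current[b]])

        # distances from the new node to the remaining taxa
        new_row = {}
        for c in active:
            if c in (a, b):
                continue
            new_row[c] = 0.5 * (
                dist[idx[a], idx[c]] + dist[idx[b], idx[c]] - d_ab
            )
        # reuse a's slot for the new node
        for c, v in new_row.items():
            dist[idx[a], idx[c]] = dist[idx[c], idx[a]] = v
        current[a] = parent
        active.remove(b)

    # resolve the final three nodes around a trifurcating root
    x, y, z = active
    dxy = dist[idx[x], idx[y]]
    dxz = dist[idx[x], idx[z]]
    dyz = dist[idx[y], idx[z]]
    current[x].length = clamp(0.5 * (dxy + dxz - dyz))
    current[y].length = clamp(0.5 * (dxy + dyz - dxz))
    current[z].length = clamp(0.5 * (dxz + dyz - dxy))
    return TreeNode(children=[current[x], current[y], current[z]])


def sanitize_label(label: str) -> str:
    """Restrict a taxon label to ``[A-Za-z0-9_]`` (shared by all writers)."""
    return re.sub(r"[^A-Za-z0-9_]", "_", label)


def write_nexus(D: DistanceMatrix, path: str | Path) -> None:
    """Serialise a distance matrix as a NEXUS file.

    Writes a TAXA block (ntax + labels) and a DISTANCES block with
    ``FORMAT TRIANGLE=BOTH DIAGONAL`` (full square matrix).  The matrix
    is validated before anything is written.
    """
    labels = [sanitize_label(t) for t in D.taxa]
    if len(set(labels)) != len(labels):
        raise ValueError("sanitised labels collide")
    n = len(labels)
    width = max(len(l) for l in labels)
    lines = [
        "#NEXUS",
        "",
        "BEGIN TAXA;",
        f"    DIMENSIONS NTAX={n};",
        "    TAXLABELS " + " ".join(labels) + ";",
        "END;",
        "",
        "BEGIN DISTANCES;",
        f"    DIMENSIONS NTAX={n};",
        "    FORMAT TRIANGLE=BOTH DIAGONAL;",
        "    MATRIX",
    ]
    for i, label in enumerate(labels):
        row = " ".join(f"{v:.9f}" for v in D.values[i])
        lines.append(f"        {label:<{width}} {row}")
    lines += ["    ;", "END;", ""]
    Path(path).write_text("\n".join(lines))


def read_nexus_distances(path: str | Path) -> DistanceMatrix:
    """Parse a NEXUS DISTANCES block written by :func:`write_nexus`."""
    text = Path(path).read_text()
    m = re.search(r"MATRIX(.*?);", text, flags=re.S | re.I)
    if not m:
        raise ValueError("no MATRIX block found")
    taxa: list[str] = []
    rows: list[list[float]] = []
    for line in m.group(1).strip().splitlines():
        parts = line.split()
        if not parts:
            continue
        taxa.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(taxa, np.asarray(rows))


def _newick_str(node: TreeNode) -> str:
    if node.is_leaf:
        return f"{sanitize_label(node.name)}:{node.length:.6f}"
    inner = ",".join(_newick_str(c) for c in node.children)
    return f"({inner}):{node.length:.6f}"


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialise a tree in Newick with 6-decimal branch lengths.

    The unrooted tree is written from its arbitrary (trifurcating) root;
    the apparent root carries no evolutionary meaning.
    """
    inner = ",".join(_newick_str(c) for c in tree.children)
    Path(path).write_text(f"({inner});\n")
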