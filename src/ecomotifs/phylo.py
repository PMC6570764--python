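"""Time-slicing an ultrametric phylogeny into lineage-level features.

To build phylogenetic motifs, species-level abundance columns are
collapsed onto the lineages present at a chosen time T (Myr before
present): the tree is cut at height T above the tips and every edge the
cut crosses defines one clade, whose count in a site is the sum over the
species it subtends. T = 0 leaves species as they are; T at or beyond
the root age pools everything into a single clade.

Boundary convention: a node sitting exactly at age T belongs with the
edge above it, i.e. an edge is a lineage at T when
``child_age <= T < parent_age`` (the root's parent age is taken as
infinite). This makes T = 0 the identity map and T = root age a single
clade, and keeps slices nested: clades at a deeper T are unions of
clades at any shallower T.

Trees are handled through dendropy; input must be rooted, with branch
lengths in Myr, and ultrametric within a small relative tolerance —
non-ultrametric trees are rejected rather than silently stretched,
because depth spread usually signals a data error upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .matrices import CountMatrix

__all__ = ["TimeTree", "CladeMap", "slice_tree", "collapse_counts"]

_ULTRAMETRIC_RTOL = 1e-6


@dataclass
class TimeTree:
    """Rooted ultrametric tree with branch lengths in Myr, tips = species."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(labels) < 2:
            raise ValueError("tree needs at least 2 tips")
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")
        self._check_ultrametric()

    # -- constructors --------------------------------------------------
    @classmethod
    def from_newick(cls, source: str | Path) -> "TimeTree":
        if isinstance(source, Path) or not source.lstrip().startswith("("):
            tree = dendropy.Tree.get(path=str(source), schema="newick")
        else:
            tree = dendropy.Tree.get(data=source, schema="newick")
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    # -- geometry ------------------------------------------------------
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def node_depths(self) -> dict[dendropy.Node, float]:
        """Distance of every node from the root (root depth 0)."""
        depths: dict[dendropy.Node, float] = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
        return depths

    @property
    def root_age(self) -> float:
        return max(self.node_depths().values())

    def node_ages(self) -> dict[dendropy.Node, float]:
        """Age of every node, measured back from the tips (tips at 0)."""
        depths = self.node_depths()
        height = max(depths.values())
        return {node: height - d for node, d in depths.items()}

    def _check_ultrametric(self) -> None:
        depths = self.node_depths()
        tip_depths = {n.taxon.label: d for n, d in depths.items() if n.is_leaf()}
        lo, hi = min(tip_depths.values()), max(tip_depths.values())
        if hi <= 0:
            raise ValueError("tree has no positive branch lengths")
        if (hi - lo) > _ULTRAMETRIC_RTOL * max(hi, 1.0):
            offenders = sorted(tip_depths, key=tip_depths.get)
            raise ValueError(
                "tree is not ultrametric: tip depths span "
                f"[{lo:.6g}, {hi:.6g}]; shallowest tip {offenders[0]!r}, "
                f"deepest {offenders[-1]!r}"
            )


@dataclass
class CladeMap:
    """Species -> lineage assignment induced by cutting the tree at T."""

    T: float
    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("empty clade map")

    @property
    def clade_ids(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    @property
    def n_clades(self) -> int:
        return len(set(self.mapping.values()))

    def members(self, clade_id: str) -> list[str]:
        return sorted(s for s, c in self.mapping.items() if c == clade_id)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"species": list(self.mapping), "clade": list(self.mapping.values())}
        ).sort_values(["clade", "species"])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, T: float = float("nan")) -> "CladeMap":
        df = pd.read_csv(path)
        return cls(T, dict(zip(df["species"].astype(str), df["clade"].astype(str))))


def slice_tree(tree: TimeTree, T: float) -> CladeMap:
    """Cut the tree T Myr before present; each crossed edge is a clade.

    Clade ids are ``T{T}_{smallest tip label}``, deterministic for a
    given tree and slice.
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    ages = tree.node_ages()
    # fuzz absorbs float error in node ages (tips can sit at +-1e-15)
    fuzz = 1e-9 * max(tree.root_age, 1.0)
    mapping: dict[str, str] = {}
    for node in tree.tree.preorder_node_iter():
        parent = node.parent_node
        parent_age = float("inf") if parent is None else ages[parent]
        if ages[node] <= T + fuzz < parent_age:
            tips = sorted(leaf.taxon.label for leaf in node.leaf_iter())
            clade_id = f"T{T:g}_{tips[0]}"
            for tip in tips:
                mapping[tip] = clade_id
    missing = set(tree.tip_labels()) - set(mapping)
    if missing:  # every species must land in exactly one lineage
        raise RuntimeError(f"slice at T={T} lost species: {sorted(missing)[:5]}")
    return CladeMap(T, mapping)


def collapse_counts(counts: CountMatrix, clade_map: CladeMap) -> CountMatrix:
    """Sum species columns within clades; row totals are conserved exactly.

    Every column of ``counts`` must appear in the map (extra map entries
    are allowed — the survey need not contain every tip of the tree).
    """
    unmapped = [c for c in counts.col_ids if c not in clade_map.mapping]
    if unmapped:
        raise KeyError(f"columns missing from clade map: {unmapped[:10]}")
    clade_ids = sorted({clade_map.mapping[c] for c in counts.col_ids})
    col_index = {cid: j for j, cid in enumerate(clade_ids)}
    out = np.zeros((counts.n_rows, len(clade_ids)), dtype=np.int64)
    for j, col in enumerate(counts.col_ids):
        out[:, col_index[clade_map.mapping[col]]] += counts.values[:, j]
    return CountMatrix(out, list(counts.row_ids), clade_ids)
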