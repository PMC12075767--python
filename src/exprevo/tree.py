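"""Species-tree container used throughout the package.

The tree is rooted and ultrametric (all root-to-tip depths equal, up to a
relative tolerance), tips are labeled with species names, and every branch
carries a small-integer *rate class* used by the Brownian-motion rate models.
Nodes are stored in post-order and addressed by their post-order index, which
is stable across re-reads of the same Newick file.
"""

from __future__ import annotations

import io as _stdio
import os
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = ["SpeciesTree", "TreeError", "read_class_map"]


class TreeError(ValueError):
    """Raised for malformed or non-ultrametric trees."""


class SpeciesTree:
    """Rooted ultrametric phylogeny with per-branch rate-class labels.

    Parameters
    ----------
    parent, length, rate_class, children, labels
        Flat post-order representation: ``parent[i]`` is the post-order index
        of node *i*'s parent (−1 for the root), ``length[i]`` the length of the
        branch above node *i* (0 for the root), ``rate_class[i]`` the class of
        that branch, ``children[i]`` the child indices in file order and
        ``labels[i]`` the tip name (internal nodes may carry a label or None).
    """

    ULTRAMETRIC_RTOL = 1e-6

    def __init__(
        self,
        parent: np.ndarray,
        length: np.ndarray,
        rate_class: np.ndarray,
        children: Sequence[Sequence[int]],
        labels: Sequence[str | None],
        validate: bool = True,
    ):
        self.parent = np.asarray(parent, dtype=int)
        self.length = np.asarray(length, dtype=float)
        self.rate_class = np.asarray(rate_class, dtype=int)
        self.children = [list(c) for c in children]
        self.labels = list(labels)
        n = self.parent.size
        if not (self.length.size == self.rate_class.size == len(self.children) == len(self.labels) == n):
            raise TreeError("inconsistent array lengths")
        self.is_tip = np.array([len(c) == 0 for c in self.children], dtype=bool)
        if validate:
            self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        source: str | os.PathLike,
        class_map: Mapping[int, Sequence[Sequence[str]]] | str | None = None,
        validate: bool = True,
    ) -> "SpeciesTree":
        """Parse a Newick tree from a file path or a literal string.

        ``class_map`` maps a rate-class label to a list of clade-defining tip
        sets; every branch inside such a clade, plus the stem branch leading to
        it, receives that class.  ``None`` (or ``"none"``) labels every branch
        class 0.  Square-bracket comments are ignored; internal node labels are
        kept but node identity is the post-order index.
        """
        text = cls._read_source(source)
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        nodes = list(dtree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        length = np.zeros(n)
        children: list[list[int]] = [[] for _ in range(n)]
        labels: list[str | None] = [None] * n
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                children[parent[i]].append(i)
                length[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label:
                labels[i] = str(nd.label)
        tree = cls(parent, length, np.zeros(n, dtype=int), children, labels, validate=validate)
        if class_map is not None and class_map != "none":
            tree.apply_class_map(class_map)
        return tree

    @staticmethod
    def _read_source(source: str | os.PathLike) -> str:
        s = os.fspath(source)
        if ";" in s or "(" in s:  # literal newick string
            return s
        with open(s) as fh:
            return fh.read()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        if self.n_tips < 2:
            raise TreeError("tree needs at least 2 tips")
        tips = [self.labels[i] for i in self.tip_ids]
        if any(t is None for t in tips):
            raise TreeError("every tip must be labeled")
        if len(set(tips)) != len(tips):
            raise TreeError("duplicate tip labels")
        if np.any(self.length < 0):
            raise TreeError("negative branch length")
        d = self.depths()
        td = d[self.is_tip]
        scale = max(td.max(), 1.0)
        if td.max() - td.min() > self.ULTRAMETRIC_RTOL * scale:
            hi = self.tip_ids[int(np.argmax(td))]
            lo = self.tip_ids[int(np.argmin(td))]
            raise TreeError(
                f"tree is not ultrametric: depth({self.labels[hi]})={td.max():g} vs "
                f"depth({self.labels[lo]})={td.min():g}"
            )

    # -- basic queries ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return self.n_nodes - 1  # post-order puts the root last

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def tip_ids(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_ids]

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    def tip_index(self, name: str) -> int:
        for i in self.tip_ids:
            if self.labels[i] == name:
                return int(i)
        raise KeyError(f"tip {name!r} not in tree")

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths (pre-order accumulation)."""
        d = np.zeros(self.n_nodes)
        for i in range(self.n_nodes - 2, -1, -1):  # reverse post-order = pre-order
            d[i] = d[self.parent[i]] + self.length[i]
        return d

    def depth(self) -> float:
        return float(self.depths()[self.is_tip].max())

    def node_key(self, i: int) -> str:
        """Stable node identifier: the label when present, else the post-order id."""
        return self.labels[i] if self.labels[i] is not None else str(i)

    def clade(self, node: int) -> list[int]:
        """Post-order list of all nodes in the subtree rooted at ``node`` (inclusive)."""
        out = []
        stack = [node]
        while stack:
            k = stack.pop()
            out.append(k)
            stack.extend(self.children[k])
        return sorted(out)

    def clade_tips(self, node: int) -> list[str]:
        return [self.labels[i] for i in self.clade(node) if self.is_tip[i]]

    def mrca(self, tips: Iterable[str]) -> int:
        want = set(tips)
        missing = want - set(self.tip_labels)
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        # smallest post-order node whose clade covers the requested tips
        for i in range(self.n_nodes):
            if want <= set(self.clade_tips(i)):
                return i
        return self.root

    # -- rate classes ------------------------------------------------------

    def apply_class_map(self, class_map: Mapping[int, Sequence[Sequence[str]]]) -> None:
        """Label clades in-place: each listed tip set marks its MRCA's stem
        branch plus every branch inside the clade; unlisted branches keep 0."""
        self.rate_class[:] = 0
        for label, clades in sorted(class_map.items()):
            for tipset in clades:
                node = self.mrca(tipset)
                if set(self.clade_tips(node)) != set(tipset):
                    raise TreeError(
                        f"tip set {sorted(tipset)} is not a clade (MRCA spans "
                        f"{sorted(self.clade_tips(node))})"
                    )
                for k in self.clade(node):
                    self.rate_class[k] = int(label)
        self.rate_class[self.root] = 0  # the root has no branch

    def with_rate_classes(self, classes: np.ndarray) -> "SpeciesTree":
        """Copy of the tree with per-branch classes replaced (root entry ignored)."""
        classes = np.asarray(classes, dtype=int)
        if classes.size != self.n_nodes:
            raise TreeError("class vector must have one entry per node")
        t = SpeciesTree(self.parent.copy(), self.length.copy(), classes.copy(),
                        [list(c) for c in self.children], list(self.labels),
                        validate=False)
        t.rate_class[t.root] = 0
        return t

    @property
    def n_classes(self) -> int:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.root] = False
        return int(len(np.unique(self.rate_class[mask])))

    # -- output ------------------------------------------------------------

    def to_newick(self, path: str | os.PathLike | None = None,
                  internal_labels: bool = False) -> str:
        def fmt(i: int) -> str:
            if self.is_tip[i]:
                core = self.labels[i]
            else:
                inner = ",".join(fmt(c) for c in self.children[i])
                lab = ""
                if internal_labels:
                    lab = self.labels[i] if self.labels[i] is not None else str(i)
                core = f"({inner}){lab}"
            if i == self.root:
                return core
            return f"{core}:{self.length[i]:.10g}"

        s = fmt(self.root) + ";"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<SpeciesTree n_tips={self.n_tips} depth={self.depth():g} "
                f"classes={self.n_classes}>")


def read_class_map(path: str | os.PathLike) -> dict[int, list[list[str]]]:
    """Read a YAML rate-class map: ``{class label: [[tip, ...], ...]}``."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise TreeError("class map must be a mapping of class label -> clades")
    out: dict[int, list[list[str]]] = {}
    for k, v in raw.items():
        out[int(k)] = [list(map(str, clade)) for clade in v]
    return out
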