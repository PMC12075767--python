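"""Global transcriptome similarity: correlations, 1 − Spearman distances and a
neighbor-joining expression tree.

Correlations are computed between the columns (species × tissue profiles) of
the complete-orthogroup expression matrix, by default on the log2(TPM + 1)
scale.  The expression tree uses the classic Saitou–Nei neighbor-joining
agglomeration on a ``1 − correlation`` distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ValidationError
from .orthomatrix import OGExpressionMatrix

__all__ = ["DistanceMatrix", "NJNode", "correlation_matrix",
           "expression_distance", "nj_tree"]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.values, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape does not match labels")
        finite = np.isfinite(d)
        if not np.allclose(np.where(finite, d, 0), np.where(finite.T, d.T, 0), atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if np.nanmax(np.abs(np.diag(d))) > 1e-12:
            raise ValidationError("distance matrix diagonal not zero")
        if np.nanmin(d) < -1e-12:
            raise ValidationError("negative distances")
        self.values = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())


def _flat_labels(df: pd.DataFrame) -> list[str]:
    if isinstance(df.columns, pd.MultiIndex):
        return [".".join(map(str, c)) for c in df.columns]
    return [str(c) for c in df.columns]


def correlation_matrix(matrix: OGExpressionMatrix | pd.DataFrame,
                       method: str = "pearson",
                       log_transform: bool = True) -> pd.DataFrame:
    """Pairwise column correlations of the OG expression matrix.

    Spearman uses mid-ranks for ties.  Pearson is computed on log2(TPM + 1) by
    default (``log_transform=False`` for the raw scale); ranks are unaffected.
    Zero-variance columns yield missing (NaN) correlations, never 0.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    df = matrix.values if isinstance(matrix, OGExpressionMatrix) else matrix
    if df.shape[0] < 3:
        raise ValidationError("need at least 3 rows for correlations")
    data = df.to_numpy(dtype=float)
    if log_transform and method == "pearson":
        data = np.log2(data + 1.0)
    labels = _flat_labels(df)
    work = pd.DataFrame(data, columns=labels)
    corr = work.corr(method=method)  # pandas: NaN for zero-variance columns
    np.fill_diagonal(corr.values, 1.0)
    zero_var = work.std(ddof=0) == 0
    corr.loc[zero_var, :] = np.nan
    corr.loc[:, zero_var] = np.nan
    return corr


def expression_distance(corr: pd.DataFrame, transform: str = "one_minus") -> DistanceMatrix:
    """Distance ``d = 1 − correlation`` (range [0, 2]); missing correlations
    propagate to missing distances."""
    if transform != "one_minus":
        raise ValidationError(f"unknown transform {transform!r}")
    d = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return DistanceMatrix(list(corr.columns), d)


@dataclass
class NJNode:
    """Node of the (unrooted, stored with a trifurcating root) NJ tree."""

    label: str | None = None
    children: list[tuple["NJNode", float]] | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def newick(self) -> str:
        return self._fmt() + ";"

    def _fmt(self) -> str:
        if self.is_leaf:
            return str(self.label)
        inner = ",".join(f"{c._fmt()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions (as frozensets of one side's leaf labels)."""
        all_leaves = frozenset(self._leaves())
        out: set[frozenset] = set()

        def walk(node: NJNode):
            leaves = set()
            if node.is_leaf:
                return {node.label}
            for c, _ in node.children:
                leaves |= walk(c)
            if 1 < len(leaves) < len(all_leaves) - 1:
                side = frozenset(leaves)
                out.add(min(side, all_leaves - side, key=sorted))
            return leaves

        walk(self)
        return out

    def _leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [x for c, _ in self.children for x in c._leaves()]


def _min_leaf(node: NJNode) -> str:
    return min(node._leaves())


def nj_tree(d: DistanceMatrix) -> NJNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing the Q criterion
    ``Q(i,j) = (n−2) d(i,j) − r(i) − r(j)`` is joined; ties are broken by the
    lexicographic order of the joined subtrees' smallest leaf labels.  A
    negative branch length is clamped to 0 with the deficit transferred to its
    sibling so path distances are preserved.  The tree is returned rooted at
    the final (trifurcating for >3 taxa) join.
    """
    if d.has_missing or not np.isfinite(d.values).all():
        raise ValidationError("neighbor joining requires finite distances")
    n0 = len(d.labels)
    if n0 < 4:
        raise ValidationError("neighbor joining needs at least 4 labels")
    nodes: list[NJNode] = [NJNode(label=l) for l in d.labels]
    D = d.values.astype(float).copy()
    active = list(range(n0))
    store: dict[int, NJNode] = {i: nodes[i] for i in active}
    next_id = n0
    Dm = {(i, j): D[i, j] for i in active for j in active if i < j}

    def dist(i, j):
        return Dm[(i, j) if i < j else (j, i)]

    while len(active) > 3:
        n = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for a_i in range(len(active)):
            for a_j in range(a_i + 1, len(active)):
                i, j = active[a_i], active[a_j]
                q = (n - 2) * dist(i, j) - r[i] - r[j]
                key = tuple(sorted((_min_leaf(store[i]), _min_leaf(store[j]))))
                if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, i, j)
        _, _, i, j = best
        dij = dist(i, j)
        bi = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        bj = dij - bi
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        u = next_id
        next_id += 1
        store[u] = NJNode(children=[(store[i], bi), (store[j], bj)])
        for k in active:
            if k in (i, j):
                continue
            Dm[(min(k, u), max(k, u))] = 0.5 * (dist(i, k) + dist(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    # three-leaf completion: b_x = (d(x,y) + d(x,z) - d(y,z)) / 2
    bi = 0.5 * (dist(i, j) + dist(i, k) - dist(j, k))
    bj = 0.5 * (dist(i, j) + dist(j, k) - dist(i, k))
    bk = 0.5 * (dist(i, k) + dist(j, k) - dist(i, j))
    bi, bj, bk = (max(b, 0.0) for b in (bi, bj, bk))
    root = NJNode(children=[(store[i], bi), (store[j], bj), (store[k], bk)])
    return root
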