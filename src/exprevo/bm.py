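"""Brownian-motion likelihood, ancestral reconstruction and the bounded
grid variant.

The model: a continuous trait (log2(TPM + 1) expression by default) evolves
along the species tree by Gaussian Brownian motion whose variance accumulates
as sigma2[class(branch)] × branch length.  The root state is a nuisance
parameter profiled at its maximum-likelihood value, which equals the GLS mean
μ̂ = (1ᵀC⁻¹x) / (1ᵀC⁻¹1) for tip covariance C built from shared path lengths.

The likelihood is evaluated by Felsenstein's post-order pruning (exact
Gaussian elimination), vectorized across orthogroups that share a tree and
missingness pattern.  Marginal ancestral states come from two-pass Gaussian
belief propagation with a flat root prior, which reproduces the GLS/BLUP
closed form.  A bounded variant discretizes expression onto a reflecting grid
with matrix-exponential branch transitions and converges to the Gaussian
likelihood as the bounds widen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import SpeciesTree, TreeError

__all__ = ["LikTree", "build_lik_tree", "prune_loglik", "bm_loglik",
           "marginal_ancestral", "bounded_bm_loglik"]

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class LikTree:
    """Flattened (possibly pruned) tree prepared for likelihood work.

    ``class_time[i, c]`` is the time node *i*'s branch spends in rate class
    *c* — pruning a tip can merge branches of different classes, so a branch
    is a per-class time vector, and its BM variance is ``class_time @ sigma2``.
    ``orig_node[i]`` is the matching node id in the original tree (for merged
    branches, the tipward segment's node), and ``tip_cols`` orders the tips.
    """

    parent: np.ndarray
    children: list[list[int]]
    class_time: np.ndarray  # (n_nodes, n_classes)
    is_tip: np.ndarray
    tip_labels: list[str]
    orig_node: np.ndarray
    classes: np.ndarray  # sorted original class labels, len n_classes

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())


def build_lik_tree(tree: SpeciesTree, keep_tips: list[str] | None = None) -> LikTree:
    """Prepare a tree (optionally pruned to ``keep_tips``) for likelihood work.

    Pruning drops absent tips, suppresses the resulting unifurcations by
    summing their per-class branch times, and drops a root with a single
    child (its dangling branch adds no information under a profiled root).
    """
    classes = np.unique(np.delete(tree.rate_class, tree.root))
    cindex = {c: k for k, c in enumerate(classes)}
    n, k = tree.n_nodes, len(classes)
    ct = np.zeros((n, k))
    for i in range(n - 1):
        ct[i, cindex[tree.rate_class[i]]] = tree.length[i]

    keep = set(keep_tips) if keep_tips is not None else set(tree.tip_labels)
    missing = keep - set(tree.tip_labels)
    if missing:
        raise TreeError(f"tips not in tree: {sorted(missing)}")
    if len(keep) < 2:
        raise TreeError("need at least 2 tips with data")

    alive = np.zeros(n, dtype=bool)
    for i in range(n):
        if tree.is_tip[i]:
            alive[i] = tree.labels[i] in keep
        else:
            alive[i] = any(alive[c] for c in tree.children[i])

    # rebuild post-order over surviving nodes, suppressing unifurcations
    new_children: list[list[int]] = []
    new_ct: list[np.ndarray] = []
    new_orig: list[int] = []
    new_lab: list[str | None] = []
    node_of: dict[int, int] = {}

    def emit(children: list[int], ctime: np.ndarray, orig: int, lab: str | None) -> int:
        new_children.append(children)
        new_ct.append(ctime)
        new_orig.append(orig)
        new_lab.append(lab)
        return len(new_children) - 1

    for i in range(n):
        if not alive[i]:
            continue
        kids = [c for c in tree.children[i] if alive[c]]
        if tree.is_tip[i]:
            node_of[i] = emit([], ct[i].copy(), i, tree.labels[i])
        elif len(kids) == 1:
            # unifurcation: absorb this node, extend the child's branch
            j = node_of[kids[0]]
            new_ct[j] = new_ct[j] + ct[i]
            node_of[i] = j
        else:
            node_of[i] = emit([node_of[c] for c in kids], ct[i].copy(), i, None)

    # the surviving root is wherever the original root was mapped (a root
    # unifurcation gets absorbed into its child); its dangling branch carries
    # no information under a profiled root, so zero it out
    root = node_of[n - 1]
    if root != len(new_children) - 1:
        raise AssertionError("pruning invariant violated")
    new_ct[root] = np.zeros(k)

    m = len(new_children)
    parent = np.full(m, -1, dtype=int)
    for i, kids in enumerate(new_children):
        for c in kids:
            parent[c] = i
    is_tip = np.array([len(c) == 0 for c in new_children], dtype=bool)
    tips = [new_lab[i] for i in range(m) if is_tip[i]]
    return LikTree(parent, new_children, np.array(new_ct), is_tip, tips,
                   np.array(new_orig), classes)


def _fold(m1, v1, m2, v2):
    """Combine two independent Gaussian messages about the same node value.

    Returns the contrast log-likelihood pieces and the combined (mean, var).
    """
    vs = v1 + v2
    ll = -0.5 * (LOG2PI + np.log(vs)) - 0.5 * (m1 - m2) ** 2 / vs
    mean = (m1 * v2 + m2 * v1) / vs
    var = v1 * v2 / vs
    return ll, mean, var


def prune_loglik(lt: LikTree, X: np.ndarray, sigma2: np.ndarray,
                 return_root: bool = False):
    """Vectorized pruning log-likelihood with the root profiled.

    ``X`` is (n_tips, N) tip data in ``lt.tip_labels`` order; ``sigma2`` a
    length-``n_classes`` vector.  Returns the per-column log-likelihood
    (length N), optionally with the profiled root mean and its variance scale.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0) or sigma2.size != lt.classes.size:
        raise ValueError("sigma2 must be positive, one value per rate class")
    bv = lt.class_time @ sigma2  # branch variance above each node
    if bv.sum() <= 0:
        raise ValueError("all branch lengths are zero; likelihood undefined")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N = X.shape[1]
    ll = np.zeros(N)
    mean = [None] * lt.n_nodes
    var = np.zeros(lt.n_nodes)
    ti = 0
    for i in range(lt.n_nodes):
        if lt.is_tip[i]:
            mean[i] = X[ti]
            var[i] = bv[i]
            ti += 1
        else:
            kids = lt.children[i]
            m, v = mean[kids[0]], var[kids[0]]
            for c in kids[1:]:
                piece, m, v = _fold(m, v, mean[c], var[c])
                ll += piece
            mean[i] = m
            var[i] = v + bv[i]
    v_root = var[lt.root]
    if v_root <= 0:
        raise ValueError("all path variances are zero; check branch lengths")
    ll += -0.5 * (LOG2PI + np.log(v_root))  # profiled root: exponent term is 0
    if return_root:
        return ll, mean[lt.root], v_root
    return ll


def bm_loglik(tree: SpeciesTree, trait: dict[str, float], sigma2_by_class) -> float:
    """Log-likelihood of one trait vector under branch-class BM.

    ``trait`` maps species → value; species missing from it are pruned from
    the tree.  ``sigma2_by_class`` maps the tree's class labels to rates (a
    scalar is broadcast to all classes).
    """
    present = [s for s in tree.tip_labels if s in trait]
    if len(present) < 2:
        raise TreeError("need at least 2 species with data")
    lt = build_lik_tree(tree, keep_tips=present)
    if np.isscalar(sigma2_by_class):
        sig = np.full(lt.classes.size, float(sigma2_by_class))
    else:
        sig = np.array([sigma2_by_class[c] for c in lt.classes], dtype=float)
    x = np.array([[trait[s]] for s in lt.tip_labels])
    return float(prune_loglik(lt, x, sig)[0])


def marginal_ancestral(lt: LikTree, X: np.ndarray, sigma2: np.ndarray):
    """Marginal (empirical-Bayes) reconstructions at every node.

    Two-pass Gaussian belief propagation with a flat prior on the root, which
    is equivalent to the GLS/BLUP estimator with the root mean estimated by
    GLS.  Returns ``(means, variances)`` with shapes (n_nodes, N) and
    (n_nodes,); tip rows equal the observations with variance 0.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    bv = lt.class_time @ sigma2
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N = X.shape[1]
    n = lt.n_nodes

    # downpass: below[i] = distribution of node i's value given descendant tips
    below_m = [None] * n
    below_v = np.zeros(n)
    ti = 0
    for i in range(n):
        if lt.is_tip[i]:
            below_m[i] = X[ti]
            below_v[i] = 0.0
            ti += 1
        else:
            m, v = None, None
            for c in lt.children[i]:
                cm, cv = below_m[c], below_v[c] + bv[c]
                if m is None:
                    m, v = cm, cv
                else:
                    _, m, v = _fold(m, v, cm, cv)
            below_m[i] = m
            below_v[i] = v

    # uppass: above[i] = distribution given everything outside i's subtree
    above_m = [None] * n  # None encodes the flat (infinite-variance) message
    above_v = np.full(n, np.inf)
    for i in range(n - 1, -1, -1):
        for c in lt.children[i]:
            m, v = above_m[i], above_v[i]
            for s in lt.children[i]:
                if s == c:
                    continue
                sm, sv = below_m[s], below_v[s] + bv[s]
                if m is None:
                    m, v = sm, sv
                else:
                    _, m, v = _fold(m, v, sm, sv)
            if m is None:
                above_m[c], above_v[c] = None, np.inf
            else:
                above_m[c], above_v[c] = m, v + bv[c]

    means = np.empty((n, N))
    variances = np.empty(n)
    for i in range(n):
        bm_, bv_ = below_m[i], below_v[i]
        am_, av_ = above_m[i], above_v[i]
        if am_ is None:
            means[i], variances[i] = bm_, bv_
        elif bv_ == 0.0:
            means[i], variances[i] = bm_, 0.0
        else:
            _, m, v = _fold(bm_, bv_, am_, av_)
            means[i], variances[i] = m, v
    return means, variances


# ---------------------------------------------------------------------------
# bounded variant

def _grid_operator(n_grid: int, lo: float, hi: float):
    """Eigendecomposition of the reflecting (Neumann) diffusion generator on a
    uniform grid: eigenvectors are the DCT-II cosine modes."""
    dx = (hi - lo) / (n_grid - 1)
    j = np.arange(n_grid)
    k = np.arange(n_grid)
    V = np.cos(np.pi * np.outer(k, (j + 0.5)) / n_grid)  # (mode, cell)
    V[0] *= np.sqrt(1.0 / n_grid)
    V[1:] *= np.sqrt(2.0 / n_grid)
    lam = -2.0 * (1.0 - np.cos(np.pi * k / n_grid)) / dx**2
    return V, lam, dx


def bounded_bm_loglik(tree: SpeciesTree, trait: dict[str, float], sigma2_by_class,
                      lo: float, hi: float, n_grid: int = 200) -> float:
    """Log-likelihood under BM bounded to [lo, hi] by reflecting boundaries.

    Expression is discretized onto ``n_grid`` uniform cells; each branch's
    transition matrix is the matrix exponential of the reflecting diffusion
    generator scaled by sigma2 × length / 2.  Tip values become point masses
    on their nearest cell; the root is profiled by maximizing over grid cells,
    and the result is reported as a log *density* (cell masses divided by the
    cell width) so that it converges to :func:`bm_loglik` as the bounds widen.
    """
    present = [s for s in tree.tip_labels if s in trait]
    lt = build_lik_tree(tree, keep_tips=present)
    if np.isscalar(sigma2_by_class):
        sig = np.full(lt.classes.size, float(sigma2_by_class))
    else:
        sig = np.array([sigma2_by_class[c] for c in lt.classes], dtype=float)
    vals = np.array([trait[s] for s in lt.tip_labels])
    if vals.min() < lo or vals.max() > hi:
        raise ValueError("tip values outside the bounds")
    bv = lt.class_time @ sig
    V, lam, dx = _grid_operator(n_grid, lo, hi)
    grid = lo + dx * np.arange(n_grid)

    def transition(v_branch: float) -> np.ndarray:
        T = V.T @ (np.exp(lam * v_branch / 2.0)[:, None] * V)
        return np.clip(T, 0.0, None)

    msg = [None] * lt.n_nodes
    ti = 0
    log_scale = 0.0
    for i in range(lt.n_nodes):
        if lt.is_tip[i]:
            # tip mass split between the two flanking cells (linear
            # interpolation keeps the discretization error O(dx^2))
            m = np.zeros(n_grid)
            pos = (vals[ti] - lo) / dx
            j0 = min(int(pos), n_grid - 2)
            frac = pos - j0
            m[j0] = 1.0 - frac
            m[j0 + 1] = frac
            ti += 1
        else:
            m = np.ones(n_grid)
            for c in lt.children[i]:
                m = m * (transition(bv[c]) @ msg[c])
            s = m.max()
            if s <= 0:
                return -np.inf
            log_scale += np.log(s)
            m = m / s
        msg[i] = m
    root_best = msg[lt.root].max()
    # cell probabilities -> density: one dx per tip observation
    return float(np.log(root_best) + log_scale - lt.n_tips * np.log(dx))
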