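"""Branch-class Brownian-motion rate models of expression evolution.

The central objects follow the model/results idiom: :class:`ExpressionBM`
holds a trait table (orthogroup × species, one tissue, log2(TPM + 1) by
default) and a species tree whose branches carry rate-class labels; its
:meth:`~ExpressionBM.fit` maximizes the summed profiled-root BM likelihood
over a per-class rate vector σ² shared by all orthogroups, returning an
:class:`ExpressionBMResults` with the estimates, −ln L, an AIC column and
ancestral reconstructions.

Model comparison follows the convention of ranking fitted models by raw
−ln L (lowest wins, ties broken by fewer rate classes); AIC is reported as
supplementary output only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .bm import LikTree, build_lik_tree, marginal_ancestral, prune_loglik
from .io import ValidationError
from .specificity import classify_specific
from .tree import SpeciesTree, TreeError

__all__ = [
    "ExpressionBM", "ExpressionBMResults", "AncestralStates",
    "trait_table", "fit_rate_model", "compare_models", "random_assignment",
    "ancestral_states", "node_changes", "ancestral_specificity",
    "log2_tpm", "inv_log2_tpm",
]

log = logging.getLogger(__name__)


def assignment_is_degenerate(tree: SpeciesTree) -> bool:
    """True when the profiled-root BM likelihood is unbounded for this
    branch-class assignment.

    Shrinking the rates of a class subset S toward zero sends every tip whose
    entire root path lies in S to zero marginal variance.  If exactly one tip
    collapses, the free (profiled) root can absorb its residual and the
    density diverges, so no maximum-likelihood fit exists.  (Two or more
    collapsing tips are forced to coincide, which distinct data penalize
    infinitely — that direction is safe.)
    """
    from itertools import combinations

    mask = np.ones(tree.n_nodes, dtype=bool)
    mask[tree.root] = False
    classes = np.unique(tree.rate_class[mask])
    paths = {}
    for t in tree.tip_ids:
        i, path = int(t), []
        while i != tree.root:
            if tree.length[i] > 0:
                path.append(int(tree.rate_class[i]))
            i = int(tree.parent[i])
        paths[int(t)] = set(path)
    for r in range(1, len(classes) + 1):
        for S in combinations(classes, r):
            s = set(int(c) for c in S)
            collapsed = sum(1 for p in paths.values() if p <= s)
            if collapsed == 1:
                return True
    return False


def log2_tpm(tpm):
    """Modeling transform: log2(TPM + 1)."""
    return np.log2(np.asarray(tpm, dtype=float) + 1.0)


def inv_log2_tpm(x):
    """Back-transform to the TPM scale (clipped at 0)."""
    return np.clip(np.exp2(np.asarray(x, dtype=float)) - 1.0, 0.0, None)


def trait_table(ogmat, tissue: str, transform: str = "log2p1") -> pd.DataFrame:
    """Extract one tissue's OG × species trait table from an OG expression matrix.

    Species lacking the tissue are omitted; ``transform`` is ``"log2p1"``
    (default modeling scale) or ``"raw"``.
    """
    df = ogmat.values
    cols = [c for c in df.columns if c[1] == tissue]
    if not cols:
        raise ValidationError(f"tissue {tissue!r} absent from matrix")
    out = df[cols].copy()
    out.columns = [c[0] for c in cols]
    if transform == "log2p1":
        out = pd.DataFrame(log2_tpm(out.to_numpy()), index=out.index,
                           columns=out.columns)
    elif transform != "raw":
        raise ValidationError(f"unknown transform {transform!r}")
    return out


class ExpressionBM:
    """Branch-class BM model for one tissue's orthogroup expression.

    Parameters
    ----------
    traits
        OG × species DataFrame; NaN marks a species missing for an OG (the
        tree is pruned per OG).  OGs with fewer than ``min_species`` present
        species are excluded from fitting (recorded in ``excluded_ogs``).
    tree
        Ultrametric :class:`~exprevo.tree.SpeciesTree`; its per-branch
        ``rate_class`` labels define the σ² classes.
    """

    def __init__(self, traits: pd.DataFrame, tree: SpeciesTree,
                 min_species: int = 3, name: str = "bm"):
        unknown = set(traits.columns) - set(tree.tip_labels)
        if unknown:
            raise ValidationError(f"trait species not in tree: {sorted(unknown)}")
        self.tree = tree
        self.name = name
        self.min_species = min_species
        mask = np.ones(tree.n_nodes, dtype=bool)
        mask[tree.root] = False
        self.classes = np.unique(tree.rate_class[mask])
        self.k = len(self.classes)
        if self.k > 1 and assignment_is_degenerate(tree):
            raise ValidationError(
                "branch-class assignment leaves the profiled-root likelihood "
                "unbounded (a class subset covers exactly one tip's entire "
                "root path); no ML fit exists for it")

        # group OGs by missing-species pattern; one pruned tree per pattern
        present = traits.notna()
        self._patterns: list[tuple[LikTree, np.ndarray, list[str]]] = []
        excluded = []
        for pat, idx in present.groupby(list(present.columns)).groups.items():
            if not isinstance(pat, tuple):
                pat = (pat,)
            species = [c for c, keep in zip(present.columns, pat) if keep]
            ogs = list(idx)
            if len(species) < min_species:
                excluded.extend(ogs)
                continue
            lt = build_lik_tree(tree, keep_tips=species)
            X = traits.loc[ogs, lt.tip_labels].to_numpy(dtype=float).T
            self._patterns.append((lt, X, ogs))
        if not self._patterns:
            raise ValidationError("no orthogroup has enough species for fitting")
        for lt, _, _ in self._patterns:
            if lt.classes.size != self.k or not np.array_equal(lt.classes, self.classes):
                raise ValidationError(
                    "a rate class has no branch after per-OG pruning; "
                    "reduce the class structure or the missingness")
        self.excluded_ogs = sorted(excluded)
        self.og_ids = sorted(og for _, _, ogs in self._patterns for og in ogs)
        self.n_ogs = len(self.og_ids)
        self.nobs = sum(X.shape[0] * X.shape[1] for _, X, _ in self._patterns)

    # -- likelihood --------------------------------------------------------

    def loglik(self, sigma2) -> float:
        """Summed log-likelihood over orthogroups at per-class rates ``sigma2``."""
        sig = np.broadcast_to(np.asarray(sigma2, dtype=float), (self.k,))
        total = 0.0
        for lt, X, _ in self._patterns:
            total += float(prune_loglik(lt, X, sig).sum())
        return total

    def _single_rate_mle(self) -> float:
        """Closed-form shared-rate MLE.

        With one rate s the likelihood is A − (M/2)·ln s − Q/(2s) with M the
        total number of Gaussian terms and Q the quadratic sum at s = 1, so
        two evaluations identify Q and the maximizer ŝ = Q/M exactly.
        """
        M = self.nobs
        l1 = self.loglik(1.0)
        le = self.loglik(np.e)
        Q = 2.0 * (l1 - le - M / 2.0) / (1.0 / np.e - 1.0)
        if Q <= 0:
            return 1.0
        return Q / M

    def fit(self, n_starts: int = 5, tol: float = 1e-8) -> "ExpressionBMResults":
        """Maximize the likelihood over log σ² by bounded quasi-Newton search
        with multiple deterministic starts seeded at the shared-rate MLE."""
        s0 = self._single_rate_mle()
        if self.k == 1:
            sig = np.array([s0])
            return self._results(sig, -self.loglik(sig), converged=True, nfev=2)

        theta0 = np.log(s0)
        signs = np.array([(-1.0) ** c for c in range(self.k)])
        offsets = [0.0, 1.0, -1.0, 2.0, -2.0, 3.0, -3.0][:max(n_starts, 1)]
        bounds = [(np.log(1e-9), np.log(1e9))] * self.k

        def objective(theta):
            return -self.loglik(np.exp(theta))

        best = None
        nfev = 2
        for off in offsets:
            start = theta0 + off * signs
            res = optimize.minimize(objective, start, method="L-BFGS-B",
                                    bounds=bounds,
                                    options={"ftol": tol, "gtol": 1e-10,
                                             "maxiter": 500})
            nfev += res.nfev
            if best is None or res.fun < best.fun:
                best = res
        sig = np.exp(best.x)
        return self._results(sig, float(best.fun), converged=bool(best.success),
                             nfev=nfev)

    def _results(self, sigma2, minus_ll, converged, nfev):
        return ExpressionBMResults(
            model=self, name=self.name,
            sigma2=pd.Series(sigma2, index=list(self.classes), name="sigma2"),
            minus_log_likelihood=float(minus_ll), converged=converged,
            n_function_evals=int(nfev),
        )


@dataclass
class ExpressionBMResults:
    """Fitted branch-class BM rates for one tissue."""

    model: ExpressionBM
    name: str
    sigma2: pd.Series  # indexed by rate-class label
    minus_log_likelihood: float
    converged: bool = True
    n_function_evals: int = 0

    @property
    def k(self) -> int:
        return len(self.sigma2)

    @property
    def loglik(self) -> float:
        return -self.minus_log_likelihood

    @property
    def aic(self) -> float:
        return 2.0 * self.k + 2.0 * self.minus_log_likelihood

    @property
    def og_ids(self) -> list[str]:
        return self.model.og_ids

    def summary(self) -> str:
        lines = [
            f"Branch-class Brownian-motion rate model: {self.name}",
            f"  orthogroups: {self.model.n_ogs}   species tree tips: "
            f"{self.model.tree.n_tips}   rate classes: {self.k}",
            f"  -ln L: {self.minus_log_likelihood:.1f}   AIC: {self.aic:.1f}"
            f"   converged: {self.converged}",
            "  class   sigma2",
        ]
        for c, s in self.sigma2.items():
            lines.append(f"  {c:>5}   {s:.4g}")
        return "\n".join(lines)

    def ancestral_states(self) -> "AncestralStates":
        return ancestral_states(self.model.tree, None, self)


@dataclass
class AncestralStates:
    """Reconstructed expression at every tree node.

    ``values`` and ``variances`` are node × OG DataFrames indexed by the
    original tree's post-order node ids; tip rows equal the observations with
    variance 0.  Nodes pruned away for an OG (missing species) are NaN.
    """

    tree: SpeciesTree
    values: pd.DataFrame
    variances: pd.DataFrame

    def internal_nodes(self, include_root: bool = True) -> list[int]:
        out = [i for i in range(self.tree.n_nodes) if not self.tree.is_tip[i]]
        if not include_root:
            out = [i for i in out if i != self.tree.root]
        return out


def ancestral_states(tree: SpeciesTree, traits: pd.DataFrame | None,
                     results: ExpressionBMResults) -> AncestralStates:
    """Marginal ancestral reconstructions under a fitted rate model.

    If ``traits`` is None the model's own trait table grouping is reused.
    Reconstructions are empirical-Bayes conditional means given all tips,
    equal to the GLS estimator with the root profiled.
    """
    model = results.model
    if traits is not None:
        model = ExpressionBM(traits, tree, min_species=model.min_species,
                             name=model.name)
    sig = results.sigma2.to_numpy()
    n = model.tree.n_nodes
    vals = pd.DataFrame(np.nan, index=range(n), columns=model.og_ids, dtype=float)
    var = pd.DataFrame(np.nan, index=range(n), columns=model.og_ids, dtype=float)
    for lt, X, ogs in model._patterns:
        means, variances = marginal_ancestral(lt, X, sig)
        vals.loc[lt.orig_node, ogs] = means
        var.loc[lt.orig_node, ogs] = variances[:, None]
    return AncestralStates(model.tree, vals, var)


def fit_rate_model(tree: SpeciesTree, traits: pd.DataFrame,
                   assignment=None, name: str = "bm",
                   min_species: int = 3, n_starts: int = 5) -> ExpressionBMResults:
    """Fit per-class σ² by maximum likelihood.

    ``assignment`` may be None (use the tree's branch classes), a per-node
    class array, or a clade class map ``{label: [[tip, ...], ...]}``.
    """
    if assignment is not None:
        if isinstance(assignment, dict):
            tree = tree.with_rate_classes(np.zeros(tree.n_nodes, dtype=int))
            tree.apply_class_map(assignment)
        else:
            tree = tree.with_rate_classes(np.asarray(assignment, dtype=int))
    return ExpressionBM(traits, tree, min_species=min_species, name=name).fit(
        n_starts=n_starts)


def compare_models(models: list[ExpressionBMResults]) -> pd.DataFrame:
    """Rank fitted models by ascending −ln L (ties: fewer classes win).

    All models must be fitted on the same orthogroup set.  The returned table
    mirrors the printed model-comparison layout: model name, number of rates,
    −ln L, the per-class σ² estimates, a supplementary AIC column, and a
    ``best`` flag on the top row.
    """
    if not models:
        raise ValidationError("no models to compare")
    ref = set(models[0].og_ids)
    for m in models[1:]:
        if set(m.og_ids) != ref:
            raise ValidationError("models were fitted on different orthogroup sets")
    order = sorted(models, key=lambda m: (m.minus_log_likelihood, m.k))
    rows = []
    for rank, m in enumerate(order):
        row = {"model": m.name, "n_rates": m.k,
               "minus_lnL": m.minus_log_likelihood, "aic": m.aic,
               "best": rank == 0}
        for c, s in m.sigma2.items():
            row[f"sigma2[{c}]"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def random_assignment(tree: SpeciesTree, k: int = 3, seed: int = 0) -> np.ndarray:
    """Uniform random branch classes, redrawn until the model is fittable.

    Each branch draws a class uniformly; a draw is rejected (and repeated)
    when a class is empty or when the assignment makes the profiled-root
    likelihood unbounded (see :func:`assignment_is_degenerate`).  Both
    rejection rules are symmetric in the class labels, so per-branch class
    frequencies stay uniform.  Returns a per-node class array (root entry
    unused); deterministic under ``seed``; ``k = 1`` labels every branch 0
    regardless of the seed.
    """
    n_branches = tree.n_branches
    if k > n_branches:
        raise ValidationError(f"k={k} exceeds branch count {n_branches}")
    classes = np.zeros(tree.n_nodes, dtype=int)
    if k == 1:
        return classes
    rng = np.random.default_rng(seed)
    for _ in range(10_000):
        draw = rng.integers(0, k, size=n_branches)
        if len(np.unique(draw)) < k:
            continue
        classes[:n_branches] = draw  # post-order: nodes 0..n-2 are branches
        if not assignment_is_degenerate(tree.with_rate_classes(classes)):
            return classes
    raise ValidationError("no fittable random assignment found")


def node_changes(anc: AncestralStates, tree: SpeciesTree, og_set,
                 epsilon: float = 0.0, label: str | None = None) -> pd.DataFrame:
    """Per-node counts of orthogroups increasing / decreasing along the branch
    into each internal node (root excluded).

    ``og_set`` is an :class:`~exprevo.orthomatrix.OGSpecificitySet` or an
    iterable of OG ids; the change for an OG is reconstruction(node) −
    reconstruction(parent), classified with threshold ``epsilon``.
    """
    if hasattr(og_set, "og_ids"):
        ogs = sorted(og_set.og_ids)
        label = label if label is not None else getattr(og_set, "tissue", None)
    else:
        ogs = sorted(og_set)
    ogs = [o for o in ogs if o in anc.values.columns]
    rows = []
    for node in anc.internal_nodes(include_root=False):
        parent = int(tree.parent[node])
        delta = anc.values.loc[node, ogs] - anc.values.loc[parent, ogs]
        delta = delta.dropna()
        rows.append({
            "node_id": node, "node_key": tree.node_key(node),
            "set_label": label or "set",
            "n_increase": int((delta > epsilon).sum()),
            "n_decrease": int((delta < -epsilon).sum()),
            "n_unchanged": int((delta.abs() <= epsilon).sum()),
            "n_ogs": int(delta.size),
        })
    return pd.DataFrame(rows)


def ancestral_specificity(anc_by_tissue: dict[str, AncestralStates],
                          tpm_min: float = 2.0, fc_min: float = 2.0,
                          transform: str = "log2p1") -> pd.DataFrame:
    """Tissue-specificity calls at internal nodes from per-tissue reconstructions.

    Reconstructed values are back-transformed to the TPM scale and passed
    through the same top-tissue/fold-change rule used for extant species.
    Nodes with reconstructions for fewer than two tissues are skipped with a
    log entry.  Returns a long DataFrame (node_id, og_id, assigned_tissue,
    top_tpm, fold_change).
    """
    if len(anc_by_tissue) < 2:
        raise ValidationError("need reconstructions for at least 2 tissues")
    tissues = sorted(anc_by_tissue)
    first = anc_by_tissue[tissues[0]]
    back = inv_log2_tpm if transform == "log2p1" else np.asarray
    out = []
    for node in first.internal_nodes():
        profiles = {}
        for t in tissues:
            anc = anc_by_tissue[t]
            if node not in anc.values.index:
                continue
            row = anc.values.loc[node].dropna()
            if row.empty:
                continue
            profiles[t] = pd.Series(back(row.to_numpy()), index=row.index)
        if len(profiles) < 2:
            log.info("node %s skipped: fewer than 2 reconstructed tissues", node)
            continue
        prof = pd.DataFrame(profiles).dropna()
        calls = classify_specific(prof, tpm_min=tpm_min, fc_min=fc_min)
        calls = calls.rename_axis("og_id").reset_index()
        calls.insert(0, "node_id", node)
        out.append(calls)
    if not out:
        return pd.DataFrame(columns=["node_id", "og_id", "assigned_tissue",
                                     "top_tpm", "fold_change"])
    return pd.concat(out, ignore_index=True)
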