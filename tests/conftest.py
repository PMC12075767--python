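import numpy as np
import pandas as pd
import pytest

import exprevo as ev
from exprevo.synth import CONUS_SPECIES, two_class_map


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def balanced4():
    return ev.SpeciesTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def study_tree():
    """The fixed 12-species topology with venom-clade branch classes."""
    tree = ev.simulate_tree(12, topology="study")
    tree.apply_class_map(two_class_map())
    return tree


@pytest.fixture
def small_expr():
    """Tiny two-species expression matrix with 3 tissues x 2 replicates."""
    samples = []
    cols = {}
    rng = np.random.default_rng(7)
    for sp in ("AAA", "BBB"):
        for t in ("gland", "esophagus", "salivary"):
            for r in (1, 2):
                sid = f"{sp}_{t}_r{r}"
                samples.append({"sample_id": sid, "species": sp,
                                "tissue": t, "replicate": r})
        genes = [f"{sp}_g{i}" for i in range(6)]
    # one shared gene table (both species' genes present, zeros elsewhere)
    genes = [f"{sp}_g{i}" for sp in ("AAA", "BBB") for i in range(6)]
    for row in samples:
        cols[row["sample_id"]] = np.where(
            [g.startswith(row["species"]) for g in genes],
            rng.uniform(0, 50, len(genes)), 0.0)
    values = pd.DataFrame(cols, index=genes)
    meta = pd.DataFrame(samples).set_index("sample_id")
    return ev.ExpressionMatrix(values, meta)


# ---------------------------------------------------------------------------
# independent oracles (dense linear algebra; no pruning)

def tip_paths(tree):
    out = {}
    for s in tree.tip_labels:
        i = tree.tip_index(s)
        path = []
        while i != tree.root:
            path.append(i)
            i = tree.parent[i]
        out[s] = path
    return out


def dense_cov(tree, tips, sigma_by_class):
    """BM tip covariance from pairwise shared-path rate-weighted lengths."""
    paths = tip_paths(tree)
    C = np.zeros((len(tips), len(tips)))
    for a, sa in enumerate(tips):
        for b, sb in enumerate(tips):
            shared = set(paths[sa]) & set(paths[sb])
            C[a, b] = sum(sigma_by_class[tree.rate_class[k]] * tree.length[k]
                          for k in shared)
    return C


def dense_loglik(tree, trait, sigma_by_class):
    """Profiled-root multivariate-normal log-likelihood."""
    tips = [s for s in tree.tip_labels if s in trait]
    C = dense_cov(tree, tips, sigma_by_class)
    x = np.array([trait[s] for s in tips])
    n = len(tips)
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    mu = one @ Ci @ x / (one @ Ci @ one)
    r = x - mu
    return -0.5 * (n * np.log(2 * np.pi) + np.linalg.slogdet(C)[1] + r @ Ci @ r)


def dense_ancestral(tree, trait, sigma_by_class):
    """GLS ancestral means: mu + c' C^-1 (x - mu) per internal node."""
    tips = [s for s in tree.tip_labels if s in trait]
    paths = tip_paths(tree)
    C = dense_cov(tree, tips, sigma_by_class)
    x = np.array([trait[s] for s in tips])
    Ci = np.linalg.inv(C)
    one = np.ones(len(tips))
    mu = one @ Ci @ x / (one @ Ci @ one)
    out = {}
    for node in range(tree.n_nodes):
        if tree.is_tip[node]:
            continue
        i, npath = node, []
        while i != tree.root:
            npath.append(i)
            i = tree.parent[i]
        c = np.array([sum(sigma_by_class[tree.rate_class[k]] * tree.length[k]
                          for k in set(npath) & set(paths[s])) for s in tips])
        out[node] = mu + c @ Ci @ (x - mu)
    return out


def random_class_tree(n_tips, k, seed):
    """Random ultrametric tree with random branch classes."""
    tree = ev.simulate_tree(n_tips, topology="random", seed=seed)
    classes = ev.random_assignment(tree, k=min(k, tree.n_branches), seed=seed + 1)
    return tree.with_rate_classes(classes)
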