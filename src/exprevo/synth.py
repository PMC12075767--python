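"""Synthetic multi-species multi-tissue expression studies.

The generator is the statistical inverse of the analysis: per orthogroup a
baseline log2(TPM + 1) value evolves along an ultrametric species tree by
Gaussian Brownian motion with branch-class rates; tissues share that baseline
except for planted tissue-specific offsets and lineage-restricted shifts;
replicates add Gaussian noise on the log scale (multiplicative on TPM).
Ground truth — the generating rates, the planted specific sets, and the true
value at every internal node — is returned alongside the data so every stage
of the analysis has something to recover.

The default study shape mirrors the system the package targets: 12 marine
caenogastropod species spanning venom glands (the four Conus species), glands
of Leiblein, simple esophageal glands and one glandless lineage, with about
three replicates per tissue and ~2,600 orthogroups complete across species.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (ExpressionMatrix, OrthogroupMap, ValidationError,
                 write_expression, write_flags, write_og_map)
from .tree import SpeciesTree

__all__ = [
    "SimConfig", "Shift", "SimResult", "simulate_tree", "simulate_bm_traits",
    "simulate_expression", "write_study",
    "STUDY_SPECIES", "CONUS_SPECIES", "LEG_SPECIES", "OEG_SPECIES",
    "GLANDLESS_SPECIES", "GLAND_TYPE", "two_class_map", "three_class_map",
]

# 12-species study layout: species codes, their gland types, and a topology
# with the venomous cone-snail clade monophyletic and sister to the glandless
# Mitra lineage, muricids together, and the two outgroups branching first.
OEG_SPECIES = ["MPI", "PMA"]                       # simple esophageal gland
LEG_SPECIES = ["NSE", "MTE", "PSE", "OAM", "VTU"]  # gland of Leiblein
GLANDLESS_SPECIES = ["MMI"]                        # no mid-esophageal gland
CONUS_SPECIES = ["CIM", "CMA", "CVI", "CQU"]       # venom gland
STUDY_SPECIES = OEG_SPECIES + LEG_SPECIES + GLANDLESS_SPECIES + CONUS_SPECIES

GLAND_TYPE = {**{s: "OEG" for s in OEG_SPECIES},
              **{s: "LEG" for s in LEG_SPECIES},
              **{s: "glandless" for s in GLANDLESS_SPECIES},
              **{s: "VG" for s in CONUS_SPECIES}}

_STUDY_TOPOLOGY = (
    "(MPI,(PMA,(((NSE,MTE),(PSE,(OAM,VTU))),(MMI,((CIM,CMA),(CVI,CQU))))));"
)


def two_class_map() -> dict[int, list[list[str]]]:
    """Venomous-clade vs background branch classes (class 1 = Conus clade)."""
    return {1: [list(CONUS_SPECIES)]}


def three_class_map() -> dict[int, list[list[str]]]:
    """Gland-type branch classes: 0 = OEG + glandless background,
    1 = gland-of-Leiblein clade, 2 = venomous clade."""
    return {1: [list(LEG_SPECIES)], 2: [list(CONUS_SPECIES)]}


def simulate_tree(n_species: int = 12, depth: float = 1.0,
                  topology: str = "study", seed: int = 0) -> SpeciesTree:
    """Ultrametric species tree with the study's fixed 12-species branching
    order (``topology="study"``, equal node-depth spacing) or a random
    coalescent-style topology."""
    if n_species < 4:
        raise ValidationError("need at least 4 species")
    if topology == "study":
        if n_species != 12:
            raise ValidationError("the fixed study topology has exactly 12 species")
        tree = SpeciesTree.from_newick(_STUDY_TOPOLOGY, validate=False)
        # node height proportional to the number of branching levels below it
        levels = np.zeros(tree.n_nodes, dtype=int)
        for i in range(tree.n_nodes):
            if not tree.is_tip[i]:
                levels[i] = 1 + max(levels[c] for c in tree.children[i])
        top = levels[tree.root]
        for i in range(tree.n_nodes - 1):
            tree.length[i] = depth * (levels[tree.parent[i]] - levels[i]) / top
        return SpeciesTree(tree.parent, tree.length, tree.rate_class,
                           tree.children, tree.labels)
    if topology != "random":
        raise ValidationError(f"unknown topology {topology!r}")
    rng = np.random.default_rng(seed)
    heights = np.sort(rng.uniform(0.05 * depth, depth, n_species - 1))
    heights[-1] = depth
    subtrees = [(f"sp{i + 1:02d}", 0.0) for i in range(n_species)]
    for h in heights:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        (na, ha), (nb, hb) = subtrees[i], subtrees[j]
        merged = (f"({na}:{h - ha:.10g},{nb}:{h - hb:.10g})", h)
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)] + [merged]
    return SpeciesTree.from_newick(subtrees[0][0] + ";")


def simulate_bm_traits(tree: SpeciesTree, n_ogs: int,
                       sigma2_by_class: Mapping[int, float],
                       root_mean: float = 5.0, root_sd: float = 2.0,
                       seed: int | np.random.Generator = 0):
    """Simulate ``n_ogs`` independent BM traits on the tree.

    Branch variance is sigma2[class] × length.  Returns ``(traits, nodes)``:
    a tip table (OG × species) and the full node × OG value matrix (original
    node ids, root included).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    need = set(int(c) for i, c in enumerate(tree.rate_class) if i != tree.root)
    lacking = need - set(int(k) for k in sigma2_by_class)
    if lacking:
        raise ValidationError(
            f"no sigma2 given for tree rate classes {sorted(lacking)}")
    sig = np.array([float(sigma2_by_class.get(int(c), 1.0))
                    for c in tree.rate_class])
    n = tree.n_nodes
    vals = np.empty((n, n_ogs))
    vals[tree.root] = root_mean + root_sd * rng.standard_normal(n_ogs)
    for i in range(n - 2, -1, -1):  # pre-order
        sd = np.sqrt(sig[i] * tree.length[i])
        vals[i] = vals[tree.parent[i]] + sd * rng.standard_normal(n_ogs)
    og_ids = [f"OG{i:05d}" for i in range(n_ogs)]
    tips = pd.DataFrame(
        {tree.labels[t]: vals[t] for t in tree.tip_ids}, index=og_ids)
    nodes = pd.DataFrame(vals, index=range(n), columns=og_ids)
    return tips, nodes


@dataclass
class Shift:
    """Lineage-restricted expression shift (a node-level gain or loss).

    Applied to the MRCA of ``tips`` and everything below it, in ``tissue``,
    for the orthogroups named in ``ogs`` — either explicit OG ids or the
    string ``"specific:<tissue>"`` to target that tissue's planted set.
    """

    tips: Sequence[str]
    tissue: str
    delta: float
    ogs: Sequence[str] | str = ()


@dataclass
class SimConfig:
    """Study-level generator settings (defaults are the study conditions)."""

    n_species: int = 12
    tissues: Sequence[str] = ("gland", "esophagus", "salivary")
    n_replicates: int = 3
    n_ogs: int = 2588
    frac_multi_member: float = 0.5
    rate_classes: Mapping[int, float] = field(default_factory=lambda: {0: 1.0})
    root_mean: float = 5.0
    root_sd: float = 2.0
    replicate_noise_sd: float = 0.25
    frac_tissue_specific: float | Mapping[str, float] = 0.04
    specific_effect: float = 3.0
    paralog_sd: float = 0.5
    frac_secreted: float = 0.15
    seed: int = 0
    shifts: Sequence[Shift] = ()
    missing: Sequence[tuple[str, str]] = ()  # (species, tissue) pairs absent

    def __post_init__(self):
        fracs = [self.frac_multi_member, self.frac_secreted]
        if isinstance(self.frac_tissue_specific, Mapping):
            fracs += list(self.frac_tissue_specific.values())
        else:
            fracs.append(self.frac_tissue_specific)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValidationError("fractions must lie in [0, 1]")
        if any(s <= 0 for s in self.rate_classes.values()):
            raise ValidationError("sigma2 must be positive")
        if self.n_replicates < 1:
            raise ValidationError("need at least 1 replicate")
        if self.replicate_noise_sd < 0 or self.root_sd < 0:
            raise ValidationError("standard deviations must be non-negative")

    def frac_specific(self, tissue: str) -> float:
        if isinstance(self.frac_tissue_specific, Mapping):
            return float(self.frac_tissue_specific.get(tissue, 0.0))
        return float(self.frac_tissue_specific)


@dataclass
class SimResult:
    """A complete synthetic study plus its ground truth."""

    tree: SpeciesTree
    config: SimConfig
    expressions: dict[str, ExpressionMatrix]       # species -> matrix
    og_map: OrthogroupMap
    flags: dict[str, pd.DataFrame]                 # species -> annotation flags
    true_sigma2: dict[int, float]
    true_specific: dict[str, set[str]]             # tissue -> planted OG ids
    true_ancestral: dict[str, pd.DataFrame]        # tissue -> node x OG values
    true_tips: dict[str, pd.DataFrame]             # tissue -> OG x species values


def simulate_expression(tree: SpeciesTree, config: SimConfig) -> SimResult:
    """Generate a full synthetic study on ``tree`` under ``config``.

    See the module docstring for the generative model.  OG ids are assigned
    in order, with the planted tissue-specific sets occupying leading blocks
    (recorded in the returned truth either way).
    """
    if tree.n_tips != config.n_species:
        raise ValidationError(
            f"tree has {tree.n_tips} tips but config.n_species={config.n_species}")
    rng = np.random.default_rng(config.seed)
    species = tree.tip_labels
    og_ids = [f"OG{i:05d}" for i in range(config.n_ogs)]

    # planted tissue-specific sets: disjoint leading blocks of the OG list
    true_specific: dict[str, set[str]] = {}
    pos = 0
    for tissue in config.tissues:
        n_spec = int(round(config.frac_specific(tissue) * config.n_ogs))
        true_specific[tissue] = set(og_ids[pos:pos + n_spec])
        pos += n_spec
    if pos > config.n_ogs:
        raise ValidationError("tissue-specific fractions exceed the OG budget")

    # baseline BM shared across tissues
    tips, nodes = simulate_bm_traits(
        tree, config.n_ogs, config.rate_classes,
        root_mean=config.root_mean, root_sd=config.root_sd, seed=rng)

    # per-tissue node-value matrices = baseline + planted structure
    node_vals = {t: nodes.copy() for t in config.tissues}
    for tissue in config.tissues:
        ogs = sorted(true_specific[tissue])
        if ogs:
            node_vals[tissue].loc[:, ogs] += config.specific_effect
    for shift in config.shifts:
        if shift.tissue not in node_vals:
            raise ValidationError(f"shift tissue {shift.tissue!r} not simulated")
        if isinstance(shift.ogs, str):
            if not shift.ogs.startswith("specific:"):
                raise ValidationError(f"bad shift og spec {shift.ogs!r}")
            ogs = sorted(true_specific[shift.ogs.split(":", 1)[1]])
        else:
            ogs = sorted(shift.ogs)
        clade = tree.clade(tree.mrca(shift.tips))
        node_vals[shift.tissue].loc[clade, ogs] += shift.delta

    # multi-member OGs: a correlated paralog per species, same offset across tissues
    multi = rng.random(config.n_ogs) < config.frac_multi_member
    paralog_offset = {sp: config.paralog_sd * rng.standard_normal(config.n_ogs)
                      for sp in species}

    expressions: dict[str, ExpressionMatrix] = {}
    flags: dict[str, pd.DataFrame] = {}
    og_rows = []
    missing = set(map(tuple, config.missing))
    secreted_og = rng.random(config.n_ogs) < config.frac_secreted
    gland_like = next((t for t in config.tissues if "gland" in t or t == "VG"),
                      config.tissues[0])

    for sp in species:
        t_id = tree.tip_index(sp)
        gene1 = [f"{sp}_{og}" for og in og_ids]
        gene2 = [f"{sp}_{og}_p2" for og in og_ids]
        genes, rows, meta_rows = [], [], []
        sample_cols: dict[str, np.ndarray] = {}
        tissues_here = [t for t in config.tissues if (sp, t) not in missing]
        if not tissues_here:
            raise ValidationError(f"species {sp} has no tissues left")
        base = {t: node_vals[t].loc[t_id].to_numpy() for t in tissues_here}
        for t in tissues_here:
            for r in range(1, config.n_replicates + 1):
                sid = f"{sp}_{t}_r{r}"
                noise = config.replicate_noise_sd * rng.standard_normal(config.n_ogs)
                v1 = base[t] + noise
                sample_cols.setdefault(sid, [])
                sample_cols[sid] = (v1, t, r)
                meta_rows.append({"sample_id": sid, "species": sp,
                                  "tissue": t, "replicate": r})
        # assemble gene rows: representative gene, plus paralog for multi OGs
        val_matrix = []
        for sid, (v1, t, r) in sample_cols.items():
            val_matrix.append(v1)
        val_matrix = np.array(val_matrix).T  # og x sample (log scale)
        tpm1 = np.clip(np.exp2(val_matrix) - 1.0, 0.0, None)
        frames = [pd.DataFrame(tpm1, index=gene1, columns=list(sample_cols))]
        if multi.any():
            off = paralog_offset[sp][multi]
            tpm2 = np.clip(np.exp2(val_matrix[multi] + off[:, None]) - 1.0, 0.0, None)
            frames.append(pd.DataFrame(
                tpm2, index=[g for g, m in zip(gene2, multi) if m],
                columns=list(sample_cols)))
        values = pd.concat(frames)
        meta = pd.DataFrame(meta_rows).set_index("sample_id")
        expressions[sp] = ExpressionMatrix(values, meta)
        for og, g1, g2, m in zip(og_ids, gene1, gene2, multi):
            og_rows.append({"og_id": og, "species": sp, "gene_id": g1})
            if m:
                og_rows.append({"og_id": og, "species": sp, "gene_id": g2})
        sec = np.concatenate([secreted_og, secreted_og[multi]])
        in_gland_set = np.array([og in true_specific.get(gland_like, set())
                                 for og in og_ids])
        tox = np.concatenate([in_gland_set, in_gland_set[multi]]) & sec
        flags[sp] = pd.DataFrame({"secreted": sec, "toxin_like": tox},
                                 index=values.index).rename_axis("gene_id")

    og_map = OrthogroupMap(pd.DataFrame(og_rows))
    true_anc = {t: node_vals[t].loc[[i for i in range(tree.n_nodes)
                                     if not tree.is_tip[i]]]
                for t in config.tissues}
    true_tip = {t: pd.DataFrame({tree.labels[i]: node_vals[t].loc[i]
                                 for i in tree.tip_ids})
                for t in config.tissues}
    return SimResult(tree=tree, config=config, expressions=expressions,
                     og_map=og_map, flags=flags,
                     true_sigma2=dict(config.rate_classes),
                     true_specific=true_specific, true_ancestral=true_anc,
                     true_tips=true_tip)


def write_study(sim: SimResult, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write every study input (and a ``truth/`` directory) as TSV/Newick."""
    out = {}
    os.makedirs(out_dir, exist_ok=True)
    truth_dir = os.path.join(out_dir, "truth")
    os.makedirs(truth_dir, exist_ok=True)
    tree_path = os.path.join(out_dir, "species_tree.nwk")
    sim.tree.to_newick(tree_path)
    out["tree"] = tree_path
    for sp, expr in sim.expressions.items():
        mp = os.path.join(out_dir, f"{sp}_tpm.tsv")
        mm = os.path.join(out_dir, f"{sp}_samples.tsv")
        write_expression(expr, mp, mm)
        write_flags(sim.flags[sp], os.path.join(out_dir, f"{sp}_flags.tsv"))
        out[f"expr:{sp}"] = mp
    ogp = os.path.join(out_dir, "orthogroups.tsv")
    write_og_map(sim.og_map, ogp)
    out["og_map"] = ogp
    pd.Series(sim.true_sigma2, name="sigma2").rename_axis("rate_class").to_csv(
        os.path.join(truth_dir, "true_sigma2.tsv"), sep="\t")
    rows = [{"tissue": t, "og_id": og}
            for t, ogs in sim.true_specific.items() for og in sorted(ogs)]
    pd.DataFrame(rows, columns=["tissue", "og_id"]).to_csv(
        os.path.join(truth_dir, "true_sets.tsv"), sep="\t", index=False)
    for t, anc in sim.true_ancestral.items():
        anc.rename_axis("node_id").to_csv(
            os.path.join(truth_dir, f"true_ancestral_{t}.tsv"), sep="\t")
    return out
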