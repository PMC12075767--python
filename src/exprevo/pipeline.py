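"""End-to-end orchestration: simulate or load → specificity → orthogroup
matrix → similarity → rate models → ancestral reconstruction → node changes.

A single YAML config drives the run; every stage's outputs and seeds are
recorded in a JSON run manifest so that re-running an identical config
reproduces identical outputs for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict

import pandas as pd
import yaml

from . import __version__
from .evolution import (ancestral_specificity, ancestral_states, compare_models,
                        fit_rate_model, node_changes, random_assignment,
                        trait_table)
from .io import ValidationError, read_expression, read_og_map, read_tree
from .orthomatrix import build_og_matrix, lift_calls_to_ogs, og_specific_sets
from .similarity import correlation_matrix, expression_distance, nj_tree
from .specificity import classify_specific, tissue_means
from .synth import Shift, SimConfig, simulate_expression, simulate_tree, write_study

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _load_config(config_path: str) -> dict:
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a YAML mapping")
    return cfg


def _preflight(cfg: dict) -> None:
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ValidationError("config needs a 'simulate' or an 'inputs' block")
    if "inputs" in cfg:
        inputs = cfg["inputs"]
        for key in ("tree", "og_map", "expressions"):
            if key not in inputs:
                raise ValidationError(f"missing input: {key!r}")
        paths = [inputs["tree"], inputs["og_map"]]
        paths += [p for sp in inputs["expressions"].values() for p in
                  (sp["matrix"], sp["metadata"])]
        missing = [p for p in paths if not os.path.exists(p)]
        if missing:
            raise ValidationError(f"input files not found: {missing}")


def run_pipeline(config_path: str, out_dir: str | None = None) -> dict:
    """Run the full analysis from a YAML config; returns the run manifest.

    Stages execute in dependency order; the first failure halts the run with
    a diagnostic naming the stage, and earlier outputs are retained.
    """
    cfg = _load_config(config_path)
    _preflight(cfg)
    out_dir = out_dir or cfg.get("out_dir", "exprevo_run")
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": cfg,
        "config_digest": _digest(config_path),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "seeds": {},
    }

    def record(stage: str, status: str, outputs: dict | None = None):
        manifest["stages"][stage] = {"status": status, "outputs": outputs or {}}
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    def run_stage(stage: str, fn):
        try:
            outputs = fn()
            record(stage, "ok", outputs)
            return outputs
        except Exception as exc:
            record(stage, f"failed: {exc}")
            raise PipelineError(stage, str(exc)) from exc

    state: dict = {}

    def stage_data():
        if "simulate" in cfg:
            sc = dict(cfg["simulate"])
            shifts = [Shift(**s) for s in sc.pop("shifts", [])]
            tree_cfg = {k: sc.pop(k) for k in ("topology", "depth") if k in sc}
            class_map = sc.pop("class_map", None)
            config = SimConfig(**sc, shifts=shifts)
            manifest["seeds"]["simulate"] = config.seed
            tree = simulate_tree(config.n_species, seed=config.seed, **tree_cfg)
            if class_map:
                tree.apply_class_map({int(k): v for k, v in class_map.items()})
            sim = simulate_expression(tree, config)
            paths = write_study(sim, os.path.join(out_dir, "data"))
            state.update(tree=tree, expressions=sim.expressions,
                         og_map=sim.og_map, sim=sim)
            return {k: str(v) for k, v in paths.items()}
        inputs = cfg["inputs"]
        state["tree"] = read_tree(inputs["tree"], inputs.get("class_map"))
        state["og_map"] = read_og_map(inputs["og_map"])
        state["expressions"] = {
            sp: read_expression(v["matrix"], v["metadata"])
            for sp, v in inputs["expressions"].items()}
        return {"inputs": {k: _digest(v) for k, v in
                           {"tree": inputs["tree"], "og_map": inputs["og_map"]}.items()}}

    run_stage("data", stage_data)

    def stage_specificity():
        pcfg = cfg.get("specificity", {})
        tpm_min = pcfg.get("tpm_min", 2.0)
        fc_min = pcfg.get("fc_min", 2.0)
        profiles, calls = {}, {}
        for sp, expr in state["expressions"].items():
            prof = tissue_means(expr, sp)
            profiles[sp] = prof
            calls[sp] = classify_specific(prof, tpm_min=tpm_min, fc_min=fc_min)
        state.update(profiles=profiles, calls=calls)
        path = os.path.join(out_dir, "specificity_calls.tsv")
        pd.concat({sp: c for sp, c in calls.items()}, names=["species", "gene_id"]
                  ).to_csv(path, sep="\t")
        return {"calls": path}

    run_stage("specificity", stage_specificity)

    def stage_og_matrix():
        pcfg = cfg.get("og_matrix", {})
        seed = pcfg.get("seed", 0)
        manifest["seeds"]["og_matrix"] = seed
        ogmat = build_og_matrix(state["og_map"], state["profiles"],
                                method=pcfg.get("method", "random"), seed=seed)
        votes = lift_calls_to_ogs(state["og_map"], state["calls"])
        sets = og_specific_sets(votes, min_species=pcfg.get("min_species", 2))
        state.update(ogmat=ogmat, og_sets=sets)
        mpath = os.path.join(out_dir, "og_matrix.tsv")
        ogmat.flat().rename_axis("og_id").to_csv(mpath, sep="\t")
        ppath = os.path.join(out_dir, "og_matrix_provenance.tsv")
        ogmat.provenance.rename_axis("og_id").to_csv(ppath, sep="\t")
        spath = os.path.join(out_dir, "og_specific_sets.tsv")
        rows = [{"tissue": t, "og_id": og, "n_species": s.support[og]}
                for t, s in sets.items() for og in sorted(s.og_ids)]
        pd.DataFrame(rows, columns=["tissue", "og_id", "n_species"]).to_csv(
            spath, sep="\t", index=False)
        return {"matrix": mpath, "provenance": ppath, "sets": spath}

    run_stage("og_matrix", stage_og_matrix)

    def stage_similarity():
        pcfg = cfg.get("similarity", {})
        method = pcfg.get("method", "spearman")
        corr = correlation_matrix(state["ogmat"], method=method)
        dist = expression_distance(corr)
        dpath = os.path.join(out_dir, "expression_distance.tsv")
        dist.to_frame().to_csv(dpath, sep="\t")
        tpath = os.path.join(out_dir, "expression_tree.nwk")
        if not dist.has_missing and len(dist.labels) >= 4:
            with open(tpath, "w") as fh:
                fh.write(nj_tree(dist).newick() + "\n")
        return {"distance": dpath, "tree": tpath}

    run_stage("similarity", stage_similarity)

    def stage_evolution():
        pcfg = cfg.get("evolution", {})
        tissue = pcfg.get("tissue", "gland")
        seed = pcfg.get("seed", 7)
        manifest["seeds"]["evolution"] = seed
        tree = state["tree"]
        traits = trait_table(state["ogmat"], tissue)
        wanted = pcfg.get("models", ["m1", "m2", "m3", "random"])
        class_maps = {
            "m2": pcfg.get("m2_classes"), "m3": pcfg.get("m3_classes")}
        fitted = []
        for name in wanted:
            if name == "m1":
                fitted.append(fit_rate_model(
                    tree, traits, assignment=[0] * tree.n_nodes, name="m1"))
            elif name in ("m2", "m3"):
                cm = class_maps[name]
                if cm is None:
                    raise ValidationError(f"model {name} needs a '{name}_classes' map")
                fitted.append(fit_rate_model(
                    tree, traits,
                    assignment={int(k): v for k, v in cm.items()}, name=name))
            elif name == "random":
                assign = random_assignment(tree, k=pcfg.get("random_k", 3), seed=seed)
                fitted.append(fit_rate_model(tree, traits, assignment=assign,
                                             name="random"))
            else:
                raise ValidationError(f"unknown model {name!r}")
        table = compare_models(fitted)
        path = os.path.join(out_dir, "model_table.tsv")
        table.to_csv(path, sep="\t", index=False)
        best_name = table.loc[table["best"], "model"].iloc[0]
        state["best_model"] = next(m for m in fitted if m.name == best_name)
        state["evo_tissue"] = tissue
        return {"model_table": path, "best": best_name}

    if "evolution" in cfg:
        run_stage("evolution", stage_evolution)

        def stage_ancestral():
            best = state["best_model"]
            anc = best.ancestral_states()
            state["ancestral"] = anc
            path = os.path.join(out_dir, f"ancestral_{state['evo_tissue']}.tsv")
            anc.values.rename_axis("node_id").to_csv(path, sep="\t")
            changes = []
            for tissue, s in state["og_sets"].items():
                changes.append(node_changes(anc, state["tree"], s))
            cpath = os.path.join(out_dir, "node_changes.tsv")
            if changes:
                pd.concat(changes, ignore_index=True).to_csv(cpath, sep="\t",
                                                             index=False)
            return {"ancestral": path, "node_changes": cpath}

        run_stage("ancestral", stage_ancestral)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    record("done", "ok", {})
    return manifest
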