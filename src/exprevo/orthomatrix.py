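"""Cross-species orthogroup expression matrices and tissue-specific OG sets.

Orthogroups (OGs) are one-to-many: a species may contribute several member
genes.  The multispecies matrix is restricted to OGs complete across the
included species, with each OG × species cell filled either from one randomly
chosen representative gene (reproducible under a seed, independent of input
file order) or from the mean over all members.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OrthogroupMap, ValidationError
from .specificity import NONE_LABEL

__all__ = ["OGExpressionMatrix", "OGSpecificitySet", "build_og_matrix",
           "lift_calls_to_ogs", "og_specific_sets", "shared_specificity"]

log = logging.getLogger(__name__)


@dataclass
class OGExpressionMatrix:
    """OG × (species, tissue) TPM matrix.

    ``values`` has a two-level column index (species, tissue); ``provenance``
    records, per OG × species, the representative gene id used (or ``"mean"``).
    """

    values: pd.DataFrame
    provenance: pd.DataFrame
    method: str = "random"
    seed: int | None = None

    def __post_init__(self):
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValidationError("negative TPM in orthogroup matrix")

    @property
    def og_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def species(self) -> list[str]:
        return sorted(self.values.columns.get_level_values(0).unique())

    def flat(self) -> pd.DataFrame:
        """Columns flattened to ``species.tissue`` strings (the TSV layout)."""
        out = self.values.copy()
        out.columns = [f"{s}.{t}" for s, t in out.columns]
        return out

    @classmethod
    def from_flat(cls, df: pd.DataFrame, method: str = "unknown") -> "OGExpressionMatrix":
        cols = pd.MultiIndex.from_tuples([tuple(c.split(".", 1)) for c in df.columns],
                                         names=["species", "tissue"])
        vals = df.copy()
        vals.columns = cols
        prov = pd.DataFrame("unknown", index=df.index,
                            columns=sorted({s for s, _ in cols}))
        return cls(vals, prov, method=method)


@dataclass
class OGSpecificitySet:
    """OGs specific to one tissue in at least ``min_species`` species."""

    tissue: str
    og_ids: set[str]
    support: dict[str, int] = field(default_factory=dict)  # og -> n supporting species

    def __len__(self) -> int:
        return len(self.og_ids)


def _representative(seed: int, og_id: str, species: str, members: list[str]) -> str:
    """Deterministic seeded draw from the sorted member list, keyed on
    (seed, og, species) so the choice is independent of input file order."""
    key = f"{seed}:{og_id}:{species}".encode()
    digest = hashlib.sha256(key).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
    members = sorted(members)
    return members[int(rng.integers(len(members)))]


def build_og_matrix(og_map: OrthogroupMap, profiles: dict[str, pd.DataFrame],
                    method: str = "random", seed: int = 0) -> OGExpressionMatrix:
    """Build the OG × (species, tissue) matrix from per-species tissue profiles.

    ``profiles`` maps species → gene × tissue mean-TPM DataFrame (from
    :func:`exprevo.specificity.tissue_means`).  Only OGs with at least one
    member present in every included species' profile are kept; excluded OGs
    are logged.  ``method="random"`` picks one representative gene per
    OG × species; ``method="mean"`` averages all members per tissue.
    """
    if method not in ("random", "mean"):
        raise ValidationError(f"unknown method {method!r}")
    species = sorted(profiles)
    members_by_og = og_map.members_by_og()
    rows, prov_rows, kept = [], [], []
    for og in sorted(members_by_og):
        members = members_by_og[og]
        resolved = {}
        for sp in species:
            genes = [g for g in members.get(sp, []) if g in profiles[sp].index]
            if not genes:
                break
            resolved[sp] = sorted(genes)
        if len(resolved) < len(species):
            log.info("orthogroup %s excluded: no member in species %s", og, sp)
            continue
        row, prow = {}, {}
        for sp in species:
            prof = profiles[sp]
            if method == "random":
                rep = _representative(seed, og, sp, resolved[sp])
                vals = prof.loc[rep]
                prow[sp] = rep
            else:
                vals = prof.loc[resolved[sp]].mean(axis=0)
                prow[sp] = "mean"
            for tissue, v in vals.items():
                row[(sp, tissue)] = float(v)
        rows.append(row)
        prov_rows.append(prow)
        kept.append(og)
    values = pd.DataFrame(rows, index=kept)
    values.columns = pd.MultiIndex.from_tuples(values.columns, names=["species", "tissue"])
    values = values.sort_index(axis=1)
    provenance = pd.DataFrame(prov_rows, index=kept)
    return OGExpressionMatrix(values, provenance, method=method,
                              seed=seed if method == "random" else None)


def lift_calls_to_ogs(og_map: OrthogroupMap,
                      calls_by_species: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Lift gene-level specificity calls to OG-level species votes.

    A species votes for a tissue in an OG when at least one member gene of
    that OG is specific to the tissue.  Returns a long DataFrame with columns
    ``og_id``, ``species``, ``tissue``; several rows per (og, species) mean an
    intra-species conflict (members specific to different tissues), which is
    logged and kept.
    """
    votes = []
    tbl = og_map.table
    for sp, calls in sorted(calls_by_species.items()):
        spec = calls[calls["assigned_tissue"] != NONE_LABEL]["assigned_tissue"]
        sub = tbl[tbl["species"] == sp]
        merged = sub.merge(spec.rename("tissue"), left_on="gene_id", right_index=True)
        v = merged[["og_id", "tissue"]].drop_duplicates()
        conflicts = v["og_id"].value_counts()
        for og in conflicts[conflicts > 1].index:
            log.info("species %s votes for several tissues in %s: %s", sp, og,
                     sorted(v.loc[v.og_id == og, "tissue"]))
        v = v.assign(species=sp)
        votes.append(v)
    if not votes:
        return pd.DataFrame(columns=["og_id", "species", "tissue"])
    return pd.concat(votes, ignore_index=True)[["og_id", "species", "tissue"]]


def og_specific_sets(votes: pd.DataFrame, min_species: int = 2) -> dict[str, OGSpecificitySet]:
    """Cross-species tissue-specific OG sets from the vote table.

    An OG joins a tissue's set when at least ``min_species`` species voted for
    that tissue.  An OG can enter several tissues' sets through different
    species' votes; such conflicts are logged.
    """
    sets: dict[str, OGSpecificitySet] = {}
    if len(votes) == 0:
        return sets
    counts = votes.groupby(["tissue", "og_id"])["species"].nunique()
    for (tissue, og), n in counts.items():
        if n >= min_species:
            s = sets.setdefault(tissue, OGSpecificitySet(tissue, set(), {}))
            s.og_ids.add(og)
            s.support[og] = int(n)
    seen: dict[str, list[str]] = {}
    for tissue, s in sets.items():
        for og in s.og_ids:
            seen.setdefault(og, []).append(tissue)
    for og, tissues in seen.items():
        if len(tissues) > 1:
            log.info("orthogroup %s is specific to several tissues: %s", og, sorted(tissues))
    return sets


def shared_specificity(sets_by_species: dict[str, set[str]],
                       grouping: dict[str, str]) -> pd.DataFrame:
    """Mean ± SD of pairwise shared gland-specific OG counts between species groups.

    ``sets_by_species`` maps species → set of gland-specific OG ids;
    ``grouping`` maps species → gland-type group.  For every ordered group
    pair the mean and SD over all between-species pairwise intersection sizes
    are reported; within a group, unordered distinct pairs are used.  A single
    pair reports SD 0.
    """
    groups: dict[str, list[str]] = {}
    for sp in sorted(sets_by_species):
        if sp not in grouping:
            raise ValidationError(f"species {sp!r} missing from grouping")
        groups.setdefault(grouping[sp], []).append(sp)
    rows = []
    for ga in sorted(groups):
        for gb in sorted(groups):
            if ga == gb:
                pairs = [(a, b) for i, a in enumerate(groups[ga])
                         for b in groups[ga][i + 1:]]
            else:
                pairs = [(a, b) for a in groups[ga] for b in groups[gb]]
            if not pairs:
                continue
            shared = [len(sets_by_species[a] & sets_by_species[b]) for a, b in pairs]
            sd = float(np.std(shared, ddof=1)) if len(shared) > 1 else 0.0
            rows.append({"group_a": ga, "group_b": gb, "n_pairs": len(pairs),
                         "mean_shared": float(np.mean(shared)), "sd_shared": sd})
    return pd.DataFrame(rows)
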