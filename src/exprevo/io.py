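"""Readers, writers and validated containers for the on-disk formats.

All tabular formats are plain TSV:

* expression matrix — first column ``gene_id``, remaining columns sample ids,
  values TPM (accepted as-is, never re-normalized);
* sample metadata — columns ``sample_id``, ``species``, ``tissue``,
  ``replicate``;
* annotation flags — ``gene_id``, ``secreted``, ``toxin_like`` with 0/1 values;
* orthogroup map — long format ``og_id``, ``species``, ``gene_id``.

Trees are Newick (see :mod:`exprevo.tree`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import SpeciesTree, TreeError, read_class_map

__all__ = [
    "ValidationError", "ExpressionMatrix", "OrthogroupMap",
    "read_expression", "write_expression", "read_flags", "write_flags",
    "read_og_map", "write_og_map", "read_tree",
    "SpeciesTree", "TreeError", "read_class_map", "DEFAULT_TISSUES",
]

#: Controlled tissue vocabulary.  The study's organ codes (venom gland VG,
#: esophageal gland OEG, gland of Leiblein LEG, salivary gland SG, esophagus E,
#: foot/columellar muscle F and CM, muscular bulb MB, glandular folds GF) plus
#: the unified organ-type names the synthetic generator uses.
DEFAULT_TISSUES = frozenset({
    "VG", "OEG", "LEG", "SG", "E", "F", "CM", "MB", "GF",
    "gland", "esophagus", "salivary", "foot",
})


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class ExpressionMatrix:
    """Gene × sample TPM matrix with sample metadata.

    ``values`` is a DataFrame indexed by gene id with one column per sample;
    ``samples`` is a DataFrame indexed by sample id with columns ``species``,
    ``tissue`` and ``replicate``.  Values must be finite and non-negative and
    the two tables must describe exactly the same samples.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    tissue_vocabulary: frozenset = field(default=DEFAULT_TISSUES, repr=False)

    def __post_init__(self):
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dup[:5]}")
        arr = v.to_numpy(dtype=float, copy=False)
        if not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains non-finite values")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative TPM at gene {v.index[g]!r}, sample {v.columns[s]!r}")
        meta = self.samples
        for col in ("species", "tissue", "replicate"):
            if col not in meta.columns:
                raise ValidationError(f"metadata misses column {col!r}")
        if meta.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        only_matrix = sorted(set(v.columns) - set(meta.index))
        only_meta = sorted(set(meta.index) - set(v.columns))
        if only_matrix or only_meta:
            raise ValidationError(
                f"sample mismatch: in matrix only {only_matrix}, in metadata only {only_meta}")
        bad = sorted(set(meta["tissue"]) - self.tissue_vocabulary)
        if bad:
            raise ValidationError(f"tissues outside vocabulary: {bad}")
        if (meta["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate numbers must be positive")
        # align metadata rows to matrix column order
        self.samples = meta.loc[list(v.columns)]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def species(self) -> list[str]:
        return sorted(self.samples["species"].unique())

    def subset_species(self, species: str) -> "ExpressionMatrix":
        keep = self.samples.index[self.samples["species"] == species]
        if len(keep) == 0:
            raise ValidationError(f"species {species!r} has no samples")
        return ExpressionMatrix(self.values[list(keep)], self.samples.loc[list(keep)],
                                self.tissue_vocabulary)


class OrthogroupMap:
    """Orthogroup membership: og_id → species → list of gene ids.

    One-to-many members are allowed; a (species, gene) pair may occur in at
    most one orthogroup.  An orthogroup with at least one member in every
    species of ``species_universe`` is *complete*.
    """

    def __init__(self, table: pd.DataFrame):
        need = {"og_id", "species", "gene_id"}
        if not need <= set(table.columns):
            raise ValidationError(f"orthogroup table needs columns {sorted(need)}")
        table = table[["og_id", "species", "gene_id"]].astype(str)
        dup = table.duplicated(["species", "gene_id"], keep=False)
        if dup.any():
            pairs = table.loc[dup, ["species", "gene_id"]].drop_duplicates()
            clash = pairs.merge(table, on=["species", "gene_id"])
            if clash.groupby(["species", "gene_id"])["og_id"].nunique().gt(1).any():
                raise ValidationError(
                    "a (species, gene) pair occurs in more than one orthogroup")
            table = table.drop_duplicates()
        self.table = table.reset_index(drop=True)

    @property
    def og_ids(self) -> list[str]:
        return sorted(self.table["og_id"].unique())

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())

    def members(self, og_id: str) -> dict[str, list[str]]:
        sub = self.table[self.table["og_id"] == og_id]
        return {sp: sorted(g) for sp, g in sub.groupby("species")["gene_id"]}

    def members_by_og(self) -> dict[str, dict[str, list[str]]]:
        out: dict[str, dict[str, list[str]]] = {}
        for (og, sp), genes in self.table.groupby(["og_id", "species"])["gene_id"]:
            out.setdefault(og, {})[sp] = sorted(genes)
        return out

    def complete_ogs(self, species: list[str] | None = None) -> list[str]:
        species = species if species is not None else self.species
        cov = self.table.groupby("og_id")["species"].agg(lambda s: set(s))
        return sorted(og for og, sp in cov.items() if set(species) <= sp)


# ---------------------------------------------------------------------------
# readers / writers

def read_expression(matrix_path: str | os.PathLike,
                    metadata_path: str | os.PathLike,
                    tissue_vocabulary: frozenset = DEFAULT_TISSUES) -> ExpressionMatrix:
    """Read a TPM matrix TSV plus its sample-metadata TSV into a validated
    :class:`ExpressionMatrix`; mismatched sample sets raise naming the offenders."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise ValidationError("metadata misses column 'sample_id'")
    meta = meta.set_index("sample_id")
    return ExpressionMatrix(values, meta, tissue_vocabulary)


def write_expression(expr: ExpressionMatrix, matrix_path: str | os.PathLike,
                     metadata_path: str | os.PathLike) -> None:
    expr.values.rename_axis("gene_id").to_csv(matrix_path, sep="\t")
    expr.samples.rename_axis("sample_id").to_csv(metadata_path, sep="\t")


def read_flags(path: str | os.PathLike, genes: list[str] | None = None) -> pd.DataFrame:
    """Read per-gene annotation flags (secreted / toxin_like as 0/1).

    If ``genes`` is given, flagged ids that do not resolve against it are
    reported in the frame's ``attrs['unresolved']`` rather than raising.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    need = {"gene_id", "secreted", "toxin_like"}
    if not need <= set(df.columns):
        raise ValidationError(f"flags table needs columns {sorted(need)}")
    df = df.set_index("gene_id")
    df["secreted"] = df["secreted"].astype(int).astype(bool)
    df["toxin_like"] = df["toxin_like"].astype(int).astype(bool)
    df.attrs["unresolved"] = [] if genes is None else sorted(set(df.index) - set(genes))
    return df


def write_flags(flags: pd.DataFrame, path: str | os.PathLike) -> None:
    out = flags[["secreted", "toxin_like"]].astype(int)
    out.rename_axis("gene_id").to_csv(path, sep="\t")


def read_og_map(path: str | os.PathLike) -> OrthogroupMap:
    return OrthogroupMap(pd.read_csv(path, sep="\t", dtype=str))


def write_og_map(og_map: OrthogroupMap, path: str | os.PathLike) -> None:
    og_map.table.to_csv(path, sep="\t", index=False)


def read_tree(newick_path: str | os.PathLike,
              class_map: dict | str | os.PathLike | None = None) -> SpeciesTree:
    """Read a Newick species tree; ``class_map`` may be a mapping, a YAML path,
    or ``"none"`` (all branches class 0).  Ultrametricity is enforced."""
    if isinstance(class_map, (str, os.PathLike)) and class_map != "none" and os.path.exists(os.fspath(class_map)):
        class_map = read_class_map(class_map)
    return SpeciesTree.from_newick(newick_path, class_map=class_map)
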