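"""Within-species tissue-specificity classification and summaries.

A gene is called *specific* to its most highly expressed tissue when the top
tissue's mean TPM is at least ``tpm_min`` and the fold change FC — the ratio
of the top tissue's mean to the second-highest tissue's mean — is at least
``fc_min`` (defaults 2 and 2).  A zero second-highest mean with an expressed
top tissue gives FC = +inf and the gene is specific; an exact tie gives FC = 1
and the gene is unassigned.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, ValidationError

__all__ = [
    "tissue_means", "classify_specific", "count_specific",
    "compare_group_counts", "secretome_summary", "NONE_LABEL",
]

NONE_LABEL = "none"


def tissue_means(expr: ExpressionMatrix, species: str,
                 aggregator: str = "mean") -> pd.DataFrame:
    """Per-gene per-tissue mean TPM over replicates for one species.

    Returns a gene × tissue DataFrame; tissues without samples for this
    species are simply absent (never zero-filled).  ``aggregator`` may be
    ``"mean"`` (default) or ``"median"``.
    """
    if species not in set(expr.samples["species"]):
        raise ValidationError(f"species {species!r} absent from metadata")
    sub = expr.subset_species(species)
    groups = sub.samples.groupby("tissue").groups
    agg = {"mean": np.mean, "median": np.median}[aggregator]
    cols = {t: agg(sub.values[list(ids)].to_numpy(), axis=1) for t, ids in groups.items()}
    return pd.DataFrame(cols, index=sub.values.index).sort_index(axis=1)


def classify_specific(profiles: pd.DataFrame, tpm_min: float = 2.0,
                      fc_min: float = 2.0) -> pd.DataFrame:
    """Apply the top-tissue/fold-change rule to a gene × tissue mean table.

    Returns a DataFrame indexed by gene with columns ``assigned_tissue``
    (tissue label or ``"none"``), ``top_tpm`` and ``fold_change``.
    """
    if profiles.shape[1] < 2:
        raise ValidationError("fold change undefined with fewer than 2 tissues")
    vals = profiles.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValidationError("negative tissue means")
    order = np.argsort(-vals, axis=1, kind="stable")
    top_idx = order[:, 0]
    rows = np.arange(vals.shape[0])
    top = vals[rows, top_idx]
    second = vals[rows, order[:, 1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(second > 0, top / second, np.where(top > 0, np.inf, np.nan))
    ok = (top >= tpm_min) & (fc >= fc_min)
    tissues = np.asarray(profiles.columns, dtype=object)
    assigned = np.where(ok, tissues[top_idx], NONE_LABEL)
    return pd.DataFrame(
        {"assigned_tissue": assigned, "top_tpm": top, "fold_change": fc},
        index=profiles.index,
    )


def count_specific(calls: pd.DataFrame) -> dict[str, int]:
    """Number of specific genes per tissue; unassigned genes are excluded."""
    if len(calls) == 0:
        return {}
    counts = calls.loc[calls["assigned_tissue"] != NONE_LABEL, "assigned_tissue"].value_counts()
    return {t: int(n) for t, n in counts.sort_index().items()}


def compare_group_counts(counts_a, counts_b, alternative: str = "greater",
                         equal_var: bool = False) -> tuple[float, float, float]:
    """One-sided two-sample t-test on per-species gene-set sizes.

    Welch by default (``equal_var=False``); the pooled-variance variant is
    selectable.  Returns ``(t, df, p)`` with the p-value for the stated
    one-sided alternative (default: group A greater).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    return float(res.statistic), float(res.df), float(res.pvalue)


def secretome_summary(profiles: pd.DataFrame, flags: pd.DataFrame,
                      expressed_min_tpm: float = 1.0) -> pd.DataFrame:
    """Per-tissue secretome summary: count and mean TPM of expressed secreted genes.

    ``profiles`` is the gene × tissue mean table of one species, ``flags`` the
    annotation table with a boolean ``secreted`` column.  A secreted gene
    counts as expressed in a tissue when its mean TPM there is at least
    ``expressed_min_tpm``; the reported mean TPM is over those genes.  Tissues
    with no expressed secreted gene report count 0, mean 0 and a warning flag.
    """
    secreted = flags.index[flags["secreted"]].intersection(profiles.index)
    rows = {}
    for tissue in profiles.columns:
        vals = profiles.loc[list(secreted), tissue]
        vals = vals[vals >= expressed_min_tpm]
        n = int(len(vals))
        rows[tissue] = {
            "n_expressed_secreted": n,
            "mean_tpm_secreted": float(vals.mean()) if n else 0.0,
            "no_secreted_warning": n == 0,
        }
    out = pd.DataFrame.from_dict(rows, orient="index").rename_axis("tissue")
    out["n_expressed_secreted"] = out["n_expressed_secreted"].astype(int)
    return out
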