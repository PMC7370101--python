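"""Organ-level expression calling from FPKM tables.

A gene is called expressed in a condition when the log10 of its mean FPKM
across replicates exceeds a threshold (default 0, i.e. mean FPKM strictly
above 1). A zero mean has no logarithm and is reported with a sentinel
display value and called not expressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from aqpkit.io_formats import ExpressionMatrix

__all__ = ["ExpressionCalls", "call_expression", "ubiquitous_set", "heatmap_matrix"]

#: Display floor substituted for log10 of a zero mean.
LOG_SENTINEL = float("-inf")


@dataclass(frozen=True)
class ExpressionCalls:
    """Per (gene, condition) mean FPKM, log10 value and expressed flag."""

    mean_fpkm: pd.DataFrame        # genes x conditions
    log10: pd.DataFrame            # genes x conditions, -inf sentinel for mean 0
    expressed: pd.DataFrame        # genes x conditions, bool
    threshold_log10: float

    @property
    def conditions(self) -> list[str]:
        return list(self.expressed.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.expressed.index)

    def expressed_counts(self) -> dict[str, int]:
        """Number of expressed genes per condition."""
        return {c: int(self.expressed[c].sum()) for c in self.conditions}

    def expressed_set(self, condition: str) -> set[str]:
        if condition not in self.expressed.columns:
            raise KeyError(f"unknown condition {condition!r}")
        col = self.expressed[condition]
        return set(col.index[col])

    def silent_set(self) -> set[str]:
        """Genes expressed in no condition."""
        return set(self.expressed.index[~self.expressed.any(axis=1)])


def call_expression(
    matrix: ExpressionMatrix,
    threshold_log10: float = 0.0,
    aggregate: str = "mean",
) -> ExpressionCalls:
    """Aggregate replicates per condition and apply the strict log threshold.

    ``aggregate`` is ``"mean"`` (default) or ``"median"``. Expression requires
    log10(aggregated FPKM) strictly greater than ``threshold_log10``; a gene
    sitting exactly at FPKM 10**threshold is not expressed.
    """
    if aggregate not in {"mean", "median"}:
        raise ValueError("aggregate must be 'mean' or 'median'")
    conditions = matrix.conditions
    agg = {}
    for cond in conditions:
        samples = matrix.samples_for(cond)
        if not samples:
            raise ValueError(f"condition {cond!r} has no samples")
        block = matrix.values[samples]
        col = block.mean(axis=1) if aggregate == "mean" else block.median(axis=1)
        # equal replicates must aggregate exactly, without summation drift
        equal = block.nunique(axis=1) == 1
        col[equal] = block.iloc[:, 0][equal]
        agg[cond] = col
    mean_fpkm = pd.DataFrame(agg)[conditions]
    with np.errstate(divide="ignore"):
        log10 = pd.DataFrame(
            np.log10(mean_fpkm.to_numpy()),
            index=mean_fpkm.index,
            columns=mean_fpkm.columns,
        )
    expressed = log10 > threshold_log10
    return ExpressionCalls(
        mean_fpkm=mean_fpkm,
        log10=log10,
        expressed=expressed,
        threshold_log10=threshold_log10,
    )


def ubiquitous_set(calls: ExpressionCalls, conditions: Sequence[str] | None = None) -> set[str]:
    """Genes expressed in every one of the named conditions (default: all)."""
    if conditions is None:
        conditions = calls.conditions
    if len(conditions) < 2:
        raise ValueError("ubiquitous set needs at least 2 conditions")
    result: set[str] | None = None
    for cond in conditions:
        genes = calls.expressed_set(cond)
        result = genes if result is None else result & genes
    return result


def heatmap_matrix(
    calls: ExpressionCalls,
    order: str = "input",
    inventory_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Genes x conditions matrix of log10 values for heatmap rendering.

    Sentinel cells (zero mean FPKM) are NA. With ``order="subfamily"`` rows
    follow ``inventory_order`` (e.g. the bundled gene inventory order),
    unknown genes appended in input order.
    """
    if order not in {"input", "subfamily"}:
        raise ValueError("order must be 'input' or 'subfamily'")
    mat = calls.log10.replace(LOG_SENTINEL, np.nan)
    if order == "subfamily":
        if inventory_order is None:
            from aqpkit.io_formats import load_gene_inventory

            inventory_order = [row.gene_name for row in load_gene_inventory()]
        known = [g for g in inventory_order if g in mat.index]
        rest = [g for g in mat.index if g not in set(known)]
        mat = mat.loc[known + rest]
    return mat


def write_heatmap_tsv(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", index_label="gene", na_rep="NA")


def render_heatmap(mat: pd.DataFrame, path) -> None:
    """Optional image render of the heatmap matrix (PNG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4 + 0.3 * mat.shape[1], 2 + 0.12 * mat.shape[0]))
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdYlGn")
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=45, ha="right")
    ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="log10 FPKM")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
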