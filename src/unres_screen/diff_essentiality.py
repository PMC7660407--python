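"""Differential gene essentiality between an index cell line and comparators.

For each comparator the gene-wise difference of gene-effect scores is
standardized to a Z vector (mean 0, sample SD 1 over shared genes); the
per-gene average across comparators is the differential-essentiality score.
Scores above +4 mark genes less essential in the index line; below -4,
uniquely essential.  Genes whose essentiality barely differs from a
wild-type comparator population are classified wt-like.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model_io import EssentialityMatrix
from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "DeltaEssTable",
    "pairwise_z",
    "delta_essentiality",
    "classify_wt_like",
    "highlight_genes",
]

MIN_SHARED_GENES = 100


@dataclass
class DeltaEssTable:
    """Per-gene averaged Z-scores for one index cell line.

    ``delta_ess``: gene-indexed Series of averaged Z-scores; ``k``: per-gene
    count of comparisons with data; ``z_per_comparison``: genes x comparators
    frame of the individual Z vectors; ``wt_like``: optional boolean Series.
    """

    index_cell: str
    delta_ess: pd.Series
    k: pd.Series
    z_per_comparison: pd.DataFrame
    wt_like: pd.Series | None = None

    def frame(self, highlight_threshold: float = 4.0) -> pd.DataFrame:
        """Flat report table: gene, delta_ess, k, z columns, labels."""
        out = pd.DataFrame({"gene": self.delta_ess.index,
                            "delta_ess": self.delta_ess.to_numpy(),
                            "k": self.k.to_numpy()})
        for comp in self.z_per_comparison.columns:
            out[f"z_vs_{comp}"] = self.z_per_comparison[comp].to_numpy()
        if self.wt_like is not None:
            out["wt_like"] = self.wt_like.to_numpy()
        less, unique = highlight_genes(self, threshold=highlight_threshold)
        out["highlight"] = [
            "less_essential" if g in less else "uniquely_essential" if g in unique else ""
            for g in out["gene"]
        ]
        return out


def pairwise_z(
    ess_out: pd.Series, ess_other: pd.Series, min_genes: int = MIN_SHARED_GENES
) -> tuple[pd.Series, bool]:
    """Z-standardized gene-effect differences between two cell lines.

    diff_g = ess_out_g - ess_other_g over genes present in both vectors;
    z_g = (diff_g - mean(diff)) / sd(diff) with the n-1 denominator.
    Returns (z, degenerate); identical profiles up to a constant give a
    zero vector flagged degenerate.
    """
    shared = ess_out.dropna().index.intersection(ess_other.dropna().index)
    if len(shared) < min_genes:
        raise InputError(
            f"only {len(shared)} shared genes; need >= {min_genes}"
        )
    diff = ess_out.loc[shared].astype(float) - ess_other.loc[shared].astype(float)
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        logger.warning("identical profiles up to a constant; z set to zeros")
        return pd.Series(0.0, index=shared), True
    return (diff - diff.mean()) / sd, False


def delta_essentiality(
    ess: EssentialityMatrix,
    index_cell: str,
    comparators: list[str],
    min_genes: int = MIN_SHARED_GENES,
) -> DeltaEssTable:
    """Average the per-comparison Z vectors into the differential score.

    Genes missing in some comparisons are averaged over the comparisons
    where they have data, with the per-gene count recorded.
    """
    if not comparators:
        raise ValueError("need at least one comparator cell line")
    ess_out = ess.profile(index_cell)
    z_cols = {}
    for comp in comparators:
        try:
            z, _ = pairwise_z(ess_out, ess.profile(comp), min_genes=min_genes)
        except InputError as exc:
            raise InputError(f"comparator {comp!r}: {exc}") from exc
        z_cols[comp] = z
    z_frame = pd.DataFrame(z_cols)  # union of gene indices, NaN where absent
    k = z_frame.notna().sum(axis=1)
    delta = z_frame.mean(axis=1, skipna=True)
    return DeltaEssTable(
        index_cell=index_cell,
        delta_ess=delta,
        k=k,
        z_per_comparison=z_frame,
    )


def classify_wt_like(
    delta_vs_sensitive: DeltaEssTable,
    delta_vs_wildtype: DeltaEssTable,
    tau: float,
) -> DeltaEssTable:
    """Label genes whose essentiality matches the wild-type population.

    A gene is wt-like iff |delta_ess vs the wild-type comparators| < tau;
    the label is attached to the sensitive-contrast table (genes absent
    from the wild-type contrast stay unlabeled/NaN).
    """
    if not tau > 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    wt = delta_vs_wildtype.delta_ess.reindex(delta_vs_sensitive.delta_ess.index)
    labels = wt.abs() < tau
    labels[wt.isna()] = pd.NA
    delta_vs_sensitive.wt_like = labels.astype("boolean")
    return delta_vs_sensitive


def highlight_genes(
    table: DeltaEssTable, threshold: float = 4.0
) -> tuple[set[str], set[str]]:
    """(less-essential, uniquely-essential) gene sets at strict |delta| > threshold."""
    d = table.delta_ess.dropna()
    less_essential = set(d.index[d > threshold])
    uniquely_essential = set(d.index[d < -threshold])
    return less_essential, uniquely_essential
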