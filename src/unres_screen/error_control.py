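"""Error control: within-tissue permutation study and hierarchical FDR.

The two-level hierarchy puts sensitivity-association tests at the parent
level (fixed p < 0.001 gate plus the effect-size filter applied upstream)
and UNRES tests at the child level; children are only tested under
significant parents, with one pooled BH pass at level 0.15 and a
closed-form bound on the overall FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model_io import CellAnnotation, CFEMatrix, DrugResponseTable
from .errors import IntegrityError
from .sensitivity_assoc import (
    SensitivityAssociation,
    discover_associations,
    enumerate_candidates,
)
from .unres_detect import UnresCase, adjust_cases, bh_adjust, detect_unres

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisParams",
    "PermutationSummary",
    "HfdrResult",
    "run_discovery_and_unres",
    "permute_within_tissue",
    "hfdr_select",
    "fdr_bound",
]


@dataclass(frozen=True)
class AnalysisParams:
    """Thresholds of the discovery + UNRES workflow (defaults as published)."""

    min_mut: int = 4
    max_extrapolated_frac: float = 0.5
    p_parent: float = 0.001
    d_threshold: float = -1.0
    alpha_child: float = 0.15
    B: int = 10_000
    i_max: int = 5


@dataclass
class PermutationSummary:
    """Replicate-level counts of the permutation study plus aggregates."""

    per_replicate: pd.DataFrame  # replicate, n_sensitivity_associations, ...
    n_perm: int

    @property
    def aggregate(self) -> dict:
        cols = [
            "n_sensitivity_associations",
            "n_assoc_with_unres",
            "max_unres_cells",
        ]
        out: dict = {"n_perm": self.n_perm}
        for col in cols:
            vals = self.per_replicate[col]
            out[col] = {
                "mean": float(vals.mean()),
                "min": int(vals.min()),
                "max": int(vals.max()),
            }
        return out


@dataclass
class HfdrResult:
    significant_parents: list[str]
    significant_children: list[tuple[str, str]]  # (parent, child)
    child_adjusted: dict[tuple[str, str], float]
    n_discoveries: int
    n_families: int
    fdr_bound: float
    tested_children: list[tuple[str, str]] = field(default_factory=list)


def run_discovery_and_unres(
    resp: DrugResponseTable,
    cfe: CFEMatrix,
    ann: CellAnnotation,
    params: AnalysisParams = AnalysisParams(),
    seed: int = 0,
) -> tuple[list[SensitivityAssociation], list[UnresCase]]:
    """Discovery then UNRES detection with the pooled BH pass.

    This is the core workflow shared by the main pipeline and the
    permutation study: enumerate candidates, test them, detect leave-top-i
    cases under each retained association, and BH-adjust all case p-values
    together at ``params.alpha_child``.
    """
    candidates = enumerate_candidates(
        cfe, resp, ann,
        min_mut=params.min_mut,
        max_extrapolated_frac=params.max_extrapolated_frac,
    )
    assocs = discover_associations(
        candidates, resp, ann,
        p_threshold=params.p_parent,
        d_threshold=params.d_threshold,
    )
    cases: list[UnresCase] = []
    for assoc in assocs:
        if assoc.retained:
            cases.extend(
                detect_unres(assoc, resp, ann, B=params.B, seed=seed,
                             i_max=params.i_max)
            )
    cases = adjust_cases(cases, alpha=params.alpha_child)
    return assocs, cases


def _permute_responses(
    resp: DrugResponseTable, ann: CellAnnotation, rng: np.random.Generator
) -> DrugResponseTable:
    """Shuffle ln-IC50s among cell lines independently per (drug, tissue).

    The extrapolated flag (and screened concentration, if present) travels
    with its IC50 value, so count-based filters are recomputed downstream
    on the permuted data.
    """
    df = resp.df.copy()
    tissue = df["cell_line_id"].map(ann.tissue_of())
    moved = ["ln_ic50", "extrapolated"] + (
        ["max_screened_conc"] if "max_screened_conc" in df.columns else []
    )
    for _, idx in df.groupby([df["drug_id"], tissue], sort=True).groups.items():
        idx = np.asarray(idx)
        perm = rng.permutation(len(idx))
        df.loc[idx, moved] = df.loc[idx[perm], moved].to_numpy()
    return DrugResponseTable(df)


def permute_within_tissue(
    resp: DrugResponseTable,
    cfe: CFEMatrix,
    ann: CellAnnotation,
    n_perm: int = 100,
    seed: int = 0,
    params: AnalysisParams = AnalysisParams(),
) -> PermutationSummary:
    """Permutation study: rerun the full workflow on shuffled responses.

    Per replicate we count retained sensitivity associations, how many of
    them carry at least one significant UNRES case, and the largest number
    of removed cell lines in any significant case.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    rows = []
    for r in range(n_perm):
        ss = np.random.SeedSequence(seed, spawn_key=(0xFE, r))
        rng = np.random.default_rng(ss)
        perm_resp = _permute_responses(resp, ann, rng)
        # detection streams get a replicate-specific integer seed
        rep_seed = int(ss.generate_state(1)[0])
        assocs, cases = run_discovery_and_unres(
            perm_resp, cfe, ann, params=params, seed=rep_seed
        )
        sig = [c for c in cases if c.significant]
        assoc_with_unres = {c.association.key for c in sig}
        rows.append(
            {
                "replicate": r,
                "n_sensitivity_associations": sum(a.retained for a in assocs),
                "n_assoc_with_unres": len(assoc_with_unres),
                "max_unres_cells": max((c.i for c in sig), default=0),
            }
        )
    return PermutationSummary(per_replicate=pd.DataFrame(rows), n_perm=n_perm)


def hfdr_select(
    parent_pvalues: Mapping[str, float],
    child_pvalues: Mapping[str, Mapping[str, float]],
    alpha_parent: float = 0.001,
    alpha_child: float = 0.15,
    n_families: int | None = None,
    pooled: bool = True,
    delta: float = 1.0,
) -> HfdrResult:
    """Two-level hierarchical selection.

    Parents pass the fixed threshold ``p < alpha_parent``; the children of
    significant parents are then BH-corrected at ``alpha_child`` — pooled
    into a single pass by default, or per parent family when
    ``pooled=False``.  Children of non-significant parents are never
    tested.
    """
    orphans = set(child_pvalues) - set(parent_pvalues)
    if orphans:
        raise IntegrityError(f"children keyed to unknown parents: {sorted(orphans)[:5]}")

    sig_parents = sorted(p for p, pv in parent_pvalues.items() if pv < alpha_parent)
    tested: list[tuple[str, str]] = []
    pvec: list[float] = []
    for parent in sig_parents:
        for child, pv in child_pvalues.get(parent, {}).items():
            tested.append((parent, child))
            pvec.append(pv)

    child_adjusted: dict[tuple[str, str], float] = {}
    sig_children: list[tuple[str, str]] = []
    if tested:
        if pooled:
            adjusted, flags = bh_adjust(pvec, alpha=alpha_child)
            for key, adj, sig in zip(tested, adjusted, flags):
                child_adjusted[key] = float(adj)
                if sig:
                    sig_children.append(key)
        else:
            for parent in sig_parents:
                fam = [(k, pv) for k, pv in zip(tested, pvec) if k[0] == parent]
                if not fam:
                    continue
                adjusted, flags = bh_adjust([pv for _, pv in fam], alpha=alpha_child)
                for (key, _), adj, sig in zip(fam, adjusted, flags):
                    child_adjusted[key] = float(adj)
                    if sig:
                        sig_children.append(key)

    n_discoveries = len(sig_parents) + len(sig_children)
    if n_families is None:
        n_families = max(len(parent_pvalues), 1)
    bound = fdr_bound(n_discoveries, n_families, alpha=alpha_child, delta=delta)
    return HfdrResult(
        significant_parents=sig_parents,
        significant_children=sorted(sig_children),
        child_adjusted=child_adjusted,
        n_discoveries=n_discoveries,
        n_families=n_families,
        fdr_bound=bound,
        tested_children=tested,
    )


def fdr_bound(
    n_discoveries: int, n_families: int, alpha: float, delta: float = 1.0
) -> float:
    """Closed-form overall-FDR bound for the two-level hierarchy.

    bound = [(D + F) / (D + 1)] * alpha * delta, with D the total number
    of significant parent+child hypotheses and F the number of families.
    """
    if n_discoveries < 0:
        raise ValueError("n_discoveries must be >= 0")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if alpha < 0 or delta < 0:
        raise ValueError("alpha and delta must be non-negative")
    return (n_discoveries + n_families) / (n_discoveries + 1) * alpha * delta
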