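"""Tissue-specific drug-sensitivity association discovery.

For every (tissue, drug, CFE) candidate that survives the power filters, a
covariate-adjusted ANOVA p-value and a signed Cohen's d are computed; an
association is retained when p < 0.001 and d < -1 (defaults).  Group 1 of
the effect size is always the CFE-altered cells, so sensitivity biomarkers
have negative d.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model_io import CellAnnotation, CFEMatrix, DrugResponseTable
from .errors import DegenerateInputError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "Candidate",
    "SensitivityAssociation",
    "enumerate_candidates",
    "cohens_d",
    "anova_pvalue",
    "discover_associations",
    "associations_frame",
]

COVARIATE_COLUMNS = ("msi_status", "medium", "growth_property")


@dataclass(frozen=True)
class Candidate:
    """A testable (tissue, drug, CFE) triple with its cell groups."""

    tissue: str
    drug_id: str
    cfe_id: str
    alt_cells: tuple[str, ...]  # CFE-altered, measured for the drug
    wt_cells: tuple[str, ...]
    frac_mut_extrapolated: float


@dataclass(frozen=True)
class SensitivityAssociation:
    tissue: str
    drug_id: str
    cfe_id: str
    p_value: float
    cohens_d: float
    n_mut: int
    n_wt: int
    frac_mut_extrapolated: float
    retained: bool
    untestable: bool = False
    alt_cells: tuple[str, ...] = ()
    wt_cells: tuple[str, ...] = ()

    @property
    def key(self) -> str:
        return f"{self.tissue}|{self.drug_id}|{self.cfe_id}"


def enumerate_candidates(
    cfe: CFEMatrix,
    resp: DrugResponseTable,
    ann: CellAnnotation,
    min_mut: int = 4,
    max_extrapolated_frac: float = 0.5,
) -> list[Candidate]:
    """List the (tissue, drug, CFE) triples that pass the power filters.

    A candidate requires a driver-gene CFE, at least ``min_mut`` altered
    cell lines with a measured response for that drug in that tissue, at
    least two wild-type lines for the contrast, and no more than
    ``max_extrapolated_frac`` of the altered lines extrapolated.
    """
    shared = (
        set(cfe.cell_lines) & set(resp.cell_lines) & set(ann.df["cell_line_id"])
    )
    if not shared:
        raise InputError("no cell line is shared by CFE matrix, responses, annotations")

    tissue_of = ann.tissue_of()
    driver_cfes = [
        c for c in cfe.cfe_ids if bool(cfe.metadata.at[c, "has_driver_gene"])
    ]
    n_dropped_driver = len(cfe.cfe_ids) - len(driver_cfes)
    if n_dropped_driver:
        logger.info("dropped %d CFEs without driver genes", n_dropped_driver)

    resp_df = resp.df[resp.df["cell_line_id"].isin(shared)]
    candidates: list[Candidate] = []
    for (drug, tissue), grp in resp_df.groupby(
        [resp_df["drug_id"], resp_df["cell_line_id"].map(tissue_of)], sort=True
    ):
        measured = grp["cell_line_id"].tolist()
        extrapolated = dict(zip(grp["cell_line_id"], grp["extrapolated"]))
        sub = cfe.matrix.reindex(measured)[driver_cfes]
        counts = sub.sum(axis=0)
        for cfe_id in driver_cfes:
            n_alt = int(counts[cfe_id])
            if n_alt < min_mut or len(measured) - n_alt < 2:
                continue
            alt = tuple(sorted(sub.index[sub[cfe_id] == 1]))
            frac_ex = float(np.mean([bool(extrapolated[c]) for c in alt]))
            if frac_ex > max_extrapolated_frac:
                continue
            wt = tuple(sorted(sub.index[sub[cfe_id] == 0]))
            candidates.append(
                Candidate(
                    tissue=tissue,
                    drug_id=drug,
                    cfe_id=cfe_id,
                    alt_cells=alt,
                    wt_cells=wt,
                    frac_mut_extrapolated=frac_ex,
                )
            )
    return candidates


def cohens_d(group_alt: Sequence[float], group_wt: Sequence[float]) -> float:
    """Signed Cohen's d of group_alt minus group_wt with pooled sample SD."""
    x1 = np.asarray(group_alt, dtype=float)
    x2 = np.asarray(group_wt, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both groups need >= 2 members, got {n1} and {n2}")
    pooled_var = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (
        n1 + n2 - 2
    )
    if pooled_var <= 0:
        raise DegenerateInputError("pooled SD is zero; effect size undefined")
    return float((x1.mean() - x2.mean()) / math.sqrt(pooled_var))


def _design_matrix(
    cfe_status: np.ndarray, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, np.ndarray]:
    """Return (X_full, X_reduced); reduced lacks the CFE column.

    Covariates are unordered categoricals with reference (dummy) coding;
    levels constant across the fitted rows contribute no columns.
    """
    n = len(cfe_status)
    cols = [np.ones(n)]
    if covariates is not None:
        for name in covariates.columns:
            series = covariates[name].astype("category")
            if series.nunique() < 2:
                continue
            dummies = pd.get_dummies(series, drop_first=True, dtype=float)
            cols.append(dummies.to_numpy())
    reduced = np.column_stack(cols)
    full = np.column_stack([reduced, cfe_status.astype(float)])
    return full, reduced


def anova_pvalue(
    ln_ic50s: Sequence[float],
    cfe_status: Sequence[int],
    covariates: pd.DataFrame | Mapping[str, Sequence] | None = None,
) -> float:
    """p-value of the CFE term from ln_ic50 ~ cfe + covariates within a tissue.

    Ordinary least squares; the CFE term is judged by its partial (type-II)
    F-test against the model with the covariates only.  Returns NaN when the
    term is untestable (CFE perfectly collinear with a covariate, or no
    residual degrees of freedom) rather than raising.
    """
    y = np.asarray(ln_ic50s, dtype=float)
    status = np.asarray(cfe_status, dtype=int)
    if status.min() == status.max():
        raise ValueError("CFE status is constant; nothing to test")
    if covariates is not None and not isinstance(covariates, pd.DataFrame):
        covariates = pd.DataFrame(dict(covariates))
    if covariates is not None:
        keep = ~covariates.isna().any(axis=1).to_numpy()
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("anova: dropped %d rows with missing covariates", n_drop)
            y, status = y[keep], status[keep]
            covariates = covariates.loc[keep]
            if status.min() == status.max():
                raise ValueError("CFE status constant after dropping missing rows")

    full, reduced = _design_matrix(status, covariates)
    rank_full = np.linalg.matrix_rank(full)
    rank_reduced = np.linalg.matrix_rank(reduced)
    if rank_full == rank_reduced:
        return float("nan")  # CFE collinear with covariates: untestable
    df_resid = len(y) - rank_full
    if df_resid < 1:
        return float("nan")

    rss_full = _rss(full, y)
    rss_reduced = _rss(reduced, y)
    if rss_full <= 0:
        return float(np.finfo(float).tiny)
    f_stat = (rss_reduced - rss_full) / (rss_full / df_resid)
    p = float(stats.f.sf(f_stat, 1, df_resid))
    return max(p, float(np.finfo(float).tiny))


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def discover_associations(
    candidates: Sequence[Candidate],
    resp: DrugResponseTable,
    ann: CellAnnotation,
    p_threshold: float = 0.001,
    d_threshold: float = -1.0,
) -> list[SensitivityAssociation]:
    """Test every candidate; retained = p < p_threshold and d < d_threshold.

    All tested candidates are reported (with the retained flag) so the
    filtering funnel stays auditable.
    """
    resp_lookup = resp.df.set_index(["drug_id", "cell_line_id"])["ln_ic50"]
    covariates = ann.covariates()
    results: list[SensitivityAssociation] = []
    for cand in candidates:
        alt_vals = resp_lookup.loc[cand.drug_id].reindex(list(cand.alt_cells))
        wt_vals = resp_lookup.loc[cand.drug_id].reindex(list(cand.wt_cells))
        cells = list(cand.alt_cells) + list(cand.wt_cells)
        y = np.concatenate([alt_vals.to_numpy(), wt_vals.to_numpy()])
        status = np.concatenate(
            [np.ones(len(cand.alt_cells), dtype=int), np.zeros(len(cand.wt_cells), dtype=int)]
        )
        untestable = False
        try:
            d = cohens_d(alt_vals.to_numpy(), wt_vals.to_numpy())
        except DegenerateInputError:
            d, untestable = float("nan"), True
        p = anova_pvalue(y, status, covariates.reindex(cells))
        if math.isnan(p):
            untestable = True
        retained = (
            not untestable and p < p_threshold and d < d_threshold
        )
        results.append(
            SensitivityAssociation(
                tissue=cand.tissue,
                drug_id=cand.drug_id,
                cfe_id=cand.cfe_id,
                p_value=p,
                cohens_d=d,
                n_mut=len(cand.alt_cells),
                n_wt=len(cand.wt_cells),
                frac_mut_extrapolated=cand.frac_mut_extrapolated,
                retained=bool(retained),
                untestable=untestable,
                alt_cells=cand.alt_cells,
                wt_cells=cand.wt_cells,
            )
        )
    n_kept = sum(a.retained for a in results)
    logger.info("tested %d candidates, retained %d associations", len(results), n_kept)
    return results


def associations_frame(assocs: Sequence[SensitivityAssociation]) -> pd.DataFrame:
    """Flat report table for the association stage."""
    return pd.DataFrame(
        [
            {
                "tissue": a.tissue,
                "drug": a.drug_id,
                "cfe": a.cfe_id,
                "n_mut": a.n_mut,
                "n_wt": a.n_wt,
                "p_value": a.p_value,
                "cohens_d": a.cohens_d,
                "frac_extrapolated": a.frac_mut_extrapolated,
                "untestable": a.untestable,
                "retained": a.retained,
            }
            for a in assocs
        ]
    )
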