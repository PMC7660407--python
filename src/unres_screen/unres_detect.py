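"""Unexpectedly-resistant (UNRES) cell-line detection.

Within each retained sensitivity association, the statistic is the change
in sample SD of the altered cells' ln-IC50s when the i highest values are
removed (i = 1..min(floor(n/2), 5)).  Its null distribution comes from a
bootstrap that resamples n values from all cell lines measured for that
drug in that tissue, ignoring CFE status.  p-values use the add-one rule
and are BH-adjusted (level 0.15) in a pooled pass across all cases.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model_io import CellAnnotation, DrugResponseTable
from .errors import InputError
from .sensitivity_assoc import SensitivityAssociation

logger = logging.getLogger(__name__)

__all__ = [
    "UnresCase",
    "sd_decrease",
    "bootstrap_null",
    "bootstrap_pvalue",
    "normalized_sd_decrease",
    "bh_adjust",
    "detect_unres",
    "case_seed_sequence",
    "cases_frame",
]

DEFAULT_B = 10_000
DEFAULT_I_MAX = 5
DENOM_TOL = 1e-12


@dataclass(frozen=True)
class UnresCase:
    """One (association, i) test: i top-IC50 lines removed from the group."""

    association: SensitivityAssociation
    i: int
    removed_cells: tuple[str, ...]  # ordered by descending ln_ic50
    sigma0: float
    sigma_i: float
    delta_sigma: float
    p_value: float
    bootstrap_median: float
    normalized_sd_decrease: float
    p_adjusted: float = float("nan")  # filled by the pooled BH pass
    significant: bool = False
    magnitude_undefined: bool = False


def _sample_sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1))


def max_removable(n: int, i_max: int = DEFAULT_I_MAX) -> int:
    return min(n // 2, i_max)


def sd_decrease(
    values: Sequence[float],
    i: int,
    cell_ids: Sequence[str] | None = None,
    i_max: int = DEFAULT_I_MAX,
) -> tuple[float, float, float]:
    """(sigma0, sigma_i, delta_sigma) after removing the i largest values.

    Sample SDs use the n-1 denominator.  Ties at the removal boundary are
    broken by cell-line id so results are reproducible.
    """
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    if n < 4:
        raise ValueError(f"need at least 4 values, got {n}")
    if not 1 <= i <= max_removable(n, i_max):
        raise ValueError(
            f"i={i} out of range 1..{max_removable(n, i_max)} for n={n}"
        )
    sigma0 = _sample_sd(vals)
    if cell_ids is not None:
        order = sorted(range(n), key=lambda k: (-vals[k], str(cell_ids[k])))
    else:
        order = np.argsort(-vals, kind="stable").tolist()
    kept = np.array([vals[k] for k in order[i:]])
    sigma_i = _sample_sd(kept)
    return sigma0, sigma_i, sigma_i - sigma0


def bootstrap_null(
    pool: Sequence[float],
    n: int,
    i: int,
    B: int = DEFAULT_B,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> np.ndarray:
    """B bootstrap draws of delta_sigma_i under resampling from the pool.

    Each draw resamples n values with replacement from the pool of all
    measured ln-IC50s for the drug within the tissue.
    """
    pool_arr = np.asarray(pool, dtype=float)
    if len(pool_arr) < n:
        raise InputError(f"pool of size {len(pool_arr)} smaller than n={n}")
    if n < 4:
        raise ValueError(f"n must be >= 4, got {n}")
    if not 1 <= i <= max_removable(n):
        raise ValueError(f"i={i} out of range for n={n}")
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)
    samples = rng.choice(pool_arr, size=(B, n), replace=True)
    samples.sort(axis=1)  # ascending; top-i removal keeps the first n-i
    sigma0 = samples.std(axis=1, ddof=1)
    sigma_i = samples[:, : n - i].std(axis=1, ddof=1)
    return sigma_i - sigma0


def bootstrap_pvalue(delta_sigma: float, null: np.ndarray, B: int | None = None) -> float:
    """Add-one bootstrap p: (1 + #{null <= observed}) / (B + 1)."""
    null = np.asarray(null, dtype=float)
    if B is None:
        B = len(null)
    elif B != len(null):
        raise ValueError(f"null has {len(null)} members, expected B={B}")
    return float((1 + int(np.sum(null <= delta_sigma))) / (B + 1))


def normalized_sd_decrease(
    delta_sigma: float, sigma0: float, bootstrap_median: float
) -> tuple[float, bool]:
    """-(delta - E)/(sigma0 - E) with E the bootstrap-null median.

    Returns (value, magnitude_undefined); when the denominator is within
    DENOM_TOL of zero the magnitude is undefined (NaN) but the case is
    still reported.
    """
    denom = sigma0 - bootstrap_median
    if abs(denom) < DENOM_TOL:
        return float("nan"), True
    return float(-(delta_sigma - bootstrap_median) / denom), False


def bh_adjust(
    p_values: Sequence[float], alpha: float = 0.15
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags.

    Adjusted values are monotone and capped at 1; flag = adjusted < alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted < alpha


def case_seed_sequence(
    seed: int, tissue: str, drug: str, cfe: str, i: int
) -> np.random.SeedSequence:
    """Order-independent stream for one (association, i) pair.

    The spawn key is derived from a hash of the association identity, so
    results do not depend on iteration order across associations.
    """
    digest = hashlib.sha256(f"{tissue}|{drug}|{cfe}|{i}".encode()).digest()
    words = tuple(int.from_bytes(digest[k : k + 4], "big") for k in range(0, 16, 4))
    return np.random.SeedSequence(seed, spawn_key=words)


def detect_unres(
    association: SensitivityAssociation,
    resp: DrugResponseTable,
    ann: CellAnnotation,
    B: int = DEFAULT_B,
    seed: int = 0,
    i_max: int = DEFAULT_I_MAX,
) -> list[UnresCase]:
    """All leave-top-i cases for one association (adjusted p filled later).

    The bootstrap pool is every measured ln-IC50 for the drug within the
    tissue, including the altered cells themselves.
    """
    alt_cells = list(association.alt_cells)
    n = len(alt_cells)
    if n < 4:
        raise InputError(
            f"association {association.key} has only {n} altered cells with responses"
        )
    resp_df = resp.df[resp.df["drug_id"] == association.drug_id]
    tissue_cells = set(ann.cells_in_tissue(association.tissue))
    pool_rows = resp_df[resp_df["cell_line_id"].isin(tissue_cells)]
    pool = pool_rows["ln_ic50"].to_numpy()
    values = (
        resp_df.set_index("cell_line_id")["ln_ic50"].reindex(alt_cells).to_numpy()
    )
    if np.unique(values[np.argsort(values)[-max_removable(n, i_max):]]).size < min(
        max_removable(n, i_max), n
    ):
        logger.warning(
            "%s: ties among top ln-IC50 values; removal order uses cell-id tie-break",
            association.key,
        )

    # removal order: descending value, ties by cell id
    order = sorted(range(n), key=lambda k: (-values[k], alt_cells[k]))
    cases: list[UnresCase] = []
    for i in range(1, max_removable(n, i_max) + 1):
        sigma0, sigma_i, delta = sd_decrease(values, i, cell_ids=alt_cells, i_max=i_max)
        ss = case_seed_sequence(seed, association.tissue, association.drug_id,
                                association.cfe_id, i)
        null = bootstrap_null(pool, n, i, B=B, seed=np.random.default_rng(ss))
        p = bootstrap_pvalue(delta, null)
        e_delta = float(np.median(null))
        norm, undefined = normalized_sd_decrease(delta, sigma0, e_delta)
        cases.append(
            UnresCase(
                association=association,
                i=i,
                removed_cells=tuple(alt_cells[k] for k in order[:i]),
                sigma0=sigma0,
                sigma_i=sigma_i,
                delta_sigma=delta,
                p_value=p,
                bootstrap_median=e_delta,
                normalized_sd_decrease=norm,
                magnitude_undefined=undefined,
            )
        )
    return cases


def adjust_cases(
    cases: Sequence[UnresCase], alpha: float = 0.15
) -> list[UnresCase]:
    """Pooled BH pass over every case's p-value; fills p_adjusted/significant."""
    if not cases:
        return []
    adjusted, flags = bh_adjust([c.p_value for c in cases], alpha=alpha)
    return [
        replace(c, p_adjusted=float(adj), significant=bool(sig))
        for c, adj, sig in zip(cases, adjusted, flags)
    ]


def cases_frame(cases: Sequence[UnresCase], label_threshold: float = 0.5) -> pd.DataFrame:
    """Flat report table for the UNRES stage."""
    return pd.DataFrame(
        [
            {
                "tissue": c.association.tissue,
                "drug": c.association.drug_id,
                "cfe": c.association.cfe_id,
                "i": c.i,
                "removed_cells": ";".join(c.removed_cells),
                "sigma0": c.sigma0,
                "sigma_i": c.sigma_i,
                "delta_sigma": c.delta_sigma,
                "p_value": c.p_value,
                "p_adjusted": c.p_adjusted,
                "significant": c.significant,
                "normalized_sd_decrease": c.normalized_sd_decrease,
                "labeled": (
                    not c.magnitude_undefined
                    and c.normalized_sd_decrease > label_threshold
                ),
            }
            for c in cases
        ]
    )
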