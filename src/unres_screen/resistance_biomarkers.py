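"""Putative resistance-biomarker calling for detected UNRES cases.

Three evidence routes against the CFE matrix: (1) extra mutations in the
sensitivity-biomarker gene(s) found only in UNRES lines; (2) CFEs mutually
exclusive between the UNRES lines and the remaining sensitive lines (in
either direction); (3) Fisher-exact enrichment when an UNRES case spans
multiple lines.  A cancer-gene-list filter yields the cleaned candidate
set; the unfiltered set is kept alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .data_model_io import CFEMatrix, GeneList
from .errors import ConfigError
from .unres_detect import UnresCase

logger = logging.getLogger(__name__)

__all__ = [
    "BiomarkerCandidate",
    "unique_target_mutations",
    "mutually_exclusive_cfes",
    "enriched_cfes",
    "filter_cancer_genes",
    "propose_biomarkers",
    "biomarkers_frame",
]

EVIDENCE_PRIORITY = ("unique_target_mutation", "mutually_exclusive", "enriched")


@dataclass(frozen=True)
class BiomarkerCandidate:
    cfe_id: str
    evidence: str  # unique_target_mutation | mutually_exclusive | enriched
    direction: str | None  # present_in_unres | absent_in_unres | None
    fisher_p: float | None
    genes: tuple[str, ...]
    in_cancer_gene_list: bool | None = None

    def __post_init__(self) -> None:
        assert self.evidence in EVIDENCE_PRIORITY, self.evidence
        assert (self.fisher_p is not None) == (self.evidence == "enriched")


def _status(cfe: CFEMatrix, cfe_id: str, cells: Sequence[str]) -> list[int]:
    return [int(cfe.matrix.at[c, cfe_id]) for c in cells]


def unique_target_mutations(
    unres_cells: Sequence[str],
    sensitive_cells: Sequence[str],
    cfe: CFEMatrix,
    association_cfe_id: str,
) -> list[BiomarkerCandidate]:
    """Mutation CFEs in the sensitivity-biomarker gene(s) private to UNRES lines.

    Scans mutation-class CFEs other than the association's own whose gene
    annotation overlaps the association CFE's genes, present in at least
    one UNRES cell and in no sensitive cell (the second-site-mutation
    pattern).  Returns an empty list, with a note, when the association
    CFE carries no gene annotation.
    """
    target_genes = set(cfe.genes_of(association_cfe_id))
    if not target_genes:
        logger.info(
            "association CFE %s has no gene annotation; "
            "unique-target-mutation route skipped",
            association_cfe_id,
        )
        return []
    out = []
    for cfe_id in cfe.cfe_ids:
        if cfe_id == association_cfe_id:
            continue
        if cfe.metadata.at[cfe_id, "alteration_class"] != "mutation":
            continue
        genes = set(cfe.genes_of(cfe_id))
        if not genes & target_genes:
            continue
        in_unres = _status(cfe, cfe_id, unres_cells)
        in_sens = _status(cfe, cfe_id, sensitive_cells)
        if sum(in_unres) >= 1 and sum(in_sens) == 0:
            out.append(
                BiomarkerCandidate(
                    cfe_id=cfe_id,
                    evidence="unique_target_mutation",
                    direction="present_in_unres",
                    fisher_p=None,
                    genes=tuple(sorted(genes)),
                )
            )
    return out


def mutually_exclusive_cfes(
    unres_cells: Sequence[str],
    sensitive_cells: Sequence[str],
    cfe: CFEMatrix,
    exclude: Sequence[str] = (),
) -> list[BiomarkerCandidate]:
    """CFEs altered in all UNRES and no sensitive line, or vice versa."""
    if not unres_cells or not sensitive_cells:
        raise ValueError("need at least one UNRES and one sensitive cell line")
    out = []
    for cfe_id in cfe.cfe_ids:
        if cfe_id in exclude:
            continue
        in_unres = _status(cfe, cfe_id, unres_cells)
        in_sens = _status(cfe, cfe_id, sensitive_cells)
        if all(v == 1 for v in in_unres) and all(v == 0 for v in in_sens):
            direction = "present_in_unres"
        elif all(v == 0 for v in in_unres) and all(v == 1 for v in in_sens):
            direction = "absent_in_unres"
        else:
            continue
        out.append(
            BiomarkerCandidate(
                cfe_id=cfe_id,
                evidence="mutually_exclusive",
                direction=direction,
                fisher_p=None,
                genes=tuple(sorted(cfe.genes_of(cfe_id))),
            )
        )
    return out


def enriched_cfes(
    unres_cells: Sequence[str],
    sensitive_cells: Sequence[str],
    cfe: CFEMatrix,
    p_threshold: float = 0.05,
    exclude: Sequence[str] = (),
) -> tuple[list[BiomarkerCandidate], pd.DataFrame]:
    """Two-sided Fisher exact test per CFE, UNRES vs sensitive lines.

    Applies only to cases with >= 2 UNRES cells; otherwise returns empty
    results with a logged note.  All CFEs are reported with their p; those
    below ``p_threshold`` become candidates (no multiplicity correction —
    hypothesis-generating output).
    """
    if len(unres_cells) < 2:
        logger.info("fewer than 2 UNRES cells; enrichment route skipped")
        return [], pd.DataFrame(columns=["cfe", "fisher_p", "direction"])
    candidates, rows = [], []
    for cfe_id in cfe.cfe_ids:
        if cfe_id in exclude:
            continue
        a = sum(_status(cfe, cfe_id, unres_cells))
        b = len(unres_cells) - a
        c = sum(_status(cfe, cfe_id, sensitive_cells))
        d = len(sensitive_cells) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        frac_unres = a / len(unres_cells)
        frac_sens = c / len(sensitive_cells)
        direction = (
            "present_in_unres" if frac_unres >= frac_sens else "absent_in_unres"
        )
        rows.append({"cfe": cfe_id, "fisher_p": float(p), "direction": direction})
        if p < p_threshold:
            candidates.append(
                BiomarkerCandidate(
                    cfe_id=cfe_id,
                    evidence="enriched",
                    direction=direction,
                    fisher_p=float(p),
                    genes=tuple(sorted(cfe.genes_of(cfe_id))),
                )
            )
    return candidates, pd.DataFrame(rows)


def filter_cancer_genes(
    candidates: Sequence[BiomarkerCandidate], genes: GeneList
) -> list[BiomarkerCandidate]:
    """Keep candidates with at least one member gene in the cancer gene list."""
    if not genes:
        raise ConfigError("cancer gene list is empty")
    return [
        c for c in candidates if any(g in genes for g in c.genes)
    ]


def _dedupe(candidates: Sequence[BiomarkerCandidate]) -> list[BiomarkerCandidate]:
    """One candidate per cfe_id, keeping the strongest evidence class."""
    rank = {e: k for k, e in enumerate(EVIDENCE_PRIORITY)}
    best: dict[str, BiomarkerCandidate] = {}
    for c in candidates:
        prev = best.get(c.cfe_id)
        if prev is None or rank[c.evidence] < rank[prev.evidence]:
            best[c.cfe_id] = c
    return sorted(best.values(), key=lambda c: (rank[c.evidence], c.cfe_id))


def propose_biomarkers(
    case: UnresCase,
    cfe: CFEMatrix,
    cancer_genes: GeneList | None = None,
    fisher_p_threshold: float = 0.05,
) -> tuple[list[BiomarkerCandidate], list[BiomarkerCandidate]]:
    """All three evidence routes for one UNRES case.

    Sensitive cells are the association's altered cells minus the case's
    removed cells.  Returns (unfiltered, cancer-gene-filtered) candidate
    lists; with no gene list the two are identical.
    """
    assoc = case.association
    unres_cells = list(case.removed_cells)
    sensitive_cells = [c for c in assoc.alt_cells if c not in set(unres_cells)]

    cands: list[BiomarkerCandidate] = []
    cands += unique_target_mutations(unres_cells, sensitive_cells, cfe, assoc.cfe_id)
    cands += mutually_exclusive_cfes(
        unres_cells, sensitive_cells, cfe, exclude=(assoc.cfe_id,)
    )
    enriched, _ = enriched_cfes(
        unres_cells, sensitive_cells, cfe,
        p_threshold=fisher_p_threshold, exclude=(assoc.cfe_id,),
    )
    cands += enriched
    unfiltered = _dedupe(cands)
    if cancer_genes is None:
        return unfiltered, list(unfiltered)
    filtered = filter_cancer_genes(unfiltered, cancer_genes)
    return unfiltered, filtered


def biomarkers_frame(
    case: UnresCase,
    candidates: Sequence[BiomarkerCandidate],
    cancer_genes: GeneList | None = None,
) -> pd.DataFrame:
    """Flat report table for one case's biomarker candidates."""
    return pd.DataFrame(
        [
            {
                "tissue": case.association.tissue,
                "drug": case.association.drug_id,
                "assoc_cfe": case.association.cfe_id,
                "i": case.i,
                "cfe": c.cfe_id,
                "evidence": c.evidence,
                "direction": c.direction if c.direction is not None else "",
                "fisher_p": c.fisher_p if c.fisher_p is not None else float("nan"),
                "genes": ",".join(c.genes),
                "in_cancer_gene_list": (
                    any(g in cancer_genes for g in c.genes)
                    if cancer_genes is not None
                    else pd.NA
                ),
            }
            for c in candidates
        ]
    )
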