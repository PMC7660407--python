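"""Synthetic pharmacogenomic screens with planted ground truth.

Every downstream stage (association discovery, outlier detection, biomarker
calling, differential essentiality) is testable against these generators
without any external data.  All generation is deterministic given the config
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model_io import (
    CFEMatrix,
    CellAnnotation,
    DrugResponseTable,
    EssentialityMatrix,
)
from .errors import ConfigError

__all__ = [
    "EssentialityConfig",
    "SimulationConfig",
    "GroundTruth",
    "generate_screen",
    "generate_essentiality",
    "write_fixture_bundle",
    "load_fixture_bundle",
]

MSI_LEVELS = ("MSI", "MSS")
MEDIUM_LEVELS = ("DMEM", "RPMI")
GROWTH_LEVELS = ("Adherent", "Semi-Adherent", "Suspension")


@dataclass(frozen=True)
class EssentialityConfig:
    n_genes: int = 2000
    n_differential: int = 5
    differential_shift: float = -6.0


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for one synthetic screen.

    Planted associations each get a dedicated CFE whose carriers in one
    tissue are shifted by ``sensitivity_shift`` on the ln-IC50 scale for one
    drug; planted UNRES cells carry that CFE but stay at the baseline level.
    """

    n_tissues: int = 2
    cells_per_tissue: int = 20
    n_drugs: int = 5
    n_cfes: int = 10
    cfe_frequency: float = 0.5
    sensitivity_shift: float = -6.0
    n_planted_associations: int = 1
    n_planted_unres_per_association: int = 0
    noise_sd: float = 1.0
    essentiality: EssentialityConfig = field(default_factory=EssentialityConfig)
    seed: int = 0
    # --- optional knobs beyond the core statistical structure ---
    max_screened_conc: float = 1000.0  # µM; high enough that extrapolation is rare
    covariate_confounding: float = 0.0  # P(force MSI for planted-CFE carriers)
    plant_resistance_cfes: bool = False  # add a CFE exclusive to planted UNRES cells

    def __post_init__(self) -> None:
        if self.cells_per_tissue < 8:
            raise ConfigError("cells_per_tissue must be >= 8")
        if not self.sensitivity_shift < 0:
            raise ConfigError("sensitivity_shift must be negative")
        if not self.noise_sd > 0:
            raise ConfigError("noise_sd must be positive")
        if not 0 < self.cfe_frequency < 1:
            raise ConfigError("cfe_frequency must be in (0,1)")
        if self.n_planted_associations > self.n_tissues * self.n_drugs:
            raise ConfigError("more planted associations than (tissue, drug) slots")
        if self.n_planted_associations > self.n_cfes:
            raise ConfigError("more planted associations than CFEs")


@dataclass
class GroundTruth:
    """What was planted: associations, UNRES lines, resistance CFEs, genes."""

    planted_associations: list[dict] = field(default_factory=list)
    planted_unres: dict[str, list[str]] = field(default_factory=dict)
    planted_resistance_cfes: dict[str, str] = field(default_factory=dict)
    differential_genes: dict[str, list[str]] = field(default_factory=dict)

    @staticmethod
    def key(tissue: str, drug: str, cfe: str) -> str:
        return f"{tissue}|{drug}|{cfe}"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            planted_associations=self.planted_associations + other.planted_associations,
            planted_unres={**self.planted_unres, **other.planted_unres},
            planted_resistance_cfes={
                **self.planted_resistance_cfes,
                **other.planted_resistance_cfes,
            },
            differential_genes={**self.differential_genes, **other.differential_genes},
        )


def _ids(prefix: str, n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"{prefix}{k:0{width}d}" for k in range(1, n + 1)]


def generate_screen(
    config: SimulationConfig,
) -> tuple[DrugResponseTable, CFEMatrix, CellAnnotation, GroundTruth]:
    """Generate one full synthetic screen.

    Baseline ln-IC50 is Normal(0, noise_sd) per (cell, drug).  For each
    planted (tissue, drug, CFE) triple the CFE's carriers in that tissue are
    shifted by ``sensitivity_shift`` for that drug, except the planted UNRES
    cells, which revert fully to the baseline distribution.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))

    tissues = _ids("TISSUE", config.n_tissues)
    drugs = _ids("DRUG", config.n_drugs)
    cfes = _ids("CFE", config.n_cfes)
    cells = [
        f"CL-{t}-{j:03d}" for t in tissues for j in range(1, config.cells_per_tissue + 1)
    ]
    tissue_of = {
        c: t for t in tissues for c in cells if c.startswith(f"CL-{t}-")
    }

    # -- CFE carriage: planted CFEs get a fixed carrier count in their tissue
    truth = GroundTruth()
    slots = [(t, d) for t in tissues for d in drugs]
    slot_idx = rng.choice(len(slots), size=config.n_planted_associations, replace=False)
    planted = [
        (slots[s][0], slots[s][1], cfes[a]) for a, s in enumerate(sorted(slot_idx))
    ]
    planted_cfe_ids = {cfe for _, _, cfe in planted}

    carriage = pd.DataFrame(0, index=pd.Index(cells, name="cell_line_id"),
                            columns=cfes, dtype=np.int8)
    n_carriers = int(round(config.cells_per_tissue * config.cfe_frequency))
    for cfe in cfes:
        if cfe in planted_cfe_ids:
            continue
        carriage[cfe] = rng.binomial(1, config.cfe_frequency, size=len(cells)).astype(
            np.int8
        )

    unres_of: dict[tuple[str, str, str], list[str]] = {}
    for tissue, drug, cfe in planted:
        tissue_cells = [c for c in cells if tissue_of[c] == tissue]
        if config.n_planted_unres_per_association >= n_carriers:
            raise ConfigError(
                f"n_planted_unres_per_association="
                f"{config.n_planted_unres_per_association} must be < carrier count "
                f"{n_carriers}"
            )
        chosen = rng.choice(tissue_cells, size=n_carriers, replace=False)
        carriers = sorted(chosen.tolist())
        carriage.loc[carriers, cfe] = 1
        # carriage outside the planted tissue stays random
        other_cells = [c for c in cells if tissue_of[c] != tissue]
        carriage.loc[other_cells, cfe] = rng.binomial(
            1, config.cfe_frequency, size=len(other_cells)
        ).astype(np.int8)
        unres = sorted(
            rng.choice(carriers, size=config.n_planted_unres_per_association,
                       replace=False).tolist()
        )
        unres_of[(tissue, drug, cfe)] = unres
        truth.planted_associations.append({"tissue": tissue, "drug": drug, "cfe": cfe})
        truth.planted_unres[GroundTruth.key(tissue, drug, cfe)] = unres

    meta = pd.DataFrame(
        {
            "alteration_class": "mutation",
            "genes": [[f"GENE{k:04d}"] for k in range(1, len(cfes) + 1)],
            "has_driver_gene": True,
        },
        index=pd.Index(cfes, name="cfe_id"),
    )

    # -- optional resistance CFEs: present in exactly the planted UNRES cells
    if config.plant_resistance_cfes:
        for k, (tissue, drug, cfe) in enumerate(planted, start=1):
            unres = unres_of[(tissue, drug, cfe)]
            if not unres:
                continue
            res_id = f"RESCFE{k:02d}"
            col = pd.Series(0, index=carriage.index, dtype=np.int8)
            col.loc[unres] = 1
            carriage[res_id] = col
            meta.loc[res_id] = {
                "alteration_class": "mutation",
                "genes": [f"RESGENE{k:02d}"],
                "has_driver_gene": True,
            }
            truth.planted_resistance_cfes[GroundTruth.key(tissue, drug, cfe)] = res_id

    cfe_matrix = CFEMatrix(matrix=carriage, metadata=meta)

    # -- responses
    base = rng.normal(0.0, config.noise_sd, size=(len(cells), len(drugs)))
    ln_ic50 = pd.DataFrame(base, index=carriage.index, columns=drugs)
    for tissue, drug, cfe in planted:
        carriers = [
            c
            for c in carriage.index[carriage[cfe] == 1]
            if tissue_of[c] == tissue and c not in unres_of[(tissue, drug, cfe)]
        ]
        ln_ic50.loc[carriers, drug] += config.sensitivity_shift

    resp_df = (
        ln_ic50.stack()
        .rename("ln_ic50")
        .reset_index()
        .rename(columns={"level_1": "drug_id"})
    )
    resp_df["max_screened_conc"] = config.max_screened_conc
    resp_df["extrapolated"] = resp_df["ln_ic50"] > np.log(config.max_screened_conc)
    resp = DrugResponseTable(resp_df)

    # -- covariates, independent of CFE status unless confounding is enabled
    ann_df = pd.DataFrame(
        {
            "cell_line_id": cells,
            "tissue": [tissue_of[c] for c in cells],
            "msi_status": rng.choice(MSI_LEVELS, size=len(cells), p=[0.2, 0.8]),
            "medium": rng.choice(MEDIUM_LEVELS, size=len(cells)),
            "growth_property": rng.choice(
                GROWTH_LEVELS, size=len(cells), p=[0.6, 0.2, 0.2]
            ),
        }
    )
    if config.covariate_confounding > 0:
        carrier_cells = set()
        for tissue, drug, cfe in planted:
            carrier_cells.update(
                c for c in carriage.index[carriage[cfe] == 1] if tissue_of[c] == tissue
            )
        mask = ann_df["cell_line_id"].isin(carrier_cells)
        flips = rng.random(len(ann_df)) < config.covariate_confounding
        ann_df.loc[mask & flips, "msi_status"] = "MSI"
    ann = CellAnnotation(ann_df)

    return resp, cfe_matrix, ann, truth


def generate_essentiality(
    config: SimulationConfig,
    index_cells: list[str],
    comparator_cells: list[str],
) -> tuple[EssentialityMatrix, GroundTruth]:
    """Standard-normal gene effects with planted differential genes.

    The planted genes are shifted by ``differential_shift`` in the index
    cells only; comparator cells keep the null distribution.
    """
    ess_cfg = config.essentiality
    if ess_cfg.n_genes < 100:
        raise ConfigError("essentiality.n_genes must be >= 100")
    if ess_cfg.n_differential > ess_cfg.n_genes:
        raise ConfigError("n_differential exceeds n_genes")
    overlap = set(index_cells) & set(comparator_cells)
    if overlap:
        raise ConfigError(f"cells in both index and comparator sets: {sorted(overlap)}")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    genes = [f"ESSGENE{k:05d}" for k in range(1, ess_cfg.n_genes + 1)]
    all_cells = list(index_cells) + list(comparator_cells)
    scores = rng.normal(0.0, 1.0, size=(len(genes), len(all_cells)))
    df = pd.DataFrame(scores, index=pd.Index(genes, name="gene_symbol"),
                      columns=all_cells)

    diff_idx = rng.choice(len(genes), size=ess_cfg.n_differential, replace=False)
    diff_genes = sorted(genes[i] for i in diff_idx)
    df.loc[diff_genes, list(index_cells)] += ess_cfg.differential_shift

    truth = GroundTruth(
        differential_genes={c: diff_genes for c in index_cells}
    )
    return EssentialityMatrix(df), truth


# ---------------------------------------------------------------------------
# Fixture bundle I/O
# ---------------------------------------------------------------------------

BUNDLE_FILES = {
    "drug_response": "drug_response.csv",
    "cfe_matrix": "cfe_matrix.csv",
    "cfe_metadata": "cfe_metadata.csv",
    "annotations": "annotations.csv",
    "gene_effect": "gene_effect.csv",
    "ground_truth": "ground_truth.json",
}


def write_fixture_bundle(
    directory: str | Path,
    resp: DrugResponseTable,
    cfe: CFEMatrix,
    ann: CellAnnotation,
    truth: GroundTruth,
    essentiality: EssentialityMatrix | None = None,
) -> dict[str, Path]:
    """Write a screen as a directory of CSVs readable by data_model_io."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    p = directory / BUNDLE_FILES["drug_response"]
    resp.df.to_csv(p, index=False, float_format="%.12g")
    out["drug_response"] = p

    p = directory / BUNDLE_FILES["cfe_matrix"]
    cfe.matrix.to_csv(p)
    out["cfe_matrix"] = p

    p = directory / BUNDLE_FILES["cfe_metadata"]
    meta_out = cfe.metadata.copy()
    meta_out["genes"] = meta_out["genes"].map(",".join)
    meta_out.reset_index().to_csv(p, index=False)
    out["cfe_metadata"] = p

    p = directory / BUNDLE_FILES["annotations"]
    ann.df.to_csv(p, index=False)
    out["annotations"] = p

    if essentiality is not None:
        p = directory / BUNDLE_FILES["gene_effect"]
        essentiality.df.to_csv(p, float_format="%.12g")
        out["gene_effect"] = p

    p = directory / BUNDLE_FILES["ground_truth"]
    p.write_text(truth.to_json())
    out["ground_truth"] = p
    return out


def load_fixture_bundle(directory: str | Path):
    """Read a bundle back; returns (resp, cfe, ann, truth, essentiality|None)."""
    from . import data_model_io as io

    directory = Path(directory)
    resp = io.read_drug_response(directory / BUNDLE_FILES["drug_response"])
    cfe = io.read_cfe_matrix(
        directory / BUNDLE_FILES["cfe_matrix"], directory / BUNDLE_FILES["cfe_metadata"]
    )
    ann = io.read_annotations(directory / BUNDLE_FILES["annotations"])
    truth = GroundTruth.from_json(
        (directory / BUNDLE_FILES["ground_truth"]).read_text()
    )
    ess_path = directory / BUNDLE_FILES["gene_effect"]
    ess = io.read_essentiality(ess_path) if ess_path.exists() else None
    return resp, cfe, ann, truth, ess
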