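import numpy as np
import pandas as pd
import pytest

from unres_screen.data_model_io import CellAnnotation, CFEMatrix
from unres_screen.synthetic_data import (
    EssentialityConfig,
    SimulationConfig,
    generate_essentiality,
    generate_screen,
    write_fixture_bundle,
)


def make_response_frame(rows):
    """rows: (cell, drug, ln_ic50[, max_conc]) tuples."""
    recs = []
    for row in rows:
        cell, drug, val = row[:3]
        rec = {"cell_line_id": cell, "drug_id": drug, "ln_ic50": float(val)}
        if len(row) > 3:
            rec["max_screened_conc"] = float(row[3])
            rec["extrapolated"] = float(val) > np.log(float(row[3]))
        else:
            rec["extrapolated"] = False
        recs.append(rec)
    return pd.DataFrame(recs)


def make_cfe(matrix: dict, metadata: dict | None = None) -> CFEMatrix:
    """matrix: {cfe_id: {cell: 0/1}}; metadata defaults to driver mutations."""
    mat = pd.DataFrame(matrix).fillna(0).astype("int8")
    mat.index.name = "cell_line_id"
    if metadata is None:
        metadata = {
            c: {"alteration_class": "mutation", "genes": [f"G_{c}"],
                "has_driver_gene": True}
            for c in mat.columns
        }
    meta = pd.DataFrame(metadata).T
    meta.index.name = "cfe_id"
    return CFEMatrix(matrix=mat, metadata=meta)


def make_annotations(cells, tissue="T1", **overrides) -> CellAnnotation:
    df = pd.DataFrame(
        {
            "cell_line_id": list(cells),
            "tissue": tissue,
            "msi_status": "MSS",
            "medium": "RPMI",
            "growth_property": "Adherent",
        }
    )
    for col, vals in overrides.items():
        df[col] = vals
    return CellAnnotation(df)


@pytest.fixture(scope="session")
def planted_config():
    return SimulationConfig(
        n_tissues=1,
        cells_per_tissue=20,
        n_drugs=3,
        n_cfes=3,
        cfe_frequency=0.5,
        sensitivity_shift=-6.0,
        n_planted_associations=1,
        n_planted_unres_per_association=1,
        noise_sd=1.0,
        essentiality=EssentialityConfig(n_genes=300, n_differential=3,
                                        differential_shift=-6.0),
        plant_resistance_cfes=True,
        seed=11,
    )


@pytest.fixture(scope="session")
def planted_screen(planted_config):
    return generate_screen(planted_config)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, planted_config, planted_screen):
    resp, cfe, ann, truth = planted_screen
    unres = sorted({c for cells in truth.planted_unres.values() for c in cells})
    comparators = sorted(set(ann.df["cell_line_id"]) - set(unres))
    ess, ess_truth = generate_essentiality(planted_config, unres, comparators)
    truth = truth.merge(ess_truth)
    d = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(d, resp, cfe, ann, truth, essentiality=ess)
    return d
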