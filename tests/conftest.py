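import numpy as np
import pandas as pd
import pytest

from top3quant import SimParams, StudyDesign, generate_truth, simulate_peptide_table
from top3quant.simdata import noise_free_params


@pytest.fixture(scope="session")
def design() -> StudyDesign:
    return StudyDesign.default()


@pytest.fixture(scope="session")
def small_noise_free(design):
    """A clean (no noise, no dropout) simulated experiment with truth ledger."""
    params = noise_free_params(SimParams(n_proteins=120, seed=11))
    truth = generate_truth(params)
    table = simulate_peptide_table(truth, design, params)
    return params, truth, table


@pytest.fixture(scope="session")
def small_noisy(design):
    params = SimParams(n_proteins=150, seed=5)
    truth = generate_truth(params)
    table = simulate_peptide_table(truth, design, params)
    return params, truth, table


def toy_peptide_table(design, rows):
    """Build a peptide table from (peptide, protein, unique, run, intensity)."""
    df = pd.DataFrame(rows, columns=["peptide", "protein", "unique", "run",
                                     "intensity"])
    df["unique"] = df["unique"].astype(bool)
    df["intensity"] = df["intensity"].astype(float)
    return df


def matrix_from_dict(values: dict, runs: list[str]):
    """ProteinQuantMatrix straight from {protein: {run: value}} for tests."""
    from top3quant.quantify import ProteinQuantMatrix

    ab = pd.DataFrame(values).T.reindex(columns=runs).astype(float)
    npep = pd.Series(3, index=ab.index)
    nuniq = pd.Series(2, index=ab.index)
    used = ab.notna().astype(int) * 3
    return ProteinQuantMatrix(abundance=ab, peptides_per_protein=npep,
                              unique_peptides_per_protein=nuniq,
                              used_peptide_count=used)
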