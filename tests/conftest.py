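import numpy as np
import pandas as pd
import pytest

from mitodep import SimulationConfig


@pytest.fixture
def small_config():
    """Tiny but fully-featured simulation: 2 conditions x 3 bio x 3 tech."""
    return SimulationConfig(n_proteins=60, frac_mito=0.5, frac_dep=0.3,
                            planted_fc=2.0, noise_cv=0.1, missing_rate=0.05,
                            seed=7)


@pytest.fixture
def noiseless_config():
    return SimulationConfig(n_proteins=50, frac_mito=0.5, frac_dep=0.4,
                            planted_fc=2.0, frac_down=0.5,
                            min_peptides=2, frac_unique_peptides=1.0,
                            noise_cv=0.0, missing_rate=0.0,
                            contamination_rate=0.0, seed=3)


def make_peptides(rows):
    """Long peptide table from (peptide, protein, unique, run, intensity)."""
    return pd.DataFrame(rows, columns=["peptide_id", "protein_id",
                                       "is_unique", "run_id", "intensity"])


@pytest.fixture
def two_run_peptides():
    """Two identical runs over three peptides of two proteins."""
    rows = []
    for run in ("r1", "r2"):
        rows += [("p1", "A", True, run, 100.0),
                 ("p2", "A", True, run, 200.0),
                 ("p3", "B", False, run, 999.0)]
    return make_peptides(rows)
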