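import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rootqtl import GenotypePanel, filter_markers, simulate_panel
from rootqtl.simulate import PanelConfig, PhenoDesign, default_qtl_set, simulate_phenotypes

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    return PanelConfig(
        n_genotypes=90,
        subpop_sizes={"cultivar": 30, "landrace": 30, "wild": 30},
        n_markers=700,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    panel, _ = filter_markers(simulate_panel(small_config))
    return panel


@pytest.fixture(scope="session")
def small_qtls(small_panel):
    return default_qtl_set(small_panel, seed=2)


@pytest.fixture(scope="session")
def small_pheno(small_panel, small_qtls):
    return simulate_phenotypes(small_panel, small_qtls, PhenoDesign(seed=3))


@pytest.fixture
def toy_panel():
    """5 genotypes x 4 markers, no missing calls."""
    dosage = np.array([
        [0, 2, 1, 0],
        [2, 0, 0, 2],
        [0, 2, 2, 0],
        [1, 1, 0, 2],
        [2, 0, 1, 0],
    ], dtype=float)
    mm = pd.DataFrame({
        "marker": ["m1", "m2", "m3", "m4"],
        "chromosome": ["1H", "1H", "2H", "2H"],
        "cM": [0.0, 10.0, 5.0, 25.0],
    })
    return GenotypePanel([f"g{i}" for i in range(5)], ["unknown"] * 5, dosage, mm)


def balanced_pheno(values_fn, genotypes=("gA", "gB"), traits=("Til",),
                   replicates=2):
    """Build a balanced 2-treatment x 2-year phenotype table; values_fn
    maps (genotype, treatment, year, rep, trait) -> value."""
    rows = []
    for g in genotypes:
        for t in ("control", "drought"):
            for y in (2014, 2015):
                for r in range(1, replicates + 1):
                    for tr in traits:
                        rows.append((g, t, y, r, tr, values_fn(g, t, y, r, tr)))
    return pd.DataFrame(rows, columns=["genotype", "treatment", "year",
                                       "replicate", "trait", "value"])
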