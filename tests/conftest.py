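import numpy as np
import pandas as pd
import pytest

from germscan.io import A, B, HET, MISSING, GenotypeMatrix


@pytest.fixture
def tiny_matrix() -> GenotypeMatrix:
    """2 accessions x 2 loci covering all four call states."""
    return GenotypeMatrix(
        ["acc1", "acc2"],
        ["L1", "L2"],
        np.array([[A, B], [HET, MISSING]], dtype=np.int8),
    )


@pytest.fixture
def small_panel():
    """4 accessions in two subgroups, 3 loci, hand-checkable frequencies."""
    g = GenotypeMatrix(
        ["a1", "a2", "b1", "b2"],
        ["L1", "L2", "L3"],
        np.array(
            [
                [A, A, MISSING],
                [A, HET, MISSING],
                [B, B, A],
                [A, B, A],
            ],
            dtype=np.int8,
        ),
    )
    metadata = pd.DataFrame(
        {
            "accession_id": ["a1", "a2", "b1", "b2"],
            "subgroup": ["CL", "CL", "MCC", "MCC"],
            "country": ["China"] * 4,
            "decade": ["pre-1950s", "pre-1950s", "1980s", "2000s"],
        }
    )
    catalog = pd.DataFrame(
        {
            "locus_id": ["L1", "L2", "L3"],
            "gene_name": ["g1", "g2", "g3"],
            "trait_category": ["yield", "quality", "adaptation"],
            "favorable_allele": ["A", "A", "B"],
        }
    )
    return g, metadata, catalog


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
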