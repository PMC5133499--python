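import numpy as np
import pandas as pd
import pytest

from owscore.dataio import GenotypeMatrix
from owscore.pedigree import phi_blocks, validate_pedigree
from owscore.phenotype import TraitVector


def make_geno(dosages, sample_ids=None) -> GenotypeMatrix:
    """Wrap a plain dosage array as a GenotypeMatrix with synthetic metadata."""
    G = np.asarray(dosages, dtype=float)
    ids = sample_ids or [f"I{k}" for k in range(G.shape[0])]
    meta = pd.DataFrame(
        {
            "id": [f"v{m + 1}" for m in range(G.shape[1])],
            "chrom": "1",
            "pos": np.arange(1, G.shape[1] + 1),
            "coded_allele": "A",
        }
    )
    return GenotypeMatrix(G, meta, list(ids))


def singleton_phi(n):
    """Kinship blocks for n unrelated singletons I0..I{n-1} (Phi = identity)."""
    peds = [
        validate_pedigree([(f"F{k}", f"I{k}", None, None, 1)]) for k in range(n)
    ]
    return peds, phi_blocks(peds)


@pytest.fixture
def toy_singletons():
    """The 4-singleton, single-variant worked example: T_OW = 4."""
    peds, phi = singleton_phi(4)
    geno = make_geno([[0.0], [1.0], [0.0], [1.0]])
    trait = TraitVector(
        np.array([-1.0, 1.0, -1.0, 1.0]),
        ["I0", "I1", "I2", "I3"],
        grand_mean_removed=True,
    )
    return geno, trait, phi


NUCLEAR_ROWS = [
    ("FAM1", "F", "0", "0", "1"),
    ("FAM1", "M", "0", "0", "2"),
    ("FAM1", "C1", "F", "M", "1"),
    ("FAM1", "C2", "F", "M", "2"),
]


@pytest.fixture
def nuclear_family():
    return validate_pedigree(NUCLEAR_ROWS)
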