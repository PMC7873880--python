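import numpy as np
import pandas as pd
import pytest

from pleiolink.genotypes import MAIZE_LIKE, GenotypeMatrix, filter_markers, generate_genotypes


def make_panel(dosages, chrom=None, pos=None) -> GenotypeMatrix:
    """Hand-built panel from a dosage matrix (individuals x markers)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    chrom = ["1"] * m if chrom is None else [str(c) for c in chrom]
    if pos is None:
        pos = []
        seen = {}
        for c in chrom:
            seen[c] = seen.get(c, 0) + 1000
            pos.append(seen[c])
    mm = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": [f"m{j}" for j in range(m)],
            "a1": "A",
            "a2": "T",
        }
    )
    ids = np.array([f"i{i}" for i in range(n)], dtype=object)
    return GenotypeMatrix(dosages, mm, ids)


@pytest.fixture(scope="session")
def maize_panel():
    """Filtered mid-size maize-like panel shared across selection/MLM tests."""
    G = generate_genotypes(300, 2, 300, MAIZE_LIKE, seed=42)
    return filter_markers(G)


@pytest.fixture(scope="session")
def tiny_panel():
    """Very small filtered panel for dense-oracle comparisons."""
    G = generate_genotypes(30, 2, 30, MAIZE_LIKE, seed=3)
    return filter_markers(G, min_mac=2)
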