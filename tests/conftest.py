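import numpy as np
import pandas as pd
import pytest

import immunocycle as ic


@pytest.fixture(scope="session")
def tiny_cds() -> dict[str, str]:
    """Two short stop-free coding sequences."""
    return {
        "GENE1": "ATGGCTAAATTTCCCGGG",
        "GENE2": "ATGTGTACTGCTAAACAT",
    }


@pytest.fixture(scope="session")
def small_opportunities():
    cds = ic.generate_cds(n_genes=8, codons=120, seed=13)
    return cds, ic.build_opportunities(cds)


@pytest.fixture()
def toy_expression() -> pd.DataFrame:
    rng = np.random.default_rng(42)
    genes = [f"G{i}" for i in range(20)]
    samples = [f"S{j}" for j in range(6)]
    return pd.DataFrame(rng.uniform(0, 10, (20, 6)), index=genes, columns=samples)


@pytest.fixture()
def toy_catalog() -> pd.DataFrame:
    # 4 samples; contexts chosen so transitions and transversions are known
    rows = [
        ("A", "G1", "synonymous", "ACA", "T", 0.30),
        ("A", "G1", "missense", "ACA", "T", 0.35),
        ("A", "G2", "missense", "TCT", "G", 0.25),
        ("A", "G2", "nonsense", "ATA", "A", 0.40),
        ("B", "G1", "synonymous", "GCG", "T", 0.20),
        ("B", "G2", "missense", "ATG", "C", 0.20),
        ("B", "G1", "missense", "ACT", "G", 0.22),
        ("C", "G2", "synonymous", "TTC", "C", 0.50),
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "gene", "impact", "ref_tri", "alt", "vaf"]
    )
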