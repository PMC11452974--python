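import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from itsakit import ChannelDesign, ProteinQuantTable, default_10plex

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def small_design(n_control: int = 2, n_treated: int = 2) -> ChannelDesign:
    pairs = [(f"C{i}", "control") for i in range(n_control)]
    pairs += [(f"T{i}", "treated") for i in range(n_treated)]
    return ChannelDesign.from_pairs("plex1", pairs)


def make_table(
    abundances: np.ndarray,
    design: ChannelDesign | None = None,
    pep: np.ndarray | None = None,
    unique: np.ndarray | None = None,
    accessions: list[str] | None = None,
) -> ProteinQuantTable:
    """Assemble a quant table from a (proteins x channels) matrix."""
    abundances = np.asarray(abundances, dtype=float)
    n, n_chan = abundances.shape
    if design is None:
        design = default_10plex() if n_chan == 10 else small_design(n_chan // 2, n_chan - n_chan // 2)
    assert len(design.labels) == n_chan
    data = pd.DataFrame(
        {
            "accession": accessions or [f"P{i:04d}" for i in range(n)],
            "gene_symbol": [f"G{i}" for i in range(n)],
            "sum_pep_score": pep if pep is not None else np.full(n, 10.0),
            "unique_peptides": unique if unique is not None else np.full(n, 3),
        }
    )
    for j, label in enumerate(design.labels):
        data[label] = abundances[:, j]
    return ProteinQuantTable(data, design)


@pytest.fixture
def rng():
    return np.random.default_rng(20240913)
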