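import numpy as np
import pandas as pd
import pytest

from baitcall.quant_io import QuantTable
from baitcall.synthetic_data import SimConfig, generate_apms_dataset


def make_quant_table(rows):
    """Build a QuantTable from (accession, unique_peptides, bait, control) tuples."""
    accs = [r[0] for r in rows]
    meta = pd.DataFrame(
        {
            "entry_name": [f"{a}_TEST" for a in accs],
            "protein_name": [f"protein {a}" for a in accs],
            "unique_peptides": [r[1] for r in rows],
        },
        index=pd.Index(accs, name="accession"),
    )
    bait = np.array([r[2] for r in rows], dtype=float)
    control = np.array([r[3] for r in rows], dtype=float)
    return QuantTable(meta=meta, bait=bait, control=control)


@pytest.fixture(scope="session")
def spikein_dataset():
    """Well-separated spike-in dataset used across enrichment/null-model/pipeline tests."""
    cfg = SimConfig(
        n_background=2000,
        n_interactors=80,
        n_exclusive=6,
        peptide_count_range=(2, 25),
        seed=1,
    )
    return cfg, *generate_apms_dataset(cfg)
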