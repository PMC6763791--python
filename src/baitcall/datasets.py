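"""Loaders for the small text fixtures bundled with the package.

Two fixtures ship with baitcall: the published curated interactor table of
the CB2 pulldown screen (bait row plus 83 prey proteins, six of them
bait-exclusive) and the six tryptic peptides by which p62/SQSTM1 was
identified in that screen. The p62 *sequence* itself is not bundled;
:func:`p62_scaffold` builds a synthetic 440-residue stand-in embedding the
six real peptides as tryptic fragments, which preserves the coverage
arithmetic (103 covered residues of 440 = 23.4%).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .quant_io import read_interactor_table
from .synthetic_data import generate_scaffold_with_peptides

#: Length of human p62/SQSTM1 in residues.
P62_LENGTH = 440

#: Accession of the bait (CB2 receptor) row in the curated table.
BAIT_ACCESSION = "P34972"


def _data_path(name: str):
    return resources.files("baitcall.data").joinpath(name)


def load_curated_interactors() -> pd.DataFrame:
    """The published curated interactor table (bait + 83 interactors)."""
    with resources.as_file(_data_path("table2_cb2_interactors.tsv")) as p:
        return read_interactor_table(p)


def load_p62_peptides() -> list[str]:
    """The six tryptic peptides identifying p62/SQSTM1."""
    text = _data_path("p62_tryptic_peptides.txt").read_text(encoding="utf-8")
    return [l.strip() for l in text.splitlines() if l.strip() and not l.startswith("#")]


def p62_scaffold(seed: int = 13) -> str:
    """Synthetic 440-residue scaffold embedding the six real p62 peptides."""
    return generate_scaffold_with_peptides(load_p62_peptides(), P62_LENGTH, seed=seed)
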