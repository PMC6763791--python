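"""In-silico tryptic digestion and peptide-based sequence coverage.

Trypsin cleaves C-terminal to lysine (K) or arginine (R) unless the next
residue is proline (P). Coverage maps observed peptides back onto the
protein by exact substring matching (no I/L equivalence, no modifications):
every occurrence of every peptide marks its residues covered, overlaps are
counted once, and percent coverage is 100 * covered / length rounded
half-up to one decimal — the formatting of the published interactor table.
Intervals are 0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError
from .quant_io import AMINO_ACIDS, round_half_up

_VALID = set(AMINO_ACIDS)


@dataclass
class CoverageResult:
    accession: str
    sequence_length: int
    covered_residues: int
    percent: float  # 100 * covered / length, one decimal, half-up
    peptide_hits: list[tuple[str, int, int]] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - _VALID
    if bad:
        raise FormatError(
            f"invalid residue character(s) {sorted(bad)} in sequence"
        )
    return seq


def tryptic_digest(sequence: str, missed_cleavages: int = 0) -> list[str]:
    """Fragments of a tryptic digest, in N-to-C order.

    Cleavage occurs after K or R except when the following residue is P.
    With ``missed_cleavages`` m, every concatenation of up to m+1 adjacent
    fully-cleaved fragments is also returned (order preserved: by start
    position, then by span).
    """
    seq = _check_sequence(sequence)
    if not seq:
        return []
    cuts = [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    bounds = [0] + cuts + [len(seq)]
    base = [seq[bounds[i]: bounds[i + 1]] for i in range(len(bounds) - 1)]
    if missed_cleavages <= 0:
        return base
    out: list[str] = []
    for i in range(len(base)):
        for span in range(1, missed_cleavages + 2):
            if i + span > len(base):
                break
            out.append("".join(base[i: i + span]))
    return out


def compute_coverage(
    sequence: str, observed_peptides: list[str], accession: str = ""
) -> CoverageResult:
    """Map observed peptides onto a protein sequence.

    Every exact occurrence of every peptide marks its residues covered;
    overlapping hits count each residue once. Peptides without any exact
    match contribute nothing and are reported in ``unmatched``.
    """
    seq = _check_sequence(sequence)
    mask = np.zeros(len(seq), dtype=bool)
    hits: list[tuple[str, int, int]] = []
    unmatched: list[str] = []
    for pep in observed_peptides:
        p = pep.upper()
        if not p:
            continue
        start = seq.find(p)
        if start < 0:
            unmatched.append(p)
            continue
        while start >= 0:
            end = start + len(p)
            mask[start:end] = True
            hits.append((p, start, end))
            start = seq.find(p, start + 1)
    covered = int(mask.sum())
    percent = round_half_up(100.0 * covered / len(seq), 1) if seq else 0.0
    return CoverageResult(
        accession=accession,
        sequence_length=len(seq),
        covered_residues=covered,
        percent=percent,
        peptide_hits=hits,
        unmatched=unmatched,
    )
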