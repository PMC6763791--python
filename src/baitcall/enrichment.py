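"""Per-protein enrichment records and replicate quality control.

Enrichment of a prey protein is summarized as the ratio of its mean bait-arm
intensity to its mean control-arm intensity; the log2 of that ratio feeds
the background null model. A protein detected in the bait arm but with zero
signal in every control replicate is *bait-exclusive*: its ratio is
undefined (flagged, never infinite). Proteins whose larger arm mean does not
exceed the intensity floor (default 1000, the ">1,000" working range of the
screen) are excluded from null-model fitting but retained in the record
list.

Replicate agreement is scored as pairwise Pearson correlation on log10
intensities of co-detected proteins; the screen's acceptance rule is
r > 0.90 for every within-arm pair, expressed as variation = 1 - min(r)
below 10%.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import QCError
from .quant_io import QuantTable

DEFAULT_INTENSITY_FLOOR = 1000.0


@dataclass
class EnrichmentRecord:
    """Arm means and enrichment ratio for one protein.

    ``ratio``/``log2_ratio`` are None when undefined (control mean of 0).
    ``exclusive`` marks bait-only detection; ``passes_floor`` marks
    max(mean_bait, mean_control) > intensity_floor.
    """

    accession: str
    mean_bait: float
    mean_control: float
    ratio: float | None
    log2_ratio: float | None
    exclusive: bool
    passes_floor: bool
    unique_peptides: int = 0


@dataclass
class ReplicateQC:
    """Pairwise within-arm Pearson correlations on log10 intensities."""

    pairwise_r: dict[tuple[str, int, int], float] = field(default_factory=dict)
    variation: float = 0.0  # 1 - min pairwise r
    pass_qc: bool = True
    threshold: float = 0.10


def compute_enrichment(
    table: QuantTable,
    intensity_floor: float = DEFAULT_INTENSITY_FLOOR,
    arm_summary: str = "mean",
) -> list[EnrichmentRecord]:
    """Compute one :class:`EnrichmentRecord` per protein.

    Arm summaries are arithmetic means of the replicate intensities
    (``arm_summary="geometric"`` switches to a geometric mean of detected
    replicates). A zero replicate within an otherwise detected protein
    contributes 0 to the arithmetic mean; no imputation is performed.
    """
    if arm_summary not in ("mean", "geometric"):
        raise ValueError(f"unknown arm_summary {arm_summary!r}")

    def summarize(row: np.ndarray) -> float:
        if arm_summary == "mean":
            return float(np.mean(row))
        detected = row[row > 0]
        if detected.size == 0:
            return 0.0
        return float(np.exp(np.mean(np.log(detected))))

    records: list[EnrichmentRecord] = []
    peptides = table.meta["unique_peptides"].to_numpy()
    for i, acc in enumerate(table.accessions):
        mb = summarize(table.bait[i])
        mc = summarize(table.control[i])
        exclusive = mc == 0.0 and mb > 0.0
        if mc > 0.0:
            ratio = mb / mc
            log2_ratio = math.log2(ratio) if ratio > 0 else None
        else:
            ratio = None
            log2_ratio = None
        records.append(
            EnrichmentRecord(
                accession=acc,
                mean_bait=mb,
                mean_control=mc,
                ratio=ratio,
                log2_ratio=log2_ratio,
                exclusive=exclusive,
                passes_floor=max(mb, mc) > intensity_floor,
                unique_peptides=int(peptides[i]),
            )
        )
    return records


def replicate_qc(table: QuantTable, threshold: float = 0.10) -> ReplicateQC:
    """Score within-arm replicate agreement.

    For every replicate pair within each arm, Pearson r is computed over
    proteins detected (> 0) in both members of the pair, on log10
    intensities. A pair with fewer than 2 co-detected proteins raises
    :class:`~baitcall.errors.QCError`.
    """
    pairwise: dict[tuple[str, int, int], float] = {}
    for arm_name, arm in (("bait", table.bait), ("control", table.control)):
        k = arm.shape[1]
        for a, b in itertools.combinations(range(k), 2):
            both = (arm[:, a] > 0) & (arm[:, b] > 0)
            if both.sum() < 2:
                raise QCError(
                    f"{arm_name} replicates {a + 1}/{b + 1}: "
                    f"fewer than 2 co-detected proteins"
                )
            x = np.log10(arm[both, a])
            y = np.log10(arm[both, b])
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                # constant log-intensities: agreement is perfect by scaling
                r = 1.0
            else:
                r = float(stats.pearsonr(x, y).statistic)
            pairwise[(arm_name, a + 1, b + 1)] = r
    variation = 1.0 - min(pairwise.values())
    return ReplicateQC(
        pairwise_r=pairwise,
        variation=variation,
        pass_qc=variation < threshold,
        threshold=threshold,
    )
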