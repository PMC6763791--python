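"""Evidence filters turning classified records into curated interactor calls.

Two filters follow the background classification: a unique-peptide floor
(default 2 — a protein identified by a single peptide is not reported, no
matter how enriched) and an optional contaminant-frequency filter against a
user-supplied library of how often each protein shows up in unrelated
control pulldowns ("frequent flyers"). Borderline proteins are excluded by
default; a flag keeps them. Filters commute: each only ever flips ``kept``
to False and records the first applicable reason in a fixed priority order
(class-based first, then peptides, then frequency).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .enrichment import EnrichmentRecord
from .errors import DataError
from .quant_io import write_interactor_table

logger = logging.getLogger(__name__)

DEFAULT_MIN_UNIQUE_PEPTIDES = 2
DEFAULT_MAX_FREQUENCY = 0.5

REJECT_REASONS = (
    "insufficient_peptides",
    "frequent_flyer",
    "unspecific",
    "borderline_excluded",
)


@dataclass
class InteractorCall:
    accession: str
    label: str  # class from the null model
    unique_peptides: int
    kept: bool
    reject_reason: str | None = None

    def _reject(self, reason: str) -> None:
        self.kept = False
        if self.reject_reason is None:
            self.reject_reason = reason


def make_calls(
    classes: dict[str, str],
    records: list[EnrichmentRecord],
    keep_borderline: bool = False,
) -> list[InteractorCall]:
    """Seed calls from the classification: specific/exclusive start kept."""
    by_acc = {r.accession: r for r in records}
    calls: list[InteractorCall] = []
    for acc, label in classes.items():
        call = InteractorCall(
            accession=acc,
            label=label,
            unique_peptides=by_acc[acc].unique_peptides,
            kept=True,
        )
        if label == "unspecific":
            call._reject("unspecific")
        elif label == "borderline" and not keep_borderline:
            call._reject("borderline_excluded")
        calls.append(call)
    return calls


def filter_min_peptides(
    calls: list[InteractorCall],
    min_unique_peptides: int = DEFAULT_MIN_UNIQUE_PEPTIDES,
) -> list[InteractorCall]:
    """Reject kept calls identified by fewer than the minimum unique peptides."""
    for call in calls:
        if call.unique_peptides < min_unique_peptides and call.label in (
            "specific",
            "exclusive",
            "borderline",
        ):
            call._reject("insufficient_peptides")
    return calls


def filter_frequency(
    calls: list[InteractorCall],
    library: dict[str, float] | None,
    max_frequency: float = DEFAULT_MAX_FREQUENCY,
) -> list[InteractorCall]:
    """Reject calls seen too often in unrelated control pulldowns.

    Accessions absent from the library are treated as frequency 0. When no
    library is supplied the filter is skipped with a logged notice.
    """
    if library is None:
        logger.info("no frequency library supplied; frequency filter skipped")
        return calls
    for acc, f in library.items():
        if not 0.0 <= f <= 1.0:
            raise DataError(f"frequency {f} for {acc!r} outside [0, 1]")
    for call in calls:
        if library.get(call.accession, 0.0) > max_frequency:
            call._reject("frequent_flyer")
    return calls


def finalize_calls(
    calls: list[InteractorCall],
    records: list[EnrichmentRecord],
    meta=None,
    bait_accession: str | None = None,
    coverage: dict[str, float] | None = None,
) -> list[dict]:
    """Assemble curated table rows in the published order.

    Bait first (retained with its own stats even though it is not a prey),
    then bait-exclusive proteins, then kept specific proteins by descending
    enrichment ratio. ``meta`` is the QuantTable metadata frame (optional
    names/weights); ``coverage`` optionally overrides sequence coverage.
    """
    by_acc = {r.accession: r for r in records}

    def meta_of(acc: str, col: str):
        if meta is not None and col in meta.columns and acc in meta.index:
            v = meta.loc[acc, col]
            return None if v is None or (isinstance(v, float) and v != v) else v
        return None

    def row(acc: str) -> dict:
        rec = by_acc[acc]
        cov = None
        if coverage and acc in coverage:
            cov = coverage[acc]
        elif meta_of(acc, "sequence_coverage_pct") is not None:
            cov = float(meta_of(acc, "sequence_coverage_pct"))
        return {
            "accession": acc,
            "entry_name": meta_of(acc, "entry_name") or "",
            "protein_name": meta_of(acc, "protein_name") or "",
            "unique_peptides": rec.unique_peptides,
            "sequence_coverage_pct": cov,
            "molecular_weight_kda": meta_of(acc, "molecular_weight_kda"),
            "ratio": rec.ratio,
            "exclusive": rec.exclusive,
        }

    kept = [c for c in calls if c.kept and c.accession != bait_accession]
    exclusives = sorted(
        (c for c in kept if c.label == "exclusive"), key=lambda c: c.accession
    )
    ranked = sorted(
        (c for c in kept if c.label != "exclusive"),
        key=lambda c: (-(by_acc[c.accession].ratio or 0.0), c.accession),
    )
    rows: list[dict] = []
    if bait_accession is not None and bait_accession in by_acc:
        rows.append(row(bait_accession))
    rows.extend(row(c.accession) for c in exclusives)
    rows.extend(row(c.accession) for c in ranked)
    return rows


def write_rejection_log(calls: list[InteractorCall], path) -> None:
    """TSV of rejected calls with their primary rejection reason."""
    import pandas as pd

    rejected = [
        {
            "accession": c.accession,
            "class": c.label,
            "unique_peptides": c.unique_peptides,
            "reject_reason": c.reject_reason,
        }
        for c in calls
        if not c.kept
    ]
    pd.DataFrame(
        rejected, columns=["accession", "class", "unique_peptides", "reject_reason"]
    ).to_csv(path, sep="\t", index=False)


__all__ = [
    "InteractorCall",
    "make_calls",
    "filter_min_peptides",
    "filter_frequency",
    "finalize_calls",
    "write_rejection_log",
    "write_interactor_table",
    "DEFAULT_MIN_UNIQUE_PEPTIDES",
    "DEFAULT_MAX_FREQUENCY",
    "REJECT_REASONS",
]
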