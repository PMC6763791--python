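"""End-to-end orchestration: quant table -> enrichment -> null model ->
evidence filters -> curated interactor table, with QC and model reports.

Every run is deterministic given its inputs and parameters; each stage's
intermediate is serialized and the run log records parameter values, input
checksums and the protein counts entering/leaving each filter.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import enrichment, evidence_filters, null_model, quant_io
from .errors import BaitcallError, DataError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters of a full interactor-calling run (defaults = screen values)."""

    quant_path: str | Path | None = None
    column_map: dict | None = None
    bait_accession: str | None = None
    intensity_floor: float = 1000.0
    bin_width: float = 0.2
    fraction_of_peak: float = 0.10
    borderline_band: float | None = None  # defaults to bin_width
    min_unique_peptides: int = 2
    frequency_library_path: str | Path | None = None
    max_frequency: float = 0.5
    keep_borderline: bool = False
    arm_summary: str = "mean"
    qc_threshold: float = 0.10
    seed: int = 0
    output_dir: str | Path = "results"


@dataclass
class PipelineResult:
    records: list = field(default_factory=list)
    qc: enrichment.ReplicateQC | None = None
    report: null_model.NullModelReport | None = None
    calls: list = field(default_factory=list)
    rows: list = field(default_factory=list)
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def kept_accessions(self) -> set[str]:
        return {c.accession for c in self.calls if c.kept}


def read_frequency_library(path) -> dict[str, float]:
    """Two-column TSV: accession, observed frequency in control pulldowns."""
    lib: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("accession\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"{path}: line {lineno}: expected 2 fields")
            f = float(parts[1])
            if not 0.0 <= f <= 1.0:
                raise DataError(f"{path}: line {lineno}: frequency {f} outside [0, 1]")
            lib[parts[0]] = f
    return lib


def analyze_quant_table(
    table: quant_io.QuantTable,
    config: PipelineConfig | None = None,
    frequency_library: dict[str, float] | None = None,
) -> PipelineResult:
    """Run the full calling cascade in memory on a parsed QuantTable."""
    cfg = config or PipelineConfig()
    band = cfg.borderline_band if cfg.borderline_band is not None else cfg.bin_width

    result = PipelineResult()
    result.stage_counts["input_proteins"] = table.n_proteins

    result.qc = enrichment.replicate_qc(table, threshold=cfg.qc_threshold)
    result.records = enrichment.compute_enrichment(
        table, intensity_floor=cfg.intensity_floor, arm_summary=cfg.arm_summary
    )

    hist = null_model.build_histogram(result.records, bin_width=cfg.bin_width)
    fit = null_model.fit_gaussian(hist)
    thr = null_model.derive_threshold(
        fit, fraction=cfg.fraction_of_peak, borderline_band=band
    )
    classes = null_model.classify(result.records, thr)
    result.report = null_model.NullModelReport(
        histogram=hist, fit=fit, threshold=thr,
        class_counts=dict(Counter(classes.values())),
    )
    result.stage_counts["fit_ratios"] = hist.n_total
    for cls in null_model.CLASSES:
        result.stage_counts[f"class_{cls}"] = result.report.class_counts.get(cls, 0)

    calls = evidence_filters.make_calls(
        classes, result.records, keep_borderline=cfg.keep_borderline
    )
    evidence_filters.filter_min_peptides(calls, cfg.min_unique_peptides)
    evidence_filters.filter_frequency(calls, frequency_library, cfg.max_frequency)
    result.calls = calls
    result.stage_counts["kept"] = sum(c.kept for c in calls)
    result.stage_counts["rejected"] = sum(not c.kept for c in calls)

    result.rows = evidence_filters.finalize_calls(
        calls, result.records, meta=table.meta, bait_accession=cfg.bait_accession
    )
    return result


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-to-file pipeline run; writes all reports under ``output_dir``."""
    if config.quant_path is None:
        raise DataError("config.quant_path is required for a file-based run")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("baitcall")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        provenance = {
            "parameters": {
                k: (str(v) if isinstance(v, Path) else v)
                for k, v in asdict(config).items()
            },
            "input_sha256": {"quant": _sha256(config.quant_path)},
        }
        if config.frequency_library_path:
            provenance["input_sha256"]["frequency_library"] = _sha256(
                config.frequency_library_path
            )
        logger.info("provenance: %s", json.dumps(provenance, sort_keys=True))

        table = quant_io.read_quant_table(config.quant_path, column_map=config.column_map)
        library = (
            read_frequency_library(config.frequency_library_path)
            if config.frequency_library_path
            else None
        )
        try:
            result = analyze_quant_table(table, config, frequency_library=library)
        except BaitcallError as exc:
            logger.error("pipeline aborted: %s", exc)
            raise
        logger.info("stage counts: %s", json.dumps(result.stage_counts))

        quant_io.write_interactor_table(result.rows, out / "interactors.tsv")
        evidence_filters.write_rejection_log(result.calls, out / "rejected.tsv")
        result.report.to_json(out / "null_model.json")
        qc_rows = [
            {"arm": arm, "replicate_a": a, "replicate_b": b, "pearson_r": r}
            for (arm, a, b), r in result.qc.pairwise_r.items()
        ]
        qc_df = pd.DataFrame(qc_rows)
        qc_df["variation"] = result.qc.variation
        qc_df["pass"] = result.qc.pass_qc
        qc_df.to_csv(out / "qc.tsv", sep="\t", index=False)
        with open(out / "provenance.json", "w", encoding="utf-8") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
        return result
    finally:
        root.removeHandler(handler)
        handler.close()
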