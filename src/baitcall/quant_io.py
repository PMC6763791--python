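"""Readers and writers for every tabular/sequence artifact the pipeline touches.

The central container is :class:`QuantTable`: one row per protein with the
replicate intensity design of the pulldown (bait arm vs. control arm, three
biological replicates each in the original study). The curated interactor
table is serialized in the published layout, where bait-exclusive proteins
carry the literal ratio cell ``"Only in CB2"``; internally exclusivity is a
boolean flag, never a magic number, so no sentinel leaks into arithmetic.

All tables are tab-separated UTF-8 with a header row; parsing is
locale-independent (decimal point, never comma). Intensities of exactly 0
mean "not detected"; no pseudocount is added at the I/O layer.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

#: Column headers of the curated interactor table, in published order.
INTERACTOR_COLUMNS = [
    "Entry",
    "Entry name",
    "Protein names",
    "Unique peptides",
    "Sequence coverage [%]",
    "Molecular weight [kDa]",
    "Ratio CB2/ctrl",
]

#: Literal ratio cell for proteins detected only in the bait pulldown.
EXCLUSIVE_SENTINEL = "Only in CB2"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, matching the table formatting convention."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class QuantTable:
    """Per-protein replicate intensities for the bait and control arms.

    Parameters
    ----------
    meta
        DataFrame indexed by unique protein accession with columns
        ``entry_name``, ``protein_name``, ``unique_peptides`` and the
        optional ``molecular_weight_kda`` / ``sequence_coverage_pct``.
    bait, control
        Arrays of shape ``(n_proteins, n_replicates)`` holding nonnegative
        intensities in arbitrary MS units, row-aligned with ``meta``.
    """

    meta: pd.DataFrame
    bait: np.ndarray
    control: np.ndarray

    def __post_init__(self) -> None:
        self.bait = np.asarray(self.bait, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        n = len(self.meta)
        if self.bait.ndim != 2 or self.control.ndim != 2:
            raise FormatError("intensity arrays must be 2-D (proteins x replicates)")
        if self.bait.shape[0] != n or self.control.shape[0] != n:
            raise FormatError("intensity arrays must have one row per protein")
        if self.bait.shape[1] < 2 or self.control.shape[1] < 2:
            raise FormatError("each arm needs at least 2 replicates")
        if not self.meta.index.is_unique:
            dup = self.meta.index[self.meta.index.duplicated()][0]
            raise FormatError(f"duplicate accession {dup!r}")
        if np.any(self.bait < 0) or np.any(self.control < 0):
            raise FormatError("negative intensity encountered")

    @property
    def accessions(self) -> list[str]:
        return list(self.meta.index)

    @property
    def n_proteins(self) -> int:
        return len(self.meta)

    @property
    def n_replicates(self) -> int:
        return self.bait.shape[1]

    def equals(self, other: "QuantTable") -> bool:
        return (
            self.meta.equals(other.meta)
            and np.array_equal(self.bait, other.bait)
            and np.array_equal(self.control, other.control)
        )


@dataclass
class EdgeList:
    """Undirected simple edges between node identifiers.

    Self-loops are rejected; duplicate pairs (in either orientation) are
    collapsed, keeping the first score seen. ``scores`` is None when the
    input carried no confidence column.
    """

    edges: list[tuple[str, str]] = field(default_factory=list)
    scores: list[float] | None = None

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], float | None] = {}
        order: list[tuple[str, str]] = []
        scores = self.scores if self.scores is not None else [None] * len(self.edges)
        if len(scores) != len(self.edges):
            raise FormatError("scores must align with edges")
        for (u, v), s in zip(self.edges, scores):
            if u == v:
                raise FormatError(f"self-loop on node {u!r}")
            key = (u, v) if u <= v else (v, u)
            if key not in seen:
                seen[key] = s
                order.append(key)
        self.edges = order
        if self.scores is not None:
            self.scores = [seen[k] for k in order]

    def __len__(self) -> int:
        return len(self.edges)

    def nodes(self) -> set[str]:
        return {n for e in self.edges for n in e}


# ---------------------------------------------------------------------------
# quantification tables
# ---------------------------------------------------------------------------

_DEFAULT_META_COLS = {
    "accession": "accession",
    "entry_name": "entry_name",
    "protein_name": "protein_name",
    "unique_peptides": "unique_peptides",
    "molecular_weight_kda": "molecular_weight_kda",
    "sequence_coverage_pct": "sequence_coverage_pct",
}


def _replicate_columns(columns: list[str], prefix: str) -> list[str]:
    cols = [c for c in columns if c.startswith(prefix)]

    def index_of(c: str) -> int:
        try:
            return int(c[len(prefix):])
        except ValueError as exc:
            raise FormatError(f"replicate column {c!r} is not {prefix}<int>") from exc

    return sorted(cols, key=index_of)


def read_quant_table(path, column_map: dict[str, str] | None = None) -> QuantTable:
    """Parse a TSV of per-protein replicate intensities.

    The default layout names replicate columns ``bait_1..bait_k`` and
    ``control_1..control_k``; ``column_map`` remaps metadata column names
    (keys: accession, entry_name, protein_name, unique_peptides, and the
    optional molecular_weight_kda / sequence_coverage_pct) plus the
    replicate prefixes ``bait_prefix`` / ``control_prefix`` to absorb
    foreign layouts.
    """
    cmap = dict(_DEFAULT_META_COLS)
    bait_prefix, control_prefix = "bait_", "control_"
    if column_map:
        bait_prefix = column_map.pop("bait_prefix", bait_prefix)
        control_prefix = column_map.pop("control_prefix", control_prefix)
        cmap.update(column_map)

    df = pd.read_csv(path, sep="\t", dtype=str)
    for logical in ("accession", "unique_peptides"):
        if cmap[logical] not in df.columns:
            raise FormatError(f"missing mandatory column {cmap[logical]!r} in {path}")
    bait_cols = _replicate_columns(list(df.columns), bait_prefix)
    ctrl_cols = _replicate_columns(list(df.columns), control_prefix)
    if len(bait_cols) < 2 or len(ctrl_cols) < 2:
        raise FormatError(f"need >=2 replicate columns per arm in {path}")
    if len(bait_cols) != len(ctrl_cols):
        raise FormatError(
            f"ragged replicate counts: {len(bait_cols)} bait vs {len(ctrl_cols)} control"
        )

    def parse_block(cols: list[str]) -> np.ndarray:
        block = np.empty((len(df), len(cols)))
        for j, c in enumerate(cols):
            for i, raw in enumerate(df[c]):
                try:
                    v = float(raw)
                except (TypeError, ValueError) as exc:
                    raise FormatError(
                        f"{path}: row {i + 2}: unparseable intensity {raw!r} in column {c}"
                    ) from exc
                if not np.isfinite(v) or v < 0:
                    raise FormatError(
                        f"{path}: row {i + 2}: invalid intensity {raw!r} in column {c}"
                    )
                block[i, j] = v
        return block

    bait = parse_block(bait_cols)
    control = parse_block(ctrl_cols)

    meta = pd.DataFrame(index=pd.Index(df[cmap["accession"]], name="accession"))
    meta["entry_name"] = (
        df[cmap["entry_name"]].values if cmap["entry_name"] in df.columns else ""
    )
    meta["protein_name"] = (
        df[cmap["protein_name"]].values if cmap["protein_name"] in df.columns else ""
    )
    try:
        meta["unique_peptides"] = df[cmap["unique_peptides"]].astype(int).values
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer unique_peptides column") from exc
    for opt in ("molecular_weight_kda", "sequence_coverage_pct"):
        if cmap[opt] in df.columns:
            meta[opt] = pd.to_numeric(df[cmap[opt]], errors="coerce").values
    return QuantTable(meta=meta, bait=bait, control=control)


def write_quant_table(table: QuantTable, path) -> None:
    """Serialize a :class:`QuantTable` to the default TSV layout."""
    out = table.meta.reset_index()
    for j in range(table.n_replicates):
        out[f"bait_{j + 1}"] = table.bait[:, j]
    for j in range(table.n_replicates):
        out[f"control_{j + 1}"] = table.control[:, j]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# curated interactor table (published layout)
# ---------------------------------------------------------------------------


def write_interactor_table(rows, path) -> None:
    """Write curated calls in the published table layout.

    ``rows`` is an iterable of mappings with keys ``accession``,
    ``entry_name``, ``protein_name``, ``unique_peptides``,
    ``sequence_coverage_pct``, ``molecular_weight_kda``, ``ratio`` (float or
    None) and ``exclusive`` (bool). Exclusive rows print the sentinel
    string in the ratio column; numeric ratios print with one decimal.
    """
    records = []
    for r in rows:
        if r.get("exclusive"):
            ratio_cell = EXCLUSIVE_SENTINEL
        elif r.get("ratio") is None:
            ratio_cell = ""
        else:
            ratio_cell = f"{round_half_up(float(r['ratio']), 1):.1f}"
        cov = r.get("sequence_coverage_pct")
        mw = r.get("molecular_weight_kda")
        records.append(
            {
                "Entry": r["accession"],
                "Entry name": r.get("entry_name", ""),
                "Protein names": r.get("protein_name", ""),
                "Unique peptides": int(r["unique_peptides"]),
                "Sequence coverage [%]": "" if cov is None or pd.isna(cov) else cov,
                "Molecular weight [kDa]": "" if mw is None or pd.isna(mw) else mw,
                "Ratio CB2/ctrl": ratio_cell,
            }
        )
    pd.DataFrame(records, columns=INTERACTOR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_interactor_table(path) -> pd.DataFrame:
    """Parse a curated interactor table back into a tidy DataFrame.

    Returns one row per protein with a float ``ratio`` (NaN for exclusives)
    and a boolean ``exclusive`` column decoded from the sentinel cell.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in INTERACTOR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = pd.DataFrame(
        {
            "accession": df["Entry"],
            "entry_name": df["Entry name"],
            "protein_name": df["Protein names"],
            "unique_peptides": df["Unique peptides"].astype(int),
            "sequence_coverage_pct": pd.to_numeric(
                df["Sequence coverage [%]"], errors="coerce"
            ),
            "molecular_weight_kda": pd.to_numeric(
                df["Molecular weight [kDa]"], errors="coerce"
            ),
        }
    )
    raw_ratio = df["Ratio CB2/ctrl"].astype(str).str.strip()
    out["exclusive"] = raw_ratio == EXCLUSIVE_SENTINEL
    ratio = pd.to_numeric(raw_ratio.where(~out["exclusive"]), errors="coerce")
    bad = (~out["exclusive"]) & ratio.isna() & (raw_ratio != "")
    if bad.any():
        i = int(np.flatnonzero(bad.values)[0])
        raise FormatError(f"{path}: row {i + 2}: unparseable ratio {raw_ratio.iloc[i]!r}")
    out["ratio"] = ratio
    return out


# ---------------------------------------------------------------------------
# sequences, peptide lists, edge lists
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an accession -> uppercase sequence mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if not s:
            raise FormatError(f"{path}: empty sequence for {rec.id!r}")
        seqs[rec.id] = s
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=acc, description="") for acc, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_peptide_list(path) -> dict[str, list[str]]:
    """Read identified peptides per accession.

    Accepts two-column TSV lines ``accession<TAB>PEPTIDE`` or
    ``accession<TAB>PEP1,PEP2,...``; repeated accessions accumulate.
    Blank lines and ``#`` comments are skipped.
    """
    peptides: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 tab-separated fields")
            acc, peps = parts
            for p in peps.split(","):
                p = p.strip().upper()
                if p:
                    peptides.setdefault(acc, []).append(p)
    return peptides


def write_peptide_list(peptides: dict[str, list[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for acc, peps in peptides.items():
            fh.write(f"{acc}\t{','.join(peps)}\n")


def read_edge_list(path) -> EdgeList:
    """Read a two- or three-column TSV edge list (node, node[, score])."""
    edges: list[tuple[str, str]] = []
    scores: list[float] = []
    has_scores: bool | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise FormatError(f"{path}: line {lineno}: expected 2 or 3 fields")
            if has_scores is None:
                has_scores = len(parts) == 3
            elif has_scores != (len(parts) == 3):
                raise FormatError(f"{path}: line {lineno}: inconsistent column count")
            edges.append((parts[0].strip(), parts[1].strip()))
            if has_scores:
                try:
                    s = float(parts[2])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: unparseable score {parts[2]!r}"
                    ) from exc
                if not 0.0 <= s <= 1.0:
                    raise FormatError(f"{path}: line {lineno}: score {s} outside [0, 1]")
                scores.append(s)
    return EdgeList(edges=edges, scores=scores if has_scores else None)


def write_edge_list(edges: EdgeList, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if edges.scores is None:
            for u, v in edges.edges:
                fh.write(f"{u}\t{v}\n")
        else:
            for (u, v), s in zip(edges.edges, edges.scores):
                fh.write(f"{u}\t{v}\t{s}\n")
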