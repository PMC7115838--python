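"""Readers and writers for every external table the curation pipeline touches.

All tabular formats are plain TSV with a fixed header; protein sequences are
standard FASTA; alignment statistics arrive in BLAST tabular (``-outfmt 6``)
layout with 12 columns, optionally extended by a 13th ``ppos`` (percent
positives) column. Output row order is always a pure function of content
(ascending accession), never of input order, so repeated writes of the same
in-memory objects are byte-identical.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Extract-purification protocols compared in the study: two centrifugal
#: ultrafiltration preparations and two acetone-precipitation preparations.
METHODS: tuple[str, ...] = ("CF2", "CF4", "ACT1", "ACT3")

#: Water-soluble vs water-insoluble skeletal organic matrix fractions.
SOLUBILITIES: tuple[str, ...] = ("SSOM", "ISOM")

#: All (method, solubility) fraction cells, in canonical order.
FRACTIONS: tuple[tuple[str, str], ...] = tuple(
    (m, s) for m in METHODS for s in SOLUBILITIES
)

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")
_GO_RE = re.compile(r"^GO:\d{7}$")

EVIDENCE_COLUMNS = (
    "protein_accession",
    "peptide",
    "spectra_count",
    "significant",
    "score",
    "method",
    "solubility",
)
ANNOTATION_COLUMNS = (
    "accession",
    "n_term_complete",
    "signal_peptide",
    "tm_span_count",
    "gpi_anchor",
    "go_terms",
)
ORTHOLOG_COLUMNS = ("target_accession", "other_accession", "other_proteome", "relation")
ORTHOLOG_RELATIONS = ("one_to_one", "one_to_many", "many_to_many", "blastp_best_hit")


class TableFormatError(ValueError):
    """A file does not conform to its declared layout or types."""


class VocabularyError(TableFormatError):
    """A value falls outside a closed vocabulary (method, solubility, ...)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: sequence plus consumed (not computed) annotation flags.

    Signal-peptide, transmembrane-span, GPI-anchor and N-terminus-completeness
    calls come from external predictors and are inputs to this pipeline.
    """

    accession: str
    sequence: str
    description: str = ""
    n_term_complete: bool = False
    go_terms: frozenset[str] = field(default_factory=frozenset)
    signal_peptide: bool = False
    tm_span_count: int = 0
    gpi_anchor: bool = False

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.accession}: sequence must be non-empty")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.accession}: illegal residue(s) {sorted(bad)!r}"
            )
        if self.tm_span_count < 0:
            raise ValueError(f"{self.accession}: tm_span_count must be >= 0")
        for term in self.go_terms:
            if not _GO_RE.match(term):
                raise ValueError(f"{self.accession}: malformed GO id {term!r}")


@dataclass(frozen=True)
class PeptideEvidence:
    """One identified peptide for one protein in one method x solubility cell."""

    protein_accession: str
    peptide: str
    spectra_count: int
    significant: bool
    score: float
    method: str
    solubility: str

    def __post_init__(self) -> None:
        if len(self.peptide) < 1:
            raise ValueError("peptide must be non-empty")
        if self.spectra_count < 1:
            raise ValueError(
                f"{self.protein_accession}/{self.peptide}: spectra_count must be >= 1"
            )
        if self.score < 0:
            raise ValueError(f"{self.protein_accession}: score must be >= 0")
        if self.method not in METHODS:
            raise VocabularyError(f"unknown method {self.method!r}")
        if self.solubility not in SOLUBILITIES:
            raise VocabularyError(f"unknown solubility {self.solubility!r}")


@dataclass(frozen=True)
class AlignmentHit:
    """One target-vs-contaminant alignment with its tabular statistics."""

    query_accession: str
    subject_accession: str
    evalue: float
    percent_similarity: float
    align_length: int
    identical_positions: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not 0 <= self.percent_similarity <= 100:
            raise ValueError("percent_similarity must lie in [0, 100]")
        if self.align_length < 1:
            raise ValueError("align_length must be >= 1")
        if not 0 <= self.identical_positions <= self.align_length:
            raise ValueError("identical_positions must lie in [0, align_length]")


@dataclass(frozen=True)
class OrthologPair:
    """A link from one curated protein to a protein in a published skeletal proteome."""

    target_accession: str
    other_accession: str
    other_proteome: str
    relation: str

    def __post_init__(self) -> None:
        if self.relation not in ORTHOLOG_RELATIONS:
            raise VocabularyError(f"unknown ortholog relation {self.relation!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into bare records (accession, sequence, description).

    The accession is the first whitespace-delimited token of the header.
    Duplicate accessions and illegal residues are format errors naming the
    offending header's line number.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        accession = header.split()[0] if header.split() else ""
        if not accession:
            raise TableFormatError(f"{path}:{header_line}: empty FASTA header")
        if accession in seen:
            raise TableFormatError(
                f"{path}:{header_line}: duplicate accession {accession!r} "
                f"(first seen at line {seen[accession]})"
            )
        sequence = "".join(chunks).upper()
        description = header[len(accession):].strip()
        try:
            record = ProteinRecord(accession, sequence, description)
        except ValueError as exc:
            raise TableFormatError(f"{path}:{header_line}: {exc}") from exc
        seen[accession] = header_line
        records.append(record)

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise TableFormatError(
                        f"{path}:{lineno}: sequence data before any FASTA header"
                    )
                chunks.append(line)
        _flush()

    if not records:
        logger.warning("FASTA file %s contains no sequences", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, sorted by accession, wrapped at ``width``."""
    path = Path(path)
    with open(path, "w") as handle:
        for rec in sorted(records, key=lambda r: r.accession):
            header = rec.accession if not rec.description else f"{rec.accession} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# generic TSV helpers
# ---------------------------------------------------------------------------

def _require_columns(frame: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")


def _parse_bool(value: str, where: str) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "1", "yes", "y"):
        return True
    if text in ("false", "0", "no", "n", ""):
        return False
    raise TableFormatError(f"{where}: cannot parse boolean {value!r}")


_BOOL_OUT = {True: "true", False: "false"}


# ---------------------------------------------------------------------------
# peptide evidence
# ---------------------------------------------------------------------------

def read_evidence_table(path: str | Path) -> list[PeptideEvidence]:
    """Read the long-format peptide-evidence TSV (one row per peptide per fraction)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(frame, EVIDENCE_COLUMNS, path)
    rows: list[PeptideEvidence] = []
    problems: list[str] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=2):  # 1-based + header
        where = f"{path}:row {idx}"
        try:
            rows.append(
                PeptideEvidence(
                    protein_accession=str(row.protein_accession),
                    peptide=str(row.peptide).upper(),
                    spectra_count=int(row.spectra_count),
                    significant=_parse_bool(row.significant, where),
                    score=float(row.score),
                    method=str(row.method),
                    solubility=str(row.solubility),
                )
            )
        except VocabularyError as exc:
            raise VocabularyError(f"{where}: {exc}") from exc
        except (ValueError, TypeError) as exc:
            problems.append(f"{where}: {exc}")
    if problems:
        raise TableFormatError("; ".join(problems))
    return rows


def write_evidence_table(rows: Iterable[PeptideEvidence], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "protein_accession": r.protein_accession,
                "peptide": r.peptide,
                "spectra_count": r.spectra_count,
                "significant": _BOOL_OUT[r.significant],
                "score": r.score,
                "method": r.method,
                "solubility": r.solubility,
            }
            for r in rows
        ],
        columns=list(EVIDENCE_COLUMNS),
    )
    frame = frame.sort_values(list(EVIDENCE_COLUMNS), kind="mergesort")
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

def read_blast_tabular(path: str | Path) -> list[AlignmentHit]:
    """Read BLAST ``-outfmt 6`` hits (12 columns, or 13 with trailing ``ppos``).

    ``percent_similarity`` is taken from the positives column (``ppos``) when
    present, else falls back to percent identity (``pident``) as a conservative
    proxy; which source applied is visible in the run report.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if frame.shape[1] not in (12, 13):
        raise TableFormatError(
            f"{path}: expected 12 or 13 tab-separated columns, found {frame.shape[1]}"
        )
    has_ppos = frame.shape[1] == 13
    hits: list[AlignmentHit] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        values = tuple(row)
        try:
            hits.append(
                AlignmentHit(
                    query_accession=str(values[0]),
                    subject_accession=str(values[1]),
                    evalue=float(values[10]),
                    percent_similarity=float(values[12] if has_ppos else values[2]),
                    align_length=int(values[3]),
                    identical_positions=min(
                        int(values[3]),
                        int(round(float(values[2]) / 100.0 * int(values[3]))),
                    ),
                )
            )
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"{path}:row {idx}: {exc}") from exc
    return hits


def write_blast_tabular(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits in the 13-column dialect (``ppos`` carries percent_similarity)."""
    ordered = sorted(
        hits, key=lambda h: (h.query_accession, h.subject_accession, h.evalue)
    )
    with open(path, "w") as handle:
        for h in ordered:
            pident = 100.0 * h.identical_positions / h.align_length
            fields = [
                h.query_accession,
                h.subject_accession,
                f"{pident:.2f}",
                str(h.align_length),
                str(h.align_length - h.identical_positions),
                "0",
                "1",
                str(h.align_length),
                "1",
                str(h.align_length),
                repr(h.evalue),
                "0.0",
                f"{h.percent_similarity:.2f}",
            ]
            handle.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# annotation table
# ---------------------------------------------------------------------------

def read_annotation_table(path: str | Path) -> dict[str, dict]:
    """Read per-protein annotation flags keyed by accession.

    Columns: accession, n_term_complete, signal_peptide, tm_span_count,
    gpi_anchor, go_terms ('|'-separated GO identifiers, may be empty).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(frame, ANNOTATION_COLUMNS, path)
    annotations: dict[str, dict] = {}
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        where = f"{path}:row {idx}"
        accession = str(row.accession)
        if accession in annotations:
            raise TableFormatError(f"{where}: duplicate accession {accession!r}")
        terms = frozenset(t for t in str(row.go_terms).split("|") if t)
        for term in terms:
            if not _GO_RE.match(term):
                raise TableFormatError(f"{where}: malformed GO id {term!r}")
        try:
            annotations[accession] = {
                "n_term_complete": _parse_bool(row.n_term_complete, where),
                "signal_peptide": _parse_bool(row.signal_peptide, where),
                "tm_span_count": int(row.tm_span_count),
                "gpi_anchor": _parse_bool(row.gpi_anchor, where),
                "go_terms": terms,
            }
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"{where}: {exc}") from exc
        if annotations[accession]["tm_span_count"] < 0:
            raise TableFormatError(f"{where}: tm_span_count must be >= 0")
    return annotations


def write_annotation_table(annotations: Mapping[str, Mapping], path: str | Path) -> None:
    rows = []
    for accession in sorted(annotations):
        ann = annotations[accession]
        rows.append(
            {
                "accession": accession,
                "n_term_complete": _BOOL_OUT[bool(ann["n_term_complete"])],
                "signal_peptide": _BOOL_OUT[bool(ann["signal_peptide"])],
                "tm_span_count": int(ann["tm_span_count"]),
                "gpi_anchor": _BOOL_OUT[bool(ann["gpi_anchor"])],
                "go_terms": "|".join(sorted(ann["go_terms"])),
            }
        )
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(path, sep="\t", index=False)


def apply_annotations(
    records: Iterable[ProteinRecord], annotations: Mapping[str, Mapping]
) -> list[ProteinRecord]:
    """Merge annotation flags onto FASTA-derived records (missing -> defaults)."""
    merged = []
    for rec in records:
        ann = annotations.get(rec.accession)
        if ann is None:
            merged.append(rec)
            continue
        merged.append(
            ProteinRecord(
                accession=rec.accession,
                sequence=rec.sequence,
                description=rec.description,
                n_term_complete=bool(ann["n_term_complete"]),
                go_terms=frozenset(ann["go_terms"]),
                signal_peptide=bool(ann["signal_peptide"]),
                tm_span_count=int(ann["tm_span_count"]),
                gpi_anchor=bool(ann["gpi_anchor"]),
            )
        )
    return merged


# ---------------------------------------------------------------------------
# ortholog pairs
# ---------------------------------------------------------------------------

def read_ortholog_table(
    path: str | Path, proteome_labels: Iterable[str] | None = None
) -> list[OrthologPair]:
    """Read ortholog-pair rows; labels must come from the configured proteome set."""
    path = Path(path)
    labels = set(proteome_labels) if proteome_labels is not None else None
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(frame, ORTHOLOG_COLUMNS, path)
    pairs: list[OrthologPair] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        where = f"{path}:row {idx}"
        label = str(row.other_proteome)
        if labels is not None and label not in labels:
            raise VocabularyError(f"{where}: unconfigured proteome label {label!r}")
        try:
            pairs.append(
                OrthologPair(
                    target_accession=str(row.target_accession),
                    other_accession=str(row.other_accession),
                    other_proteome=label,
                    relation=str(row.relation),
                )
            )
        except VocabularyError as exc:
            raise VocabularyError(f"{where}: {exc}") from exc
    return pairs


def write_ortholog_table(pairs: Iterable[OrthologPair], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "target_accession": p.target_accession,
                "other_accession": p.other_accession,
                "other_proteome": p.other_proteome,
                "relation": p.relation,
            }
            for p in pairs
        ],
        columns=list(ORTHOLOG_COLUMNS),
    )
    frame = frame.sort_values(list(ORTHOLOG_COLUMNS), kind="mergesort")
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# curated proteome output
# ---------------------------------------------------------------------------

CURATED_COLUMNS = (
    "accession",
    "annotation",
    "best_score",
    "SSOM",
    "ISOM",
    "CF2",
    "CF4",
    "ACT1",
    "ACT3",
    "categories",
)


def write_curated_table(
    curated_frame: pd.DataFrame,
    tsv_path: str | Path,
    json_path: str | Path | None = None,
    summary: Mapping | None = None,
) -> None:
    """Write the final curated-proteome TSV (ascending accession) and a JSON report.

    ``curated_frame`` must be indexed by accession and carry the columns of
    :data:`CURATED_COLUMNS` except ``accession``. Boolean columns are written
    as ``true``/``false``; ``categories`` as a '|'-joined sorted list.
    """
    frame = curated_frame.sort_index().reset_index(names="accession")
    out = pd.DataFrame()
    out["accession"] = frame["accession"]
    out["annotation"] = frame["annotation"]
    out["best_score"] = frame["best_score"]
    for col in ("SSOM", "ISOM", "CF2", "CF4", "ACT1", "ACT3"):
        out[col] = frame[col].map(lambda v: _BOOL_OUT[bool(v)])
    out["categories"] = frame["categories"].map(lambda cats: "|".join(sorted(cats)))
    out.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        report = dict(summary or {})
        report.setdefault("total_proteins", int(len(out)))
        with open(json_path, "w") as handle:
            json.dump(report, handle, indent=2, sort_keys=True)
            handle.write("\n")
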