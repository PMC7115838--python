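"""End-to-end curation: load, screen, filter, summarize, classify, compare.

Stage order follows the curation procedure: contaminant screening first,
then the evidence filter (the two commute — both are per-protein
predicates), then the detection matrix, fraction set summaries, export/GO
classification, orthology overlap, and a single write phase. Nothing is
written until every stage has succeeded, so a failing stage never leaves
partial outputs behind. The pipeline proper is fully deterministic; all
randomness lives in :mod:`sompkit.synthetic`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .classify import (
    CategoryMap,
    classify_export,
    classify_function,
    tally_categories,
    write_classification_table,
)
from .contamination import ContaminantThresholds, screen_proteome, write_verdict_table
from .evidence import DetectionMatrix, EvidenceThresholds, build_detection_matrix
from .fractions import method_summary, solubility_summary
from .io_tables import (
    apply_annotations,
    read_annotation_table,
    read_blast_tabular,
    read_evidence_table,
    read_fasta,
    read_ortholog_table,
    write_curated_table,
)
from .orthology import overlap_with_enrichment
from .synthetic import DEFAULT_PROTEOME_LABELS

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class CuratedProteome:
    """The final filtered, screened, classified protein list.

    ``frame`` is indexed by accession (ascending) with columns: annotation,
    best_score, SSOM, ISOM, CF2, CF4, ACT1, ACT3 (booleans pooled over the
    other axis), categories (set of category labels).
    """

    frame: pd.DataFrame
    matrix: DetectionMatrix

    @property
    def accessions(self) -> list[str]:
        return list(self.frame.index)


@dataclass
class RunReport:
    """Audit record of one curation run."""

    input_digests: dict[str, str] = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    fraction_summary: dict = field(default_factory=dict)
    category_tallies: dict = field(default_factory=dict)
    overlap: dict = field(default_factory=dict)
    removed_accessions: list[str] = field(default_factory=list)
    category_map_hash: str = ""
    similarity_source: str = "ppos_else_pident"
    peptide_source: str = "observed"
    version: str = __version__
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "input_digests": self.input_digests,
            "thresholds": self.thresholds,
            "stage_counts": self.stage_counts,
            "fraction_summary": self.fraction_summary,
            "category_tallies": self.category_tallies,
            "overlap": self.overlap,
            "removed_accessions": self.removed_accessions,
            "category_map_hash": self.category_map_hash,
            "similarity_source": self.similarity_source,
            "peptide_source": self.peptide_source,
            "version": self.version,
            "seed": self.seed,
        }


def load_config(path: str | Path) -> dict:
    with open(path) as handle:
        return yaml.safe_load(handle)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_curation(
    config: Mapping | str | Path,
    out_dir: str | Path | None = None,
) -> tuple[CuratedProteome, RunReport]:
    """Execute the full curation pipeline from a config mapping or YAML path.

    Config keys: ``inputs`` (target_fasta, contaminant_fasta, evidence,
    alignments, annotations, orthologs), optional ``thresholds`` (``evidence``
    and ``contamination`` sub-maps), ``proteomes`` (labels), ``background``
    (``p`` and/or ``counts: [K, N]``), ``category_map`` (YAML path),
    ``peptide_source``, ``seed``. When ``out_dir`` is given, all output
    tables and the JSON run report are written there.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    inputs = config.get("inputs", {})
    required = ("target_fasta", "contaminant_fasta", "evidence", "alignments",
                "annotations", "orthologs")
    missing = [k for k in required if k not in inputs]
    if missing:
        raise PipelineError("config", f"missing input file keys {missing}")
    paths = {k: Path(inputs[k]) for k in required}

    ev_thresholds = EvidenceThresholds(**config.get("thresholds", {}).get("evidence", {}))
    ct_thresholds = ContaminantThresholds(
        **config.get("thresholds", {}).get("contamination", {})
    )
    proteome_labels = tuple(config.get("proteomes", DEFAULT_PROTEOME_LABELS))
    background = config.get("background", {"p": 0.002})
    peptide_source = config.get("peptide_source", "observed")
    if "category_map" in config:
        category_map = CategoryMap.from_yaml(config["category_map"])
    else:
        category_map = CategoryMap.default()

    # ---- load ------------------------------------------------------------
    try:
        targets = {r.accession: r for r in read_fasta(paths["target_fasta"])}
        contaminant_db = read_fasta(paths["contaminant_fasta"])
        evidence = read_evidence_table(paths["evidence"])
        hits = read_blast_tabular(paths["alignments"])
        annotations = read_annotation_table(paths["annotations"])
        pairs = read_ortholog_table(paths["orthologs"], proteome_labels)
    except (OSError, ValueError, KeyError) as exc:
        raise PipelineError("load", str(exc)) from exc

    proteins_in = sorted({row.protein_accession for row in evidence})
    logger.info("loaded evidence for %d proteins", len(proteins_in))

    # ---- contamination screen -------------------------------------------
    try:
        verdicts = screen_proteome(
            proteins_in, evidence, hits, contaminant_db, ct_thresholds,
            peptide_source=peptide_source, target_db=targets,
        )
    except (ValueError, KeyError) as exc:
        raise PipelineError("contamination_screen", str(exc)) from exc
    removed = {v.accession for v in verdicts if v.removed}
    retained_evidence = [r for r in evidence if r.protein_accession not in removed]
    for v in sorted(verdicts, key=lambda v: v.accession):
        if v.removed:
            logger.info(
                "removed %s: candidate via %s (evalue=%.3g, similarity=%.1f), "
                "%d shared peptides",
                v.accession, v.triggering_hit.subject_accession,
                v.triggering_hit.evalue, v.triggering_hit.percent_similarity,
                v.shared_peptide_count,
            )

    # ---- evidence filter / detection matrix ------------------------------
    try:
        matrix = build_detection_matrix(retained_evidence, ev_thresholds)
    except ValueError as exc:
        raise PipelineError("evidence_filter", str(exc)) from exc
    curated_accessions = matrix.accessions
    if not curated_accessions:
        logger.warning("curated proteome is empty")

    # ---- fraction summaries ----------------------------------------------
    total = len(curated_accessions)
    methods = method_summary(matrix, total=total)
    solubility = solubility_summary(matrix, total=total)

    # ---- classification ---------------------------------------------------
    annotated = apply_annotations(
        [targets[a] for a in curated_accessions if a in targets], annotations
    )
    known = {r.accession for r in annotated}
    unknown = [a for a in curated_accessions if a not in known]
    if unknown:
        raise PipelineError(
            "classify", f"curated accession(s) missing from target FASTA: {unknown}"
        )
    classifications = {
        rec.accession: (classify_export(rec), classify_function(rec, category_map))
        for rec in annotated
    }
    tallies = tally_categories(classifications.values())

    # ---- orthology overlap ------------------------------------------------
    try:
        overlap = overlap_with_enrichment(
            curated_accessions,
            pairs,
            proteome_labels,
            background_p=background.get("p"),
            background_counts=tuple(background["counts"]) if "counts" in background else None,
        )
    except (ValueError, KeyError) as exc:
        raise PipelineError("orthology_overlap", str(exc)) from exc

    # ---- assemble ----------------------------------------------------------
    rows = {}
    for accession in curated_accessions:
        cells = matrix.cells(accession)
        rows[accession] = {
            "annotation": targets[accession].description,
            "best_score": float(matrix.table.loc[accession, "best_score"]),
            "SSOM": any(s == "SSOM" for _, s in cells),
            "ISOM": any(s == "ISOM" for _, s in cells),
            "CF2": any(m == "CF2" for m, _ in cells),
            "CF4": any(m == "CF4" for m, _ in cells),
            "ACT1": any(m == "ACT1" for m, _ in cells),
            "ACT3": any(m == "ACT3" for m, _ in cells),
            "categories": classifications[accession][1],
        }
    curated_columns = ["annotation", "best_score", "SSOM", "ISOM",
                       "CF2", "CF4", "ACT1", "ACT3", "categories"]
    if rows:
        frame = pd.DataFrame.from_dict(rows, orient="index")[curated_columns].sort_index()
    else:
        frame = pd.DataFrame(columns=curated_columns)
    frame.index.name = "accession"
    curated = CuratedProteome(frame=frame, matrix=matrix)

    report = RunReport(
        input_digests={k: _sha256(p) for k, p in sorted(paths.items())},
        thresholds={
            "evidence": vars(ev_thresholds).copy(),
            "contamination": vars(ct_thresholds).copy(),
        },
        stage_counts={
            "proteins_in": len(proteins_in),
            "after_screen": len(proteins_in) - len(removed),
            "removed_contaminants": len(removed),
            "curated": total,
        },
        fraction_summary={
            "methods": methods.to_dict(),
            "solubility": solubility.to_dict(),
        },
        category_tallies=tallies,
        overlap=overlap.to_dict(),
        removed_accessions=sorted(removed),
        category_map_hash=category_map.map_hash(),
        peptide_source=peptide_source,
        seed=config.get("seed"),
    )
    assert (
        report.stage_counts["proteins_in"]
        >= report.stage_counts["after_screen"]
        >= report.stage_counts["curated"]
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_curated_table(
            frame, out_dir / "curated.tsv", out_dir / "report.json",
            summary=report.to_dict() | {"total_proteins": total},
        )
        matrix.write_tsv(out_dir / "detection_matrix.tsv")
        write_verdict_table(verdicts, out_dir / "screen_verdicts.tsv")
        write_classification_table(classifications, out_dir / "classification.tsv")
        with open(out_dir / "overlap.json", "w") as handle:
            json.dump(overlap.to_dict(), handle, indent=2, sort_keys=True)
            handle.write("\n")
    return curated, report
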