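"""Export-route and functional classification of curated skeletal proteins.

Skeletal matrix proteins must leave the calicoblastic cell (or span its
membrane) to reach the extracellular calcification site. Each protein is
classified by documented export evidence — signal peptide (counted only on
gene models with a complete N-terminus), transmembrane spans, GPI anchor —
or, lacking all three, as a candidate for non-classical secretion.

Functionally, proteins are grouped into five GO-derived categories used to
reason about likely cellular location: membrane processing
(lipid/phosphate/glycan metabolism), ECM/transmembrane, metal binding,
vesicular/secretion, and protein modification. The GO-to-category map is an
explicit, editable artifact whose SHA-256 hash is stamped into every report;
a protein may receive several categories, or none.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .io_tables import ProteinRecord

CATEGORIES = (
    "membrane_processing",
    "ecm_tm_protein_modification",
    "metal_binding",
    "vesicular_secretion",
    "protein_modification",
)


class CategoryConfigError(ValueError):
    """A category-map rule is malformed."""


@dataclass(frozen=True)
class CategoryRule:
    """One mapping rule: a GO id or a keyword regex, targeting one category."""

    match: str  # "go" | "keyword"
    pattern: str
    category: str

    def __post_init__(self) -> None:
        if self.match not in ("go", "keyword"):
            raise CategoryConfigError(f"unknown rule kind {self.match!r}")
        if self.category not in CATEGORIES:
            raise CategoryConfigError(f"unknown category {self.category!r}")
        if self.match == "go" and not re.match(r"^GO:\d{7}$", self.pattern):
            raise CategoryConfigError(f"malformed GO id {self.pattern!r}")
        if self.match == "keyword":
            try:
                re.compile(self.pattern)
            except re.error as exc:
                raise CategoryConfigError(
                    f"invalid keyword pattern {self.pattern!r}: {exc}"
                ) from exc


@dataclass(frozen=True)
class CategoryMap:
    """An ordered rule list mapping GO ids / keywords to the five categories."""

    rules: tuple[CategoryRule, ...]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CategoryMap":
        with open(path) as handle:
            payload = yaml.safe_load(handle)
        if not isinstance(payload, dict) or "rules" not in payload:
            raise CategoryConfigError(f"{path}: expected a mapping with a 'rules' list")
        rules = tuple(
            CategoryRule(
                match=str(entry["match"]),
                pattern=str(entry["pattern"]),
                category=str(entry["category"]),
            )
            for entry in payload["rules"]
        )
        return cls(rules=rules)

    @classmethod
    def default(cls) -> "CategoryMap":
        """The category map shipped with the package (data/default_category_map.yaml)."""
        from importlib.resources import files

        return cls.from_yaml(files("sompkit").joinpath("data/default_category_map.yaml"))

    def map_hash(self) -> str:
        """SHA-256 over the canonical JSON form of the rules."""
        canonical = json.dumps(
            [[r.match, r.pattern, r.category] for r in self.rules],
            separators=(",", ":"),
        )
        return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass(frozen=True)
class ExportClassification:
    """Documented export evidence for one protein.

    ``has_sp`` requires both the predicted signal peptide and a complete
    N-terminus (a truncated gene model cannot support an SP call);
    ``ecm_evidence`` is the disjunction of SP, TM and GPI evidence, and its
    complement flags the protein as a non-classical-secretion candidate.
    """

    accession: str
    has_sp: bool
    has_tm: bool
    has_gpi: bool
    ecm_evidence: bool
    non_classical_candidate: bool
    signal_peptide_raw: bool = False

    def __post_init__(self) -> None:
        if self.ecm_evidence == self.non_classical_candidate:
            raise ValueError(
                f"{self.accession}: ecm_evidence and non_classical_candidate "
                "must partition"
            )


def classify_export(record: ProteinRecord) -> ExportClassification:
    """Derive the export classification from a protein's annotation flags."""
    has_sp = record.signal_peptide and record.n_term_complete
    has_tm = record.tm_span_count >= 1
    has_gpi = record.gpi_anchor
    ecm = has_sp or has_tm or has_gpi
    return ExportClassification(
        accession=record.accession,
        has_sp=has_sp,
        has_tm=has_tm,
        has_gpi=has_gpi,
        ecm_evidence=ecm,
        non_classical_candidate=not ecm,
        signal_peptide_raw=record.signal_peptide,
    )


def classify_function(record: ProteinRecord, category_map: CategoryMap) -> set[str]:
    """Union of categories over all matching rules; empty set = uncharacterized.

    GO rules match the protein's GO identifiers exactly; keyword rules are
    case-insensitive regex searches of the protein description.
    """
    categories: set[str] = set()
    for rule in category_map.rules:
        if rule.match == "go":
            if rule.pattern in record.go_terms:
                categories.add(rule.category)
        else:
            if re.search(rule.pattern, record.description, flags=re.IGNORECASE):
                categories.add(rule.category)
    return categories


def tally_categories(
    classifications: Iterable[tuple[ExportClassification, set[str]]],
) -> dict:
    """Per-category protein counts plus export-class counts.

    A protein in several categories increments each of them once; the export
    tallies count proteins, so ``ecm_evidence + non_classical`` equals the
    number of proteins classified.
    """
    category_counts = {category: 0 for category in CATEGORIES}
    export_counts = {
        "has_sp": 0,
        "has_tm": 0,
        "has_gpi": 0,
        "ecm_evidence": 0,
        "non_classical": 0,
        "signal_peptide_raw": 0,
    }
    n_classified = 0
    n_with_category = 0
    for export, categories in classifications:
        n_classified += 1
        for category in set(categories):
            category_counts[category] += 1
        if categories:
            n_with_category += 1
        export_counts["has_sp"] += export.has_sp
        export_counts["has_tm"] += export.has_tm
        export_counts["has_gpi"] += export.has_gpi
        export_counts["ecm_evidence"] += export.ecm_evidence
        export_counts["non_classical"] += export.non_classical_candidate
        export_counts["signal_peptide_raw"] += export.signal_peptide_raw
    return {
        "n_proteins": n_classified,
        "n_with_category": n_with_category,
        "categories": category_counts,
        "export": export_counts,
    }


def write_classification_table(
    rows: Mapping[str, tuple[ExportClassification, set[str]]], path: str | Path
) -> None:
    """Emit the per-protein classification TSV, ascending accession."""
    import pandas as pd

    bool_out = {True: "true", False: "false"}
    table = [
        {
            "accession": accession,
            "has_sp": bool_out[cls.has_sp],
            "signal_peptide_raw": bool_out[cls.signal_peptide_raw],
            "has_tm": bool_out[cls.has_tm],
            "has_gpi": bool_out[cls.has_gpi],
            "ecm_evidence": bool_out[cls.ecm_evidence],
            "non_classical_candidate": bool_out[cls.non_classical_candidate],
            "categories": "|".join(sorted(categories)),
        }
        for accession, (cls, categories) in sorted(rows.items())
    ]
    pd.DataFrame(
        table,
        columns=[
            "accession",
            "has_sp",
            "signal_peptide_raw",
            "has_tm",
            "has_gpi",
            "ecm_evidence",
            "non_classical_candidate",
            "categories",
        ],
    ).to_csv(path, sep="\t", index=False)
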