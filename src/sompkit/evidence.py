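"""Protein acceptance rule and the per-fraction detection matrix.

A protein is accepted within one method x solubility fraction when its peptide
evidence there contains at least two distinct significant peptides, or at
least one significant peptide backed by >= 10 spectra with an identification
score of 250 or greater. Acceptance is evaluated independently per fraction;
the resulting boolean protein x fraction table is the substrate of all
downstream set analytics.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .io_tables import FRACTIONS, METHODS, SOLUBILITIES, PeptideEvidence

CELL_COLUMNS = tuple(f"{m}_{s}" for m, s in FRACTIONS)


@dataclass(frozen=True)
class EvidenceThresholds:
    """Thresholds of the protein acceptance rule."""

    min_significant_peptides: int = 2
    alt_min_spectra: int = 10
    alt_min_score: float = 250.0

    def __post_init__(self) -> None:
        if self.min_significant_peptides < 1 or self.alt_min_spectra < 1:
            raise ValueError("peptide/spectra thresholds must be positive")
        if self.alt_min_score < 0:
            raise ValueError("alt_min_score must be >= 0")


def accept_protein(
    evidence: Iterable[PeptideEvidence],
    thresholds: EvidenceThresholds = EvidenceThresholds(),
) -> bool:
    """Apply the acceptance rule to one protein's evidence in one fraction.

    True iff the rows contain >= ``min_significant_peptides`` distinct
    significant peptide sequences, or at least one significant peptide with
    ``spectra_count >= alt_min_spectra`` and ``score >= alt_min_score``.
    All rows must share one accession, one method and one solubility.
    """
    rows = list(evidence)
    if not rows:
        return False
    keys = {(r.protein_accession, r.method, r.solubility) for r in rows}
    if len(keys) > 1:
        raise ValueError(
            f"accept_protein expects evidence from a single (protein, method, "
            f"solubility) cell, got {sorted(keys)}"
        )
    significant = [r for r in rows if r.significant]
    distinct_peptides = {r.peptide for r in significant}
    if len(distinct_peptides) >= thresholds.min_significant_peptides:
        return True
    return any(
        r.spectra_count >= thresholds.alt_min_spectra
        and r.score >= thresholds.alt_min_score
        for r in significant
    )


@dataclass
class DetectionMatrix:
    """Boolean protein x (method, solubility) presence with per-protein best score.

    ``table`` is indexed by accession (ascending) with one boolean column per
    fraction cell (``CF2_SSOM`` ... ``ACT3_ISOM``) and a float ``best_score``
    column holding the maximum score over accepted cells.
    """

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=[*CELL_COLUMNS, "best_score"]
        )
    )

    @property
    def accessions(self) -> list[str]:
        return list(self.table.index)

    def cells(self, accession: str) -> set[tuple[str, str]]:
        """The fraction cells in which this protein was accepted."""
        row = self.table.loc[accession]
        return {
            (m, s) for (m, s), col in zip(FRACTIONS, CELL_COLUMNS) if bool(row[col])
        }

    def proteins_in_methods(self, methods: Iterable[str]) -> set[str]:
        """Proteins with a true cell in any listed method (either solubility)."""
        methods = set(methods)
        unknown = methods - set(METHODS)
        if unknown:
            raise ValueError(f"unknown method label(s) {sorted(unknown)}")
        cols = [f"{m}_{s}" for m in methods for s in SOLUBILITIES]
        if self.table.empty:
            return set()
        mask = self.table[cols].any(axis=1)
        return set(self.table.index[mask])

    def proteins_in_solubility(self, solubility: str) -> set[str]:
        """Proteins with a true cell in the given solubility (any method)."""
        if solubility not in SOLUBILITIES:
            raise ValueError(f"unknown solubility label {solubility!r}")
        cols = [f"{m}_{solubility}" for m in METHODS]
        if self.table.empty:
            return set()
        mask = self.table[cols].any(axis=1)
        return set(self.table.index[mask])

    def write_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        for col in CELL_COLUMNS:
            out[col] = out[col].map(lambda v: "true" if v else "false")
        out.sort_index().to_csv(path, sep="\t", index_label="accession")


def build_detection_matrix(
    evidence: Iterable[PeptideEvidence],
    thresholds: EvidenceThresholds = EvidenceThresholds(),
) -> DetectionMatrix:
    """Evaluate the acceptance rule per (protein, method, solubility) cell.

    Proteins with no accepted cell are dropped. ``best_score`` is the maximum
    evidence score over a protein's accepted cells.
    """
    by_cell: dict[tuple[str, str, str], list[PeptideEvidence]] = defaultdict(list)
    for row in evidence:
        by_cell[(row.protein_accession, row.method, row.solubility)].append(row)

    accepted: dict[str, dict[str, bool]] = defaultdict(
        lambda: {col: False for col in CELL_COLUMNS}
    )
    best: dict[str, float] = {}
    for (accession, method, solubility), rows in by_cell.items():
        if accept_protein(rows, thresholds):
            accepted[accession][f"{method}_{solubility}"] = True
            cell_best = max(r.score for r in rows)
            best[accession] = max(best.get(accession, 0.0), cell_best)

    if not accepted:
        return DetectionMatrix()
    table = pd.DataFrame.from_dict(accepted, orient="index")
    table = table[list(CELL_COLUMNS)]
    table["best_score"] = pd.Series(best)
    table.index.name = "accession"
    return DetectionMatrix(table=table.sort_index())
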