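"""Cross-species contaminant screening.

Human keratins, collagens and other handling contaminants survive even
careful sample preparation and can be mis-assigned to the target organism
when its proteome contains close homologs. The screen works in two stages:

1. *candidate flagging* from alignment statistics of target-vs-contaminant
   BLAST hits — a protein is a candidate when any hit has
   (e-value < 1e-50 and percent similarity > 50) or (e-value < 1e-100) or
   (percent similarity > 80), all strict inequalities;
2. *shared-peptide confirmation* — a candidate is removed only when three or
   more distinct peptides of seven or more residues are identical (verbatim
   substrings, I/L kept distinct) between the target protein and a single
   contaminant protein.

By default the shared peptides are the MS-observed identified peptides; a
fallback mode derives fully-tryptic in-silico peptides (cleavage after K/R
except before P, no missed cleavages) when observed peptides are unavailable.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

from pyteomics import parser as _pyt_parser

from .io_tables import AlignmentHit, PeptideEvidence, ProteinRecord


@dataclass(frozen=True)
class ContaminantThresholds:
    """Thresholds of the two-stage contaminant screen."""

    pair_evalue_max: float = 1e-50
    pair_similarity_min: float = 50.0
    strong_evalue_max: float = 1e-100
    strong_similarity_min: float = 80.0
    min_shared_peptides: int = 3
    min_peptide_length: int = 7

    def __post_init__(self) -> None:
        if self.min_shared_peptides < 1 or self.min_peptide_length < 1:
            raise ValueError("shared-peptide thresholds must be positive")


@dataclass(frozen=True)
class ScreenVerdict:
    """The screen's decision for one protein."""

    accession: str
    candidate: bool
    shared_peptide_count: int
    removed: bool
    triggering_hit: AlignmentHit | None = None

    def __post_init__(self) -> None:
        if self.removed and not self.candidate:
            raise ValueError(f"{self.accession}: removed implies candidate")


def flag_candidate(
    hits: Iterable[AlignmentHit],
    thresholds: ContaminantThresholds = ContaminantThresholds(),
) -> tuple[bool, AlignmentHit | None]:
    """Flag a protein as a potential contaminant from its alignment hits.

    Returns ``(candidate, triggering_hit)``; the triggering hit is the
    satisfying hit with the smallest e-value (ties broken by highest
    similarity, then lexicographic subject accession).
    """
    satisfying = [
        h
        for h in hits
        if (h.evalue < thresholds.pair_evalue_max and h.percent_similarity > thresholds.pair_similarity_min)
        or h.evalue < thresholds.strong_evalue_max
        or h.percent_similarity > thresholds.strong_similarity_min
    ]
    if not satisfying:
        return False, None
    trigger = min(
        satisfying, key=lambda h: (h.evalue, -h.percent_similarity, h.subject_accession)
    )
    return True, trigger


def tryptic_peptides(sequence: str) -> set[str]:
    """Fully-tryptic in-silico peptides (cleave after K/R except before P)."""
    return set(_pyt_parser.cleave(sequence, _pyt_parser.expasy_rules["trypsin"], 0))


def shared_peptides(
    target_peptides: Iterable[str],
    contaminant: ProteinRecord | str,
    min_length: int = 7,
) -> tuple[int, set[str]]:
    """Count distinct target peptides occurring verbatim in a contaminant sequence.

    Only peptides of length >= ``min_length`` count; matching is exact
    substring matching on uppercase sequence, with I and L kept distinct.
    """
    sequence = contaminant.sequence if isinstance(contaminant, ProteinRecord) else contaminant
    sequence = sequence.upper()
    shared = {
        p.upper()
        for p in set(target_peptides)
        if len(p) >= min_length and p.upper() in sequence
    }
    return len(shared), shared


def screen_proteome(
    accessions: Iterable[str],
    evidence: Iterable[PeptideEvidence],
    hits: Iterable[AlignmentHit],
    contaminant_db: Iterable[ProteinRecord],
    thresholds: ContaminantThresholds = ContaminantThresholds(),
    peptide_source: Literal["observed", "tryptic"] = "observed",
    target_db: Mapping[str, ProteinRecord] | None = None,
) -> list[ScreenVerdict]:
    """Screen candidate proteins and decide removal per the two-stage rule.

    Shared peptides are counted first against the triggering hit's subject;
    if below threshold there, against every other aligned subject. Removal
    requires >= ``min_shared_peptides`` shared peptides against at least one
    *single* contaminant protein (counts are never pooled across subjects).

    ``peptide_source='tryptic'`` replaces observed peptides by in-silico
    fully-tryptic peptides of the target sequence (``target_db`` required).
    """
    subjects = {rec.accession: rec for rec in contaminant_db}
    hits_by_query: dict[str, list[AlignmentHit]] = defaultdict(list)
    for hit in hits:
        if hit.subject_accession not in subjects:
            raise KeyError(
                f"alignment hit references unknown contaminant subject "
                f"{hit.subject_accession!r}"
            )
        hits_by_query[hit.query_accession].append(hit)

    peptides_by_protein: dict[str, set[str]] = defaultdict(set)
    if peptide_source == "observed":
        for row in evidence:
            peptides_by_protein[row.protein_accession].add(row.peptide)
    elif peptide_source == "tryptic":
        if target_db is None:
            raise ValueError("peptide_source='tryptic' requires target_db")
        for accession, rec in target_db.items():
            peptides_by_protein[accession] = tryptic_peptides(rec.sequence)
    else:
        raise ValueError(f"unknown peptide_source {peptide_source!r}")

    verdicts: list[ScreenVerdict] = []
    for accession in sorted(set(accessions)):
        protein_hits = hits_by_query.get(accession, [])
        candidate, trigger = flag_candidate(protein_hits, thresholds)
        peptides = peptides_by_protein.get(accession, set())
        # evaluate the triggering subject first, then the remaining aligned
        # subjects; report the maximum single-subject shared count
        ordered_subjects: list[str] = []
        if trigger is not None:
            ordered_subjects.append(trigger.subject_accession)
        for hit in sorted(protein_hits, key=lambda h: (h.evalue, h.subject_accession)):
            if hit.subject_accession not in ordered_subjects:
                ordered_subjects.append(hit.subject_accession)
        best_count = 0
        for subject in ordered_subjects:
            count, _ = shared_peptides(
                peptides, subjects[subject], thresholds.min_peptide_length
            )
            best_count = max(best_count, count)
            if candidate and best_count >= thresholds.min_shared_peptides:
                break
        removed = candidate and best_count >= thresholds.min_shared_peptides
        verdicts.append(
            ScreenVerdict(
                accession=accession,
                candidate=candidate,
                shared_peptide_count=best_count,
                removed=removed,
                triggering_hit=trigger,
            )
        )
    return verdicts


def write_verdict_table(verdicts: Iterable[ScreenVerdict], path) -> None:
    """Emit the verdict TSV (accession, candidate, shared count, removed, subject)."""
    import pandas as pd

    rows = [
        {
            "accession": v.accession,
            "candidate": "true" if v.candidate else "false",
            "shared_peptide_count": v.shared_peptide_count,
            "removed": "true" if v.removed else "false",
            "triggering_subject": (
                v.triggering_hit.subject_accession if v.triggering_hit else ""
            ),
        }
        for v in sorted(verdicts, key=lambda v: v.accession)
    ]
    pd.DataFrame(
        rows,
        columns=[
            "accession",
            "candidate",
            "shared_peptide_count",
            "removed",
            "triggering_subject",
        ],
    ).to_csv(path, sep="\t", index=False)
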