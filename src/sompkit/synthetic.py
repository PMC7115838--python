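"""Seeded synthetic input bundles with planted ground truth.

The generator emulates the statistical structure of a skeletal-proteome
curation run — a target FASTA, a contaminant FASTA, a long-format peptide
evidence table, a BLAST-tabular alignment table, an annotation table and an
ortholog-pair table — with every planted decision recorded in a ground-truth
manifest, so each pipeline stage can be tested without any deposited
mass-spectrometry data.

Three protein populations are planted:

* *skeletal* proteins whose evidence passes the acceptance rule in every
  planted fraction cell and which carry no disqualifying alignment;
* *sub-threshold* proteins whose evidence falls strictly below both branches
  of the acceptance rule;
* *contaminant-like* proteins whose evidence passes, but which share the
  planned number of long peptides with a paired human-like contaminant entry
  and carry an alignment hit strictly inside the candidate thresholds.

Identical config and seed produce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .classify import CATEGORIES
from .io_tables import (
    FRACTIONS,
    AlignmentHit,
    OrthologPair,
    PeptideEvidence,
    ProteinRecord,
    write_annotation_table,
    write_blast_tabular,
    write_evidence_table,
    write_fasta,
    write_ortholog_table,
)

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# K/R boosted so random sequences cleave into usable tryptic peptides
_AA_WEIGHTS = np.array(
    [1.0] * 20
)
_AA_WEIGHTS[list("ACDEFGHIKLMNPQRSTVWY").index("K")] = 2.0
_AA_WEIGHTS[list("ACDEFGHIKLMNPQRSTVWY").index("R")] = 2.0
_AA_PROBS = _AA_WEIGHTS / _AA_WEIGHTS.sum()

DEFAULT_PROTEOME_LABELS = (
    "A_digitifera_2016",
    "A_millepora_2013",
    "S_pistillata_2013",
)

#: Default per-cell detection probabilities, shaped like the study's outcome:
#: insoluble fractions dominate and CF protocols detect far more than ACT.
DEFAULT_DETECTION_PROFILE: dict[str, float] = {
    "CF2_SSOM": 0.08,
    "CF2_ISOM": 0.65,
    "CF4_SSOM": 0.08,
    "CF4_ISOM": 0.65,
    "ACT1_SSOM": 0.03,
    "ACT1_ISOM": 0.18,
    "ACT3_SSOM": 0.03,
    "ACT3_ISOM": 0.18,
}

# GO ids understood by the default category map, one per category
_CATEGORY_GO = {
    "membrane_processing": "GO:0006629",
    "ecm_tm_protein_modification": "GO:0031012",
    "metal_binding": "GO:0005509",
    "vesicular_secretion": "GO:0016192",
    "protein_modification": "GO:0008233",
}


@dataclass(frozen=True)
class SharedPeptidePlan:
    """Planted overlap between one contaminant-like target and its human entry."""

    n_peptides: int = 3
    peptide_length: int = 9
    evalue: float = 1e-110
    percent_similarity: float = 85.0


@dataclass
class SyntheticConfig:
    """Everything the generator needs; identical config + seed => identical bundle."""

    seed: int = 0
    n_skeletal: int = 12
    n_contaminant_like: int = 3
    n_subthreshold: int = 5
    mean_protein_length: int = 300
    detection_profile: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DETECTION_PROFILE)
    )
    planted_cells: Sequence[Sequence[tuple[str, str]]] | None = None
    shared_peptide_plan: SharedPeptidePlan = field(default_factory=SharedPeptidePlan)
    category_plan: Mapping[int, Sequence[str]] | None = None
    export_plan: Mapping[int, Mapping] | None = None
    ortholog_plan: Mapping[int, Sequence[str]] | None = None
    proteome_labels: Sequence[str] = DEFAULT_PROTEOME_LABELS
    score_range: tuple[float, float] = (260.0, 750.0)


@dataclass
class Bundle:
    """Paths of one generated bundle plus its ground truth."""

    out_dir: Path
    files: dict[str, Path]
    ground_truth: dict
    manifest: dict


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=max(20, length), p=_AA_PROBS))


def _long_tryptic_peptides(sequence: str, min_length: int) -> list[str]:
    """Fully-tryptic peptides of at least ``min_length`` residues, in order."""
    from .contamination import tryptic_peptides

    return sorted(p for p in tryptic_peptides(sequence) if len(p) >= min_length)


def _pick_peptides(
    rng: np.random.Generator, sequence: str, n: int, min_length: int = 7
) -> list[str]:
    """Deterministically pick n distinct long tryptic peptides of a sequence."""
    pool = _long_tryptic_peptides(sequence, min_length)
    if len(pool) < n:
        raise ValueError(
            f"sequence yields only {len(pool)} tryptic peptides of length "
            f">= {min_length}; cannot plant {n}"
        )
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def _sample_cells(
    rng: np.random.Generator, profile: Mapping[str, float]
) -> list[tuple[str, str]]:
    """Draw a non-empty set of detection cells from per-cell probabilities."""
    while True:
        cells = [
            (m, s)
            for m, s in FRACTIONS
            if rng.random() < float(profile.get(f"{m}_{s}", 0.0))
        ]
        if cells:
            return cells


def generate_bundle(config: SyntheticConfig, out_dir: str | Path) -> Bundle:
    """Generate a complete input bundle with planted ground truth.

    Writes target.fasta, contaminants.fasta, evidence.tsv, alignments.tsv,
    annotations.tsv, orthologs.tsv and ground_truth.json under ``out_dir``
    and returns a manifest with the SHA-256 of every file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    plan = config.shared_peptide_plan

    skeletal = [f"SPIS_{i:04d}" for i in range(config.n_skeletal)]
    contaminant_like = [f"CTM_{i:04d}" for i in range(config.n_contaminant_like)]
    subthreshold = [f"SUB_{i:04d}" for i in range(config.n_subthreshold)]
    human = [f"HSAP_{i:04d}" for i in range(config.n_contaminant_like)]

    def _length() -> int:
        return int(rng.integers(
            max(60, config.mean_protein_length // 2),
            config.mean_protein_length * 3 // 2 + 1,
        ))

    targets: dict[str, ProteinRecord] = {}
    for accession in skeletal + contaminant_like + subthreshold:
        targets[accession] = ProteinRecord(
            accession, _random_sequence(rng, _length()), "synthetic target protein"
        )

    # contaminant entries embed the planned shared peptides of their paired
    # target inside random background sequence
    contaminants: dict[str, ProteinRecord] = {}
    shared_plan: dict[str, list[str]] = {}
    for target_acc, human_acc in zip(contaminant_like, human):
        peptides = _pick_peptides(
            rng, targets[target_acc].sequence, plan.n_peptides, plan.peptide_length
        )
        shared_plan[target_acc] = peptides
        background = _random_sequence(rng, _length())
        insert_at = len(background) // 2
        embedded = background[:insert_at] + "".join(peptides) + background[insert_at:]
        contaminants[human_acc] = ProteinRecord(
            human_acc, embedded, "synthetic human-like contaminant"
        )

    # detection cells for every protein whose evidence should pass
    planted_cells: dict[str, list[tuple[str, str]]] = {}
    for i, accession in enumerate(skeletal):
        if config.planted_cells is not None:
            planted_cells[accession] = [tuple(c) for c in config.planted_cells[i]]
        else:
            planted_cells[accession] = _sample_cells(rng, config.detection_profile)
    for accession in contaminant_like:
        planted_cells[accession] = _sample_cells(rng, config.detection_profile)

    # evidence: accepted plants get two distinct significant peptides per cell,
    # the first with >= 10 spectra and a score inside score_range, so both
    # branches of the rule hold with margin; sub-threshold plants rotate
    # through three strictly-failing patterns
    evidence: list[PeptideEvidence] = []
    best_scores: dict[str, float] = {}
    lo, hi = config.score_range
    for accession in skeletal + contaminant_like:
        if accession in shared_plan:
            pool = list(shared_plan[accession])
            extra = [
                p
                for p in _long_tryptic_peptides(targets[accession].sequence, 7)
                if p not in pool
            ]
            pool += extra[:2]
        else:
            pool = _pick_peptides(rng, targets[accession].sequence, 2)
        for method, solubility in planted_cells[accession]:
            score_main = float(np.round(rng.uniform(lo, hi), 1))
            score_minor = float(np.round(rng.uniform(80.0, 240.0), 1))
            best_scores[accession] = max(best_scores.get(accession, 0.0), score_main)
            evidence.append(
                PeptideEvidence(accession, pool[0], int(rng.integers(10, 30)),
                                True, score_main, method, solubility)
            )
            evidence.append(
                PeptideEvidence(accession, pool[1], int(rng.integers(1, 6)),
                                True, score_minor, method, solubility)
            )
            for peptide in pool[2:]:
                evidence.append(
                    PeptideEvidence(accession, peptide, int(rng.integers(1, 6)),
                                    True, float(np.round(rng.uniform(80.0, 240.0), 1)),
                                    method, solubility)
                )
    for i, accession in enumerate(subthreshold):
        peptide = _pick_peptides(rng, targets[accession].sequence, 1)[0]
        method, solubility = FRACTIONS[int(rng.integers(0, len(FRACTIONS)))]
        pattern = i % 3
        if pattern == 0:  # one significant peptide, too few spectra
            evidence.append(
                PeptideEvidence(accession, peptide, 9, True, 600.0, method, solubility)
            )
        elif pattern == 1:  # spectra fine, score strictly below threshold
            evidence.append(
                PeptideEvidence(accession, peptide, 15, True, 249.0, method, solubility)
            )
        else:  # only non-significant evidence
            evidence.append(
                PeptideEvidence(accession, peptide, 50, False, 700.0, method, solubility)
            )

    # alignments: contaminant-like plants strictly inside candidate thresholds;
    # about half the clean proteins get a weak hit strictly outside them
    hits: list[AlignmentHit] = []
    for target_acc, human_acc in zip(contaminant_like, human):
        length = min(len(targets[target_acc].sequence), len(contaminants[human_acc].sequence))
        hits.append(
            AlignmentHit(
                query_accession=target_acc,
                subject_accession=human_acc,
                evalue=plan.evalue,
                percent_similarity=plan.percent_similarity,
                align_length=length,
                identical_positions=int(round(plan.percent_similarity / 100 * length)),
            )
        )
    if human:
        for accession in skeletal:
            if rng.random() < 0.5:
                subject = human[int(rng.integers(0, len(human)))]
                length = 80
                sim = float(np.round(rng.uniform(20.0, 45.0), 1))
                hits.append(
                    AlignmentHit(
                        query_accession=accession,
                        subject_accession=subject,
                        evalue=float(10.0 ** rng.uniform(-35, -3)),
                        percent_similarity=sim,
                        align_length=length,
                        identical_positions=int(round(sim / 100 * length)),
                    )
                )

    # annotations: explicit export/category plans when supplied, else random
    annotations: dict[str, dict] = {}
    categories_truth: dict[str, list[str]] = {}
    export_truth: dict[str, dict] = {}
    for i, accession in enumerate(skeletal):
        if config.export_plan is not None and i in config.export_plan:
            exp = dict(config.export_plan[i])
        else:
            exp = {
                "signal_peptide": bool(rng.random() < 0.3),
                "n_term_complete": bool(rng.random() < 0.7),
                "tm_span_count": int(rng.integers(0, 3)) if rng.random() < 0.2 else 0,
                "gpi_anchor": bool(rng.random() < 0.15),
            }
        if config.category_plan is not None:
            cats = sorted(config.category_plan.get(i, ()))
        else:
            cats = sorted(
                c for c in CATEGORIES if rng.random() < 0.25
            )
        go_terms = frozenset(_CATEGORY_GO[c] for c in cats)
        annotations[accession] = {**exp, "go_terms": go_terms}
        categories_truth[accession] = cats
        export_truth[accession] = exp
    for accession in contaminant_like + subthreshold:
        annotations[accession] = {
            "signal_peptide": False,
            "n_term_complete": True,
            "tm_span_count": 0,
            "gpi_anchor": False,
            "go_terms": frozenset(),
        }

    # orthologs
    pairs: list[OrthologPair] = []
    ortholog_truth: dict[str, list[str]] = {}
    labels = list(config.proteome_labels)
    for i, accession in enumerate(skeletal):
        if config.ortholog_plan is not None:
            member_of = list(config.ortholog_plan.get(i, ()))
        else:
            member_of = [l for l in labels if rng.random() < 0.12]
        if member_of:
            ortholog_truth[accession] = sorted(member_of)
        for label in member_of:
            pairs.append(
                OrthologPair(
                    target_accession=accession,
                    other_accession=f"{label}_g{i:04d}",
                    other_proteome=label,
                    relation="one_to_one",
                )
            )

    files = {
        "target_fasta": out_dir / "target.fasta",
        "contaminant_fasta": out_dir / "contaminants.fasta",
        "evidence": out_dir / "evidence.tsv",
        "alignments": out_dir / "alignments.tsv",
        "annotations": out_dir / "annotations.tsv",
        "orthologs": out_dir / "orthologs.tsv",
    }
    write_fasta(targets.values(), files["target_fasta"])
    write_fasta(contaminants.values(), files["contaminant_fasta"])
    write_evidence_table(evidence, files["evidence"])
    write_blast_tabular(hits, files["alignments"])
    write_annotation_table(annotations, files["annotations"])
    write_ortholog_table(pairs, files["orthologs"])

    ground_truth = {
        "seed": config.seed,
        "skeletal": skeletal,
        "contaminant_like": contaminant_like,
        "subthreshold": subthreshold,
        "human_entries": human,
        "planted_cells": {
            acc: sorted(f"{m}_{s}" for m, s in cells)
            for acc, cells in planted_cells.items()
        },
        "best_scores": best_scores,
        "shared_peptides": shared_plan,
        "categories": categories_truth,
        "export": export_truth,
        "orthologs": ortholog_truth,
        "proteome_labels": labels,
        "shared_peptide_plan": asdict(config.shared_peptide_plan),
    }
    truth_path = out_dir / "ground_truth.json"
    with open(truth_path, "w") as handle:
        json.dump(ground_truth, handle, indent=2, sort_keys=True)
        handle.write("\n")
    files["ground_truth"] = truth_path

    manifest = {
        name: hashlib.sha256(path.read_bytes()).hexdigest()
        for name, path in sorted(files.items())
    }
    return Bundle(out_dir=out_dir, files=files, ground_truth=ground_truth, manifest=manifest)


def headline_bundle(seed: int, out_dir: str | Path) -> Bundle:
    """A bundle whose planted structure reproduces the study's headline counts.

    60 curated proteins; combined-CF 52 and combined-ACT 13 with 5 shared
    (12 CF2-only, 16 CF4-only, 19 in both CF protocols; 1 ACT1-only, 5
    ACT3-only, 2 in both ACT protocols; 2 proteins in all four methods and
    2 more in three); ISOM 57 / SSOM 8 with 5 in both; signal peptides on 17
    complete-N-terminus proteins, 8 transmembrane, 10 GPI-anchored, 25 with
    ECM-localization evidence; the five GO groups at 10/19/25/21/12 over 39
    annotated proteins; 16 proteins with orthologs in previously published
    skeletal proteomes, 7 of them in all three. Three contaminant-like and
    four sub-threshold plants exercise both filters.
    """
    method_plan: list[tuple[str, ...]] = (
        [("CF2",)] * 12
        + [("CF4",)] * 16
        + [("CF2", "CF4")] * 19
        + [("ACT1",)]
        + [("ACT3",)] * 5
        + [("ACT1", "ACT3")] * 2
        + [("CF2", "CF4", "ACT1", "ACT3")] * 2
        + [("CF2", "CF4", "ACT1")]
        + [("CF2", "CF4", "ACT3")]
        + [("CF2", "ACT1")]
    )
    ssom_only = {0, 12, 28}
    both_sol = {1, 13, 29, 47, 55}
    cells: list[list[tuple[str, str]]] = []
    for i, methods in enumerate(method_plan):
        if i in ssom_only:
            sols: tuple[str, ...] = ("SSOM",)
        elif i in both_sol:
            sols = ("SSOM", "ISOM")
        else:
            sols = ("ISOM",)
        cells.append([(m, s) for m in methods for s in sols])

    sp_set = set(range(0, 17))
    tm_set = set(range(12, 20))
    gpi_set = set(range(15, 25))
    export_plan = {}
    for i in range(60):
        export_plan[i] = {
            "signal_peptide": i in sp_set or i in (30, 31),
            # 30/31 carry an SP call on an incomplete gene model: not counted
            "n_term_complete": (i in sp_set) or (i not in (30, 31) and i % 2 == 0),
            "tm_span_count": 1 + i % 2 if i in tm_set else 0,
            "gpi_anchor": i in gpi_set,
        }

    category_plan = {}
    for i in range(60):
        cats = []
        if i <= 24:
            cats.append("metal_binding")
        if 18 <= i <= 38:
            cats.append("vesicular_secretion")
        if 29 <= i <= 38:
            cats.append("membrane_processing")
        if i <= 18:
            cats.append("ecm_tm_protein_modification")
        if 27 <= i <= 38:
            cats.append("protein_modification")
        if cats:
            category_plan[i] = tuple(cats)

    labels = DEFAULT_PROTEOME_LABELS
    ortholog_plan = {i: labels for i in range(7)}
    for j, i in enumerate(range(7, 16)):
        ortholog_plan[i] = (labels[j % 3],)

    config = SyntheticConfig(
        seed=seed,
        n_skeletal=60,
        n_contaminant_like=3,
        n_subthreshold=4,
        planted_cells=cells,
        export_plan=export_plan,
        category_plan=category_plan,
        ortholog_plan=ortholog_plan,
    )
    return generate_bundle(config, out_dir)
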