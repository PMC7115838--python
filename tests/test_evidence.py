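"""Acceptance rule and detection matrix, including the brute-force oracle."""

import random

import pytest

from sompkit.evidence import (
    CELL_COLUMNS,
    EvidenceThresholds,
    accept_protein,
    build_detection_matrix,
)
from sompkit.io_tables import FRACTIONS
from conftest import make_evidence


def naive_accept(rows, thresholds=EvidenceThresholds()):
    """Independent double-loop statement of the rule."""
    peptides = set()
    alt = False
    for r in rows:
        if r.significant:
            peptides.add(r.peptide)
            if r.spectra_count >= thresholds.alt_min_spectra and r.score >= thresholds.alt_min_score:
                alt = True
    return len(peptides) >= thresholds.min_significant_peptides or alt


class TestAcceptProtein:
    @pytest.mark.parametrize(
        "rows, expected",
        [
            # two distinct significant peptides, minimal support each
            (
                [
                    make_evidence(peptide="MKLVNTTR", spectra=1, score=50.0),
                    make_evidence(peptide="GQWERTYK", spectra=1, score=50.0),
                ],
                True,
            ),
            # the alternative branch at its exact boundary
            ([make_evidence(spectra=10, score=250.0)], True),
            # one spectrum short of the alternative branch
            ([make_evidence(spectra=9, score=600.0)], False),
            # abundant but never significant
            (
                [make_evidence(peptide=f"PEPTIDEK{i}AK"[:8] + "K", significant=False, spectra=50)
                 for i in range(3)],
                False,
            ),
        ],
        ids=["two_sig_peptides", "boundary_10_spectra_250", "nine_spectra", "no_significant"],
    )
    def test_rule_examples(self, rows, expected):
        assert accept_protein(rows) is expected

    def test_duplicate_peptide_counts_once(self):
        rows = [
            make_evidence(peptide="MKLVNTTR", spectra=3),
            make_evidence(peptide="MKLVNTTR", spectra=5),
        ]
        assert accept_protein(rows) is False

    def test_mixed_cells_rejected(self):
        rows = [make_evidence(method="CF2"), make_evidence(method="CF4")]
        with pytest.raises(ValueError, match="single"):
            accept_protein(rows)

    def test_empty_evidence_rejected(self):
        assert accept_protein([]) is False


def _random_rows(rng, accession="P1", method="CF2", solubility="ISOM", n=None):
    peptides = ["MKLVNTTR", "GQWERTYK", "AAAAAAAK", "TTTTTTTK"]
    n = n if n is not None else rng.randint(1, 6)
    return [
        make_evidence(
            accession,
            rng.choice(peptides),
            rng.randint(1, 15),
            rng.random() < 0.6,
            round(rng.uniform(0, 400), 1),
            method,
            solubility,
        )
        for _ in range(n)
    ]


class TestMonotonicity:
    def test_strengthening_evidence_never_revokes_acceptance(self):
        rng = random.Random(42)
        checked = 0
        for _ in range(1000):
            rows = _random_rows(rng)
            if not accept_protein(rows):
                continue
            checked += 1
            i = rng.randrange(len(rows))
            r = rows[i]
            move = rng.choice(["spectra", "score", "significant"])
            boosted = make_evidence(
                r.protein_accession,
                r.peptide,
                r.spectra_count + (5 if move == "spectra" else 0),
                True if move == "significant" else r.significant,
                r.score + (100.0 if move == "score" else 0.0),
                r.method,
                r.solubility,
            )
            rows[i] = boosted
            assert accept_protein(rows), f"boost {move} revoked acceptance"
        assert checked > 200


class TestDetectionMatrix:
    def test_single_accepted_cell(self):
        rows = [
            make_evidence("P1", "MKLVNTTR", method="CF2", solubility="ISOM"),
            make_evidence("P1", "GQWERTYK", method="CF2", solubility="ISOM"),
        ]
        matrix = build_detection_matrix(rows)
        assert matrix.accessions == ["P1"]
        assert matrix.cells("P1") == {("CF2", "ISOM")}

    def test_all_cells_and_best_score(self):
        rows = []
        for i, (m, s) in enumerate(FRACTIONS):
            rows.append(make_evidence("P1", "MKLVNTTR", score=100.0 + i, method=m, solubility=s))
            rows.append(make_evidence("P1", "GQWERTYK", score=50.0, method=m, solubility=s))
        matrix = build_detection_matrix(rows)
        assert matrix.cells("P1") == set(FRACTIONS)
        assert matrix.table.loc["P1", "best_score"] == 100.0 + len(FRACTIONS) - 1

    def test_rejected_proteins_dropped(self):
        rows = [make_evidence("P1", spectra=9, score=600.0)]
        assert build_detection_matrix(rows).accessions == []

    def test_best_score_only_over_accepted_cells(self):
        rows = [
            make_evidence("P1", "MKLVNTTR", method="CF2"),
            make_evidence("P1", "GQWERTYK", method="CF2", score=120.0),
            # this lone sub-threshold cell carries the highest raw score
            make_evidence("P1", "AAAAAAAK", method="ACT1", spectra=9, score=999.0),
        ]
        matrix = build_detection_matrix(rows)
        assert matrix.cells("P1") == {("CF2", "ISOM")}
        assert matrix.table.loc["P1", "best_score"] == 120.0

    def test_matches_bruteforce_on_random_small_sets(self):
        rng = random.Random(7)
        for _ in range(100):
            rows = []
            for acc in ("P1", "P2", "P3"):
                for m, s in FRACTIONS:
                    if rng.random() < 0.4:
                        rows.extend(
                            _random_rows(rng, acc, m, s, n=rng.randint(1, 4))
                        )
            rows = rows[:50]
            matrix = build_detection_matrix(rows)
            for acc in ("P1", "P2", "P3"):
                for m, s in FRACTIONS:
                    cell_rows = [
                        r for r in rows
                        if (r.protein_accession, r.method, r.solubility) == (acc, m, s)
                    ]
                    expected = naive_accept(cell_rows) if cell_rows else False
                    got = (
                        acc in matrix.table.index
                        and bool(matrix.table.loc[acc, f"{m}_{s}"])
                    )
                    assert got == expected

    def test_planted_ground_truth_recovered(self, tmp_path):
        from sompkit.io_tables import read_evidence_table
        from sompkit.synthetic import SyntheticConfig, generate_bundle

        bundle = generate_bundle(
            SyntheticConfig(seed=5, n_skeletal=12, n_contaminant_like=0, n_subthreshold=5),
            tmp_path,
        )
        matrix = build_detection_matrix(read_evidence_table(bundle.files["evidence"]))
        assert matrix.accessions == sorted(bundle.ground_truth["skeletal"])
        for acc in matrix.accessions:
            got = sorted(f"{m}_{s}" for m, s in matrix.cells(acc))
            assert got == bundle.ground_truth["planted_cells"][acc]

    def test_every_accepted_protein_has_a_true_cell(self, headline_bundle_fixture):
        from sompkit.io_tables import read_evidence_table

        matrix = build_detection_matrix(
            read_evidence_table(headline_bundle_fixture.files["evidence"])
        )
        assert matrix.table[list(CELL_COLUMNS)].any(axis=1).all()
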