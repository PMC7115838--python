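"""Two-stage contaminant screen: candidate flagging and shared peptides."""

import random

import pytest

from sompkit.contamination import (
    ContaminantThresholds,
    ScreenVerdict,
    flag_candidate,
    screen_proteome,
    shared_peptides,
    tryptic_peptides,
)
from sompkit.io_tables import AlignmentHit, ProteinRecord
from conftest import make_evidence

AA = "ACDEFGHIKLMNPQRSTVWY"


def _hit(evalue, similarity, subject="HS1", query="P1"):
    return AlignmentHit(query, subject, evalue, similarity, 100, 50)


class TestFlagCandidate:
    @pytest.mark.parametrize(
        "evalue, similarity, expected",
        [
            (1e-60, 55.0, True),    # pair branch: e-value and similarity together
            (1e-120, 30.0, True),   # strong e-value alone
            (0.5, 85.0, True),      # strong similarity alone
            (1e-50, 50.0, False),   # exact thresholds fail: strict inequalities
            (1e-100, 50.0, False),  # boundary of the strong e-value branch
            (1e-10, 80.0, False),   # boundary of the similarity branch
        ],
    )
    def test_branch_boundaries(self, evalue, similarity, expected):
        candidate, trigger = flag_candidate([_hit(evalue, similarity)])
        assert candidate is expected
        assert (trigger is not None) is expected

    def test_no_hits(self):
        assert flag_candidate([]) == (False, None)

    def test_triggering_hit_tie_breaks(self):
        hits = [
            _hit(1e-110, 60.0, subject="HS2"),
            _hit(1e-110, 70.0, subject="HS3"),
            _hit(1e-110, 70.0, subject="HS1"),
            _hit(1e-90, 99.0, subject="HS0"),
        ]
        _, trigger = flag_candidate(hits)
        assert trigger.subject_accession == "HS1"  # min evalue, max sim, lexicographic


class TestSharedPeptides:
    def test_all_three_present(self):
        peptides = {"MKLVNTTR", "GQWERTYK", "AAAAAAAK"}
        contaminant = "CCC" + "MKLVNTTR" + "DD" + "GQWERTYK" + "EE" + "AAAAAAAK" + "FF"
        count, shared = shared_peptides(peptides, contaminant)
        assert count == 3 and shared == peptides

    def test_short_peptide_excluded(self):
        count, shared = shared_peptides({"MKLVNTTR", "SHORTK"}, "MKLVNTTRSHORTK")
        assert count == 1 and shared == {"MKLVNTTR"}

    def test_isoleucine_leucine_distinct(self):
        count, _ = shared_peptides({"MKIVNTTR"}, "CCMKLVNTTRCC")
        assert count == 0

    def test_matches_exhaustive_scan_on_random_pairs(self):
        rng = random.Random(123)
        for _ in range(200):
            contaminant = "".join(rng.choice(AA) for _ in range(300))
            peptides = set()
            for _ in range(20):
                if rng.random() < 0.5:  # half planted as true substrings
                    start = rng.randrange(0, 292)
                    peptides.add(contaminant[start : start + 8])
                else:
                    peptides.add("".join(rng.choice(AA) for _ in range(8)))
            count, shared = shared_peptides(peptides, contaminant)
            oracle = {p for p in peptides if len(p) >= 7 and p in contaminant}
            assert shared == oracle and count == len(oracle)

    def test_monotone_in_target_peptides(self):
        contaminant = "MKLVNTTRGQWERTYK"
        base = {"MKLVNTTR"}
        count_small, _ = shared_peptides(base, contaminant)
        count_large, _ = shared_peptides(base | {"GQWERTYK"}, contaminant)
        assert count_large >= count_small


class TestTrypticPeptides:
    def test_cleaves_after_k_and_r_but_not_before_p(self):
        peptides = tryptic_peptides("AAAKBBBRPCCCRDDD")
        # K/R cleavage with the proline block keeps BBBRPCCCR intact
        assert peptides == {"AAAK", "BBBRPCCCR", "DDD"}


class TestScreenProteome:
    @staticmethod
    def _setup():
        shared = ["MKLVNTTRW", "GQWERTYKA", "AAACDEFGK"]
        target = ProteinRecord("P1", "".join(shared) + "VVV")
        human = ProteinRecord("HS1", "WWW" + "".join(shared) + "YYY")
        evidence = [make_evidence("P1", p) for p in shared]
        return target, human, evidence

    def test_planted_contaminant_removed(self):
        target, human, evidence = self._setup()
        hits = [_hit(1e-110, 85.0)]
        (verdict,) = screen_proteome(["P1"], evidence, hits, [human])
        assert verdict.candidate and verdict.shared_peptide_count == 3 and verdict.removed
        assert verdict.triggering_hit.subject_accession == "HS1"

    def test_candidate_with_two_shared_peptides_retained(self):
        target, human, evidence = self._setup()
        hits = [_hit(1e-110, 85.0)]
        (verdict,) = screen_proteome(["P1"], evidence[:2], hits, [human])
        assert verdict.candidate and verdict.shared_peptide_count == 2
        assert not verdict.removed

    def test_shared_peptides_without_candidate_hit_retained(self):
        # the alignment exists but satisfies none of the three branches,
        # so despite three shared peptides the protein stays
        target, human, evidence = self._setup()
        hits = [_hit(1e-10, 40.0)]
        (verdict,) = screen_proteome(["P1"], evidence, hits, [human])
        assert verdict.shared_peptide_count == 3
        assert not verdict.candidate and not verdict.removed

    def test_counts_not_pooled_across_subjects(self):
        # two shared peptides sit in one human entry, one in another:
        # no single subject reaches three, so the protein is retained
        evidence = [
            make_evidence("P1", p) for p in ("MKLVNTTRW", "GQWERTYKA", "AAACDEFGK")
        ]
        hs1 = ProteinRecord("HS1", "XXMKLVNTTRWXXGQWERTYKAXX")
        hs2 = ProteinRecord("HS2", "XXAAACDEFGKXX")
        hits = [_hit(1e-110, 85.0, "HS1"), _hit(1e-105, 85.0, "HS2")]
        (verdict,) = screen_proteome(["P1"], evidence, hits, [hs1, hs2])
        assert verdict.candidate and verdict.shared_peptide_count == 2
        assert not verdict.removed

    def test_tryptic_fallback_mode(self):
        target, human, _ = self._setup()
        hits = [_hit(1e-110, 85.0)]
        (verdict,) = screen_proteome(
            ["P1"], [], hits, [human],
            peptide_source="tryptic", target_db={"P1": target},
        )
        # MKLVNTTRW...: tryptic digestion of the target regenerates peptides
        # long enough to match inside the human entry
        assert verdict.candidate

    def test_unknown_subject_is_referential_error(self):
        with pytest.raises(KeyError, match="unknown contaminant subject"):
            screen_proteome(["P1"], [], [_hit(1e-110, 85.0, "NOPE")], [])

    def test_removed_implies_candidate_invariant(self):
        with pytest.raises(ValueError, match="removed implies candidate"):
            ScreenVerdict("P1", candidate=False, shared_peptide_count=5, removed=True)

    def test_relaxing_thresholds_never_unremoves(self):
        target, human, evidence = self._setup()
        hits = [_hit(1e-110, 85.0)]
        strict = ContaminantThresholds()
        relaxed = ContaminantThresholds(
            pair_evalue_max=1e-10, pair_similarity_min=10.0,
            strong_evalue_max=1e-20, strong_similarity_min=40.0,
            min_shared_peptides=1, min_peptide_length=5,
        )
        (v_strict,) = screen_proteome(["P1"], evidence, hits, [human], strict)
        (v_relaxed,) = screen_proteome(["P1"], evidence, hits, [human], relaxed)
        assert v_strict.removed <= v_relaxed.removed

    def test_perfect_recall_and_retention_on_synthetic_bundle(self, tmp_path):
        from sompkit.io_tables import read_blast_tabular, read_evidence_table, read_fasta
        from sompkit.synthetic import SyntheticConfig, generate_bundle

        bundle = generate_bundle(
            SyntheticConfig(seed=9, n_skeletal=15, n_contaminant_like=4, n_subthreshold=3),
            tmp_path,
        )
        evidence = read_evidence_table(bundle.files["evidence"])
        verdicts = screen_proteome(
            {r.protein_accession for r in evidence},
            evidence,
            read_blast_tabular(bundle.files["alignments"]),
            read_fasta(bundle.files["contaminant_fasta"]),
        )
        removed = {v.accession for v in verdicts if v.removed}
        assert removed == set(bundle.ground_truth["contaminant_like"])
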