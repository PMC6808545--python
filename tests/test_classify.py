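"""Donor/recipient classification, verdicts, splitting, and summaries."""

import itertools

import pytest

from crossclean.classify import (
    STATUS_CLEAN,
    STATUS_EXCLUDED,
    STATUS_POSSIBLE,
    STATUS_VERIFIED,
    Verdict,
    assign_verdicts,
    classify_candidate,
    dedupe_candidates,
    split_library,
    summarize_libraries,
)
from crossclean.formats import AlnHit, TranscriptSeq, parse_newick_string
from crossclean.threshold import Candidate

from conftest import detection_metrics


def _hit(q, s, identity=99.0, bitscore=500.0, evalue=1e-50, length=500):
    return AlnHit(q, s, identity, length, 0, 0, 1, length, 1, length, evalue, bitscore)


def _cand(seq_id="OTAN_1_x", sample="OTAN", partner="XMQO_1_y", psample="XMQO"):
    return Candidate(seq_id, sample, partner, psample, 99.5)


@pytest.fixture()
def taxo(sample_map):
    # OTAN distant from everyone; XMQO and GUNT confamilial
    samples = sample_map(
        OTAN="Hydrangeaceae", XMQO="Gunneraceae", GUNT="Gunneraceae", ZAAA="Zamiaceae"
    )
    phylo = parse_newick_string("(((XMQO,GUNT),OTAN),ZAAA);")
    return samples, phylo


class TestClassifyCandidate:
    def test_one_close_hit_in_top3_rescues(self, taxo):
        samples, phylo = taxo
        cand = Candidate("XMQO_1_x", "XMQO", "OTAN_9_y", "OTAN", 99.5)
        hits = [
            _hit("XMQO_1_x", "OTAN_9_y", bitscore=900),  # distant
            _hit("XMQO_1_x", "GUNT_1_y", bitscore=500),  # same family
            _hit("XMQO_1_x", "ZAAA_1_y", bitscore=400),  # distant
        ]
        v = classify_candidate(cand, hits, samples, phylo)
        assert v.status == STATUS_EXCLUDED and v.donor_sample is None

    def test_all_distant_hits_verify_with_best_hit_donor(self, taxo):
        samples, phylo = taxo
        hits = [
            _hit("OTAN_1_x", "XMQO_5_y", bitscore=900),
            _hit("OTAN_1_x", "GUNT_2_y", bitscore=600),
            _hit("OTAN_1_x", "ZAAA_3_y", bitscore=300),
        ]
        v = classify_candidate(_cand(), hits, samples, phylo)
        assert v.status == STATUS_VERIFIED and v.donor_sample == "XMQO"

    def test_no_evidence_is_unresolved_possible(self, taxo):
        samples, phylo = taxo
        v = classify_candidate(_cand(), [], samples, phylo)
        assert v.status == STATUS_POSSIBLE and v.donor_sample is None

    def test_close_hit_beyond_top3_does_not_rescue(self, taxo):
        samples, phylo = taxo
        cand = Candidate("XMQO_1_x", "XMQO", "OTAN_9_y", "OTAN", 99.5)
        hits = [
            _hit("XMQO_1_x", "OTAN_9_y", bitscore=900),
            _hit("XMQO_1_x", "ZAAA_1_y", bitscore=800),
            _hit("XMQO_1_x", "OTAN_2_y", bitscore=700),
            _hit("XMQO_1_x", "GUNT_1_y", bitscore=100),  # rank 4: not considered
        ]
        v = classify_candidate(cand, hits, samples, phylo)
        assert v.status == STATUS_VERIFIED

    def test_unparseable_subject_codes_skipped(self, taxo, caplog):
        samples, phylo = taxo
        hits = [
            _hit("OTAN_1_x", "contig77", bitscore=999),
            _hit("OTAN_1_x", "XMQO_5_y", bitscore=900),
        ]
        with caplog.at_level("WARNING"):
            v = classify_candidate(_cand(), hits, samples, phylo)
        assert v.status == STATUS_VERIFIED and v.donor_sample == "XMQO"

    def test_deterministic_under_permutation_of_tied_hits(self, taxo):
        samples, phylo = taxo
        hits = [
            _hit("OTAN_1_x", "XMQO_5_y"),
            _hit("OTAN_1_x", "ZAAA_3_y"),
            _hit("OTAN_1_x", "GUNT_2_y"),
        ]  # all scores tied: subject id breaks the tie
        donors = set()
        for perm in itertools.permutations(hits):
            v = classify_candidate(_cand(), sorted(perm, key=lambda h: (-h.bitscore, h.evalue, -h.pct_identity, h.subject_id)), samples, phylo)
            donors.add(v.donor_sample)
        assert donors == {"GUNT"}


class TestDedupe:
    def test_highest_identity_occurrence_kept(self):
        c1 = Candidate("OTAN_1_x", "OTAN", "XMQO_1_y", "XMQO", 99.0)
        c2 = Candidate("OTAN_1_x", "OTAN", "GUNT_1_y", "GUNT", 99.8)
        assert dedupe_candidates([c1, c2]) == [c2]


class TestAssignVerdicts:
    def _library(self, n):
        return [TranscriptSeq(f"OTAN_{i}_x", "ACGT") for i in range(1, n + 1)]

    def test_partition_of_candidates_and_clean(self):
        records = self._library(10)
        classified = {
            "OTAN_3_x": Verdict("OTAN_3_x", "OTAN", STATUS_VERIFIED, donor_sample="XMQO"),
            "OTAN_7_x": Verdict("OTAN_7_x", "OTAN", STATUS_VERIFIED, donor_sample="XMQO"),
        }
        verdicts = assign_verdicts(records, classified)
        assert len(verdicts) == 10
        assert sum(v.status == STATUS_VERIFIED for v in verdicts) == 2
        assert sum(v.status == STATUS_CLEAN for v in verdicts) == 8

    def test_no_candidates_all_clean(self):
        verdicts = assign_verdicts(self._library(5), {})
        assert all(v.status == STATUS_CLEAN for v in verdicts)

    def test_unknown_candidate_is_error(self):
        classified = {"OTAN_99_x": Verdict("OTAN_99_x", "OTAN", STATUS_VERIFIED, donor_sample="XMQO")}
        with pytest.raises(ValueError):
            assign_verdicts(self._library(3), classified)

    def test_one_verdict_per_sequence_on_simulated_run(self, small_run):
        result, screened = small_run
        for code, verdicts in screened["verdicts"].items():
            assert len(verdicts) == len(result.libraries[code])
            assert {v.seq_id for v in verdicts} == {r.seq_id for r in result.libraries[code]}


class TestSplitLibrary:
    def test_conservation(self):
        records = [TranscriptSeq(f"OTAN_{i}_x", "ACGT" * i) for i in range(1, 6)]
        verdicts = [
            Verdict(r.seq_id, "OTAN", STATUS_VERIFIED if i == 2 else STATUS_CLEAN)
            for i, r in enumerate(records)
        ]
        clean, contam = split_library(records, verdicts)
        assert len(clean) == 4 and len(contam) == 1
        assert [r.seq_id for r in clean + contam] != []
        assert {r.seq_id for r in clean} | {r.seq_id for r in contam} == {r.seq_id for r in records}

    def test_possible_stays_in_clean_file(self):
        records = [TranscriptSeq("OTAN_1_x", "ACGT")]
        verdicts = [Verdict("OTAN_1_x", "OTAN", STATUS_POSSIBLE)]
        clean, contam = split_library(records, verdicts)
        assert len(clean) == 1 and not contam

    def test_missing_verdict_is_error(self):
        with pytest.raises(ValueError):
            split_library([TranscriptSeq("OTAN_1_x", "A")], [])

    def test_bitwise_conservation_on_simulated_run(self, small_run):
        result, screened = small_run
        for code, records in result.libraries.items():
            clean, contam = split_library(records, screened["verdicts"][code])
            assert len(clean) + len(contam) == len(records)
            merged = {r.seq_id: r.sequence for r in clean}
            merged.update({r.seq_id: r.sequence for r in contam})
            assert merged == {r.seq_id: r.sequence for r in records}


class TestSummaries:
    def test_single_contaminant_bookkeeping(self):
        verdicts = {
            "OTAN": [Verdict("OTAN_1_x", "OTAN", STATUS_VERIFIED, donor_sample="XMQO", partner_seq_id="XMQO_1_y")],
            "XMQO": [Verdict("XMQO_1_y", "XMQO", STATUS_CLEAN)],
        }
        summaries, matrix, pair_list = summarize_libraries(verdicts)
        by_code = {s.sample: s for s in summaries}
        assert by_code["OTAN"].n_contaminant == 1
        assert by_code["XMQO"].n_contaminant_in_others == 1
        assert matrix.loc["OTAN", "XMQO"] == 1
        assert pair_list == [("OTAN_1_x", "XMQO_1_y")]

    def test_no_contaminants_empty_matrix(self):
        verdicts = {"OTAN": [Verdict("OTAN_1_x", "OTAN", STATUS_CLEAN)]}
        summaries, matrix, pair_list = summarize_libraries(verdicts)
        assert matrix.size == 0 and pair_list == []

    def test_matrix_cells_sum_to_total_verified(self, small_run):
        _, screened = small_run
        total = sum(s.n_contaminant for s in screened["summaries"])
        assert screened["matrix"].to_numpy().sum() == total

    def test_library_conservation_invariant(self, small_run):
        _, screened = small_run
        for s in screened["summaries"]:
            assert s.n_contaminant + s.n_clean + s.n_possible == s.n_total


class TestEndToEndAccuracy:
    def test_small_scenario_perfect_detection(self, small_run):
        result, screened = small_run
        m = detection_metrics(result, screened)
        assert m["recall"] == 1.0
        assert m["precision"] == 1.0
        assert m["donor_accuracy"] == 1.0
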