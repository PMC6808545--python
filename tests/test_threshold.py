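"""Identity histograms, cutoff detection, and candidate calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossclean.formats import AlnHit
from crossclean.pairs import PairKey
from crossclean.threshold import (
    IdentityHistogram,
    Match,
    build_histogram,
    call_candidates,
    find_cutoff,
    select_best_matches,
)

from _oracles import cutoff_scan_oracle
from conftest import random_histogram

PAIR = PairKey("AAAA", "BBBB")

#: The worked cutoff example: background rising below 96, valley at 97,
#: contamination peak at 99-100.
WORKED_COUNTS = {100.0: 50, 99.0: 30, 98.0: 5, 97.0: 2, 96.0: 10, 95.0: 40, 94.0: 60}


def _hit(q, s, identity=90.0, bitscore=100.0, evalue=1e-30, length=500):
    return AlnHit(q, s, identity, length, 0, 0, 1, length, 1, length, evalue, bitscore)


def _matches(identities):
    return [
        Match(f"AAAA_{i}_x", "AAAA", f"BBBB_{i}_y", "BBBB", ident)
        for i, ident in enumerate(identities, start=1)
    ]


def hist_from_counts(counts, bin_width=1.0):
    return IdentityHistogram(
        pair=PAIR, bin_width=bin_width, counts=dict(counts), n_total=int(sum(counts.values()))
    )


class TestSelectBestMatches:
    def test_highest_bitscore_wins(self):
        hits = [_hit("AAAA_1_x", "BBBB_1_y", bitscore=300), _hit("AAAA_1_x", "BBBB_2_y", bitscore=800)]
        (m,) = select_best_matches(hits, PAIR)
        assert m.subject_id == "BBBB_2_y"

    def test_no_hits_no_matches(self):
        assert select_best_matches([], PAIR) == []

    def test_hits_outside_pair_ignored(self):
        hits = [_hit("CCCC_1_x", "BBBB_1_y"), _hit("AAAA_1_x", "AAAA_2_y")]
        assert select_best_matches(hits, PAIR) == []

    def test_tie_break_deterministic_under_permutation(self):
        # equal bitscore and e-value: identity decides, then subject id
        hits = [
            _hit("AAAA_1_x", "BBBB_3_y", identity=97.0),
            _hit("AAAA_1_x", "BBBB_2_y", identity=98.0),
            _hit("AAAA_1_x", "BBBB_1_y", identity=98.0),
        ]
        import itertools

        results = set()
        for perm in itertools.permutations(hits):
            (m,) = select_best_matches(list(perm), PAIR)
            results.add(m.subject_id)
        assert results == {"BBBB_1_y"}


class TestBuildHistogram:
    def test_direct_binning(self):
        hist = build_histogram(_matches([85.2, 85.9, 99.5]), 1.0, pair=PAIR)
        assert hist.counts == {85.0: 2, 99.0: 1}
        assert hist.n_total == 3

    def test_identity_100_goes_to_top_bin(self):
        hist = build_histogram(_matches([100.0]), 1.0)
        assert hist.counts == {99.0: 1}

    def test_empty_matches(self):
        hist = build_histogram([], 1.0)
        assert hist.n_total == 0 and hist.counts == {}

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            build_histogram([], 0.0)
        with pytest.raises(ValueError):
            build_histogram([], 3.0)  # does not divide 100

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=100.0), max_size=200))
    def test_counts_sum_to_total(self, identities):
        hist = build_histogram(_matches(identities), 1.0)
        assert sum(hist.counts.values()) == hist.n_total == len(identities)


class TestFindCutoff:
    def test_worked_example(self):
        th = find_cutoff(hist_from_counts(WORKED_COUNTS))
        assert th.status == "found"
        assert th.cutoff == 97.0

    def test_no_mass_near_100_gives_no_peak(self):
        th = find_cutoff(hist_from_counts({80.0: 500}))
        assert th.status == "no_peak" and th.cutoff is None

    def test_unimodal_peak_at_100_is_degenerate(self):
        th = find_cutoff(hist_from_counts({100.0: 50, 99.0: 30, 98.0: 10}))
        assert th.status == "degenerate" and th.cutoff is None

    def test_min_peak_support_monotone(self):
        # raising min_peak_support can only turn found/degenerate into no_peak
        hist = hist_from_counts(WORKED_COUNTS)
        statuses = [find_cutoff(hist, min_peak_support=mps).status for mps in (1, 80, 81, 500)]
        assert statuses == ["found", "found", "no_peak", "no_peak"]

    def test_even_smooth_window_rejected(self):
        with pytest.raises(ValueError):
            find_cutoff(hist_from_counts(WORKED_COUNTS), smooth_window=2)

    def test_agrees_with_exhaustive_oracle_on_random_histograms(self):
        rng = np.random.default_rng(1234)
        n_checked = 0
        for _ in range(300):
            counts = random_histogram(rng)
            if not counts:
                continue
            th = find_cutoff(hist_from_counts(counts))
            expected_cutoff, expected_status = cutoff_scan_oracle(counts)
            assert th.status == expected_status
            assert th.cutoff == expected_cutoff
            n_checked += 1
        assert n_checked > 250

    def test_cutoff_between_background_mode_and_100(self):
        # bimodal histograms: background mode at the species divergence plus
        # a contamination peak near 100 — the generative case the scan targets
        rng = np.random.default_rng(99)
        for _ in range(200):
            mode = float(rng.integers(60, 91))
            width = float(rng.integers(2, 6))
            counts = {}
            for edge in np.arange(mode - 3 * width, min(97.0, mode + 3 * width)):
                c = int(300 * np.exp(-((edge - mode) ** 2) / (2 * width**2)))
                if c > 0:
                    counts[float(edge)] = c
            counts[99.0] = int(rng.integers(5, 100))
            counts[100.0] = int(rng.integers(0, 50))
            th = find_cutoff(hist_from_counts(counts))
            assert th.status == "found"
            assert mode < th.cutoff < 100.0

    def test_simulated_spiked_pair_cutoff_between_divergence_and_peak(self, default_run):
        result, screened = default_run
        pair = PairKey(result.config.donor, result.config.recipient)
        th, n_matches = screened["thresholds"][pair]
        assert th.status == "found"
        assert 86.0 < th.cutoff < 99.0


class TestCallCandidates:
    def test_threshold_application(self):
        matches = _matches([99.5, 96.0, 98.2])
        th = find_cutoff(hist_from_counts(WORKED_COUNTS))
        cands = call_candidates(matches, th)
        assert {c.identity for c in cands} == {99.5, 98.2}
        assert len(cands) == 4  # two per flagged match, one per library
        assert {c.sample for c in cands} == {"AAAA", "BBBB"}

    def test_no_cutoff_no_candidates(self):
        th = find_cutoff(hist_from_counts({80.0: 500}))
        assert call_candidates(_matches([99.9]), th) == []

    def test_monotone_in_cutoff(self):
        matches = _matches(np.linspace(80, 100, 50))
        from crossclean.threshold import Threshold

        sizes = [
            len(call_candidates(matches, Threshold(PAIR, c, 10, "found")))
            for c in (85.0, 90.0, 95.0, 99.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_all_spiked_contaminants_recovered(self, default_run):
        result, screened = default_run
        flagged = {c.seq_id for c in screened["candidates"]}
        spiked = {sid for sid, t in result.truth.items() if t.is_contaminant}
        assert spiked <= flagged
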