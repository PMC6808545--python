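from __future__ import annotations

import numpy as np
import pytest

from crossclean.formats import SampleMeta, parse_newick_string
from crossclean.pipeline import screen_scenario
from crossclean.simulate import SimConfig, simulate


def random_histogram(rng: np.random.Generator) -> dict[float, int]:
    """A random identity histogram mixing the regimes the scanner must face:
    a background mode at the species divergence, an optional near-100%
    contamination peak, sparse noise, and occasional empty/degenerate shapes.
    """
    counts: dict[float, int] = {}
    regime = rng.integers(0, 4)
    if regime != 3:  # background mode somewhere in (55, 95)
        mode = float(rng.integers(55, 95))
        width = float(rng.integers(2, 8))
        for edge in np.arange(max(0.0, mode - 3 * width), min(99.0, mode + 3 * width)):
            c = int(200 * np.exp(-((edge - mode) ** 2) / (2 * width**2)))
            if c > 0:
                counts[float(edge)] = c
    if regime in (1, 3):  # near-100% spike
        counts[99.0] = counts.get(99.0, 0) + int(rng.integers(1, 80))
        if rng.random() < 0.5:
            counts[100.0] = counts.get(100.0, 0) + int(rng.integers(1, 40))
        if rng.random() < 0.5:
            counts[98.0] = counts.get(98.0, 0) + int(rng.integers(1, 10))
    for _ in range(int(rng.integers(0, 6))):  # sparse noise bins
        edge = float(rng.integers(0, 101))
        counts[edge] = counts.get(edge, 0) + int(rng.integers(1, 5))
    return counts


def detection_metrics(result, screened) -> dict[str, float]:
    """Precision/recall/donor accuracy of verified contaminants vs truth."""
    truth = result.truth
    tp = fp = donor_ok = 0
    for verdicts in screened["verdicts"].values():
        for v in verdicts:
            if v.status != "verified_contaminant":
                continue
            if truth[v.seq_id].is_contaminant:
                tp += 1
                if v.donor_sample == truth[v.seq_id].donor_sample:
                    donor_ok += 1
            else:
                fp += 1
    n_true = sum(1 for t in truth.values() if t.is_contaminant)
    return {
        "tp": tp,
        "fp": fp,
        "fn": n_true - tp,
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "recall": tp / n_true if n_true else float("nan"),
        "donor_accuracy": donor_ok / tp if tp else float("nan"),
    }


def run_default_scenario(seed: int, **overrides):
    """Simulate the default 3-library spiked scenario and screen it."""
    result = simulate(SimConfig(seed=seed, **overrides))
    phylo = parse_newick_string(result.tree_newick)
    screened = screen_scenario(
        result.samples, phylo, result.pair_hits, result.research_hits, result.libraries
    )
    return result, screened


@pytest.fixture(scope="session")
def default_run():
    """One full simulated run of the default scenario (seed 11), screened."""
    return run_default_scenario(11)


@pytest.fixture(scope="session")
def small_run():
    """A quick scenario (300 transcripts) for structural/IO tests."""
    return run_default_scenario(7, n_transcripts=300)


EIGHT_LEAF_CODES = ("AAAA", "BBBB", "CCCC", "DDDD", "EEEE", "FFFF", "GGGG", "HHHH")
EIGHT_LEAF_NEWICK = "(((AAAA,BBBB),(CCCC,DDDD)),((EEEE,FFFF),(GGGG,HHHH)));"


@pytest.fixture()
def eight_leaf_tree():
    return parse_newick_string(EIGHT_LEAF_NEWICK)


@pytest.fixture()
def sample_map():
    def make(**families: str) -> dict[str, SampleMeta]:
        return {
            code: SampleMeta(code=code, species=f"Species {code.lower()}", family=fam, clade="Embryophyta")
            for code, fam in families.items()
        }

    return make
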