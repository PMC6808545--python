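"""Per-pair identity distributions and the contamination cutoff.

For an eligible pair of libraries the percent identities of best-matched
sequences form a distribution with a single mode at the pairwise divergence
of the two species.  Cross-contamination adds a second mode near 100%
identity (a contaminant is an almost exact copy of its donor).  Scanning the
binned distribution downward from 100%, the first local minimum below the
near-100% peak separates the two modes and becomes the per-pair cutoff:
matches at or above it are contamination candidates in one or both
libraries.

No curve fitting or mixture modelling is attempted — the cutoff is a direct
scan of the histogram, optionally after a short moving-average smooth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .formats import AlnHit, sample_code_from_id
from .pairs import PairKey

STATUS_FOUND = "found"
STATUS_NO_PEAK = "no_peak"
STATUS_DEGENERATE = "degenerate"

#: Lower edge of the "near-100%" region used to require a contamination peak.
PEAK_REGION_LOWER = 99.0


@dataclass
class Match:
    """One best-matched sequence pair between the two libraries of a pair."""

    query_id: str
    query_sample: str
    subject_id: str
    subject_sample: str
    identity: float


@dataclass
class IdentityHistogram:
    """Binned identity counts for one library pair.

    ``counts`` maps each bin's lower edge to the number of matches whose
    identity falls in ``[edge, edge + bin_width)``; identity exactly 100 is
    assigned to the top bin.
    """

    pair: PairKey | None
    bin_width: float
    counts: dict[float, int]
    n_total: int


@dataclass
class Threshold:
    """Detected contamination cutoff for one library pair."""

    pair: PairKey | None
    cutoff: float | None
    peak_support: int
    status: str  # found | no_peak | degenerate


@dataclass
class Candidate:
    """One potential contaminant sequence flagged by the cutoff.

    Every flagged match produces two candidates — one per library — because
    the histogram alone cannot tell donor from recipient.
    """

    seq_id: str
    sample: str
    partner_seq_id: str
    partner_sample: str
    identity: float


def _hit_rank(hit: AlnHit) -> tuple:
    # Highest bitscore, then lowest e-value, then highest identity, then
    # subject id: deterministic under any input permutation.
    return (-hit.bitscore, hit.evalue, -hit.pct_identity, hit.subject_id)


def select_best_matches(hits: Iterable[AlnHit], pair: PairKey) -> list[Match]:
    """Reduce raw hits of one pair to the single best hit per query sequence.

    Only cross-library hits between the two members of ``pair`` are used;
    matches therefore count sequences, not alignments, and self-pairs are
    impossible by construction.  Ties are broken by bitscore, e-value,
    identity, then subject id, so the result is independent of input order.
    """
    members = {pair.a, pair.b}
    best: dict[str, AlnHit] = {}
    order: list[str] = []
    for hit in hits:
        qs = sample_code_from_id(hit.query_id)
        ss = sample_code_from_id(hit.subject_id)
        if qs not in members or ss not in members or qs == ss:
            continue
        prev = best.get(hit.query_id)
        if prev is None:
            best[hit.query_id] = hit
            order.append(hit.query_id)
        elif _hit_rank(hit) < _hit_rank(prev):
            best[hit.query_id] = hit
    matches = []
    for qid in sorted(order):
        h = best[qid]
        matches.append(
            Match(
                query_id=h.query_id,
                query_sample=sample_code_from_id(h.query_id),
                subject_id=h.subject_id,
                subject_sample=sample_code_from_id(h.subject_id),
                identity=h.pct_identity,
            )
        )
    return matches


def build_histogram(
    matches: Sequence[Match],
    bin_width: float = 1.0,
    pair: PairKey | None = None,
) -> IdentityHistogram:
    """Bin match identities into an :class:`IdentityHistogram`.

    ``bin_width`` must divide 100 evenly.  Bins are half-open
    ``[edge, edge + bin_width)`` with identity 100 assigned to the top bin.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive (got {bin_width})")
    n_bins = 100.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin_width must divide 100 evenly (got {bin_width})")
    top_edge = 100.0 - bin_width
    counts: dict[float, int] = {}
    for m in matches:
        edge = np.floor(m.identity / bin_width) * bin_width
        if edge >= 100.0:
            edge = top_edge
        counts[edge] = counts.get(edge, 0) + 1
    return IdentityHistogram(pair=pair, bin_width=bin_width, counts=counts, n_total=len(matches))


def _dense_counts(hist: IdentityHistogram) -> tuple[np.ndarray, np.ndarray]:
    """Expand the sparse count mapping into a dense ascending grid from 0."""
    bw = hist.bin_width
    if hist.counts:
        max_edge = max(hist.counts)
    else:
        max_edge = 100.0 - bw
    n = int(round(max_edge / bw)) + 1
    edges = np.arange(n) * bw
    counts = np.zeros(n)
    for edge, c in hist.counts.items():
        counts[int(round(edge / bw))] += c
    return edges, counts


def find_cutoff(
    hist: IdentityHistogram,
    min_peak_support: int = 5,
    smooth_window: int = 1,
) -> Threshold:
    """Detect the contamination cutoff of one pair's identity histogram.

    A contaminated pair must show appreciable mass near 100% identity: if the
    raw count in bins overlapping (99, 100] is below ``min_peak_support`` the
    status is ``no_peak`` and no cutoff is reported.  Otherwise the (optionally
    smoothed) counts are scanned downward from the top bin, and the cutoff is
    the lower edge of the first bin whose count is <= the bin above and
    strictly < the bin below — the first local minimum.  If the counts never
    rise again before the bottom of the histogram (a unimodal near-100% pile,
    e.g. an unexcluded conspecific pair) the status is ``degenerate``.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError(f"smooth_window must be an odd count >= 1 (got {smooth_window})")
    bw = hist.bin_width
    peak_support = int(
        sum(c for edge, c in hist.counts.items() if edge + bw > PEAK_REGION_LOWER)
    )
    if peak_support < min_peak_support:
        return Threshold(hist.pair, None, peak_support, STATUS_NO_PEAK)
    edges, counts = _dense_counts(hist)
    if smooth_window > 1:
        kernel = np.ones(smooth_window)
        counts = np.convolve(counts, kernel, mode="same") / np.convolve(
            np.ones_like(counts), kernel, mode="same"
        )
    for i in range(len(edges) - 2, 0, -1):
        if counts[i] <= counts[i + 1] and counts[i] < counts[i - 1]:
            return Threshold(hist.pair, float(edges[i]), peak_support, STATUS_FOUND)
    return Threshold(hist.pair, None, peak_support, STATUS_DEGENERATE)


def call_candidates(matches: Sequence[Match], th: Threshold) -> list[Candidate]:
    """Flag every match at or above the cutoff, one candidate per library.

    Identity ties at exactly the cutoff are flagged (>=, not >): conservative
    toward contamination detection.  Without a found cutoff there are no
    candidates.
    """
    if th.status != STATUS_FOUND:
        return []
    out: list[Candidate] = []
    for m in matches:
        if m.identity >= th.cutoff:
            out.append(Candidate(m.query_id, m.query_sample, m.subject_id, m.subject_sample, m.identity))
            out.append(Candidate(m.subject_id, m.subject_sample, m.query_id, m.query_sample, m.identity))
    return out


def write_histogram(hist: IdentityHistogram, path: str | Path) -> None:
    """Dump one pair's histogram as TSV ``bin_lower  count``."""
    with open(path, "w") as fh:
        fh.write("bin_lower\tcount\n")
        for edge in sorted(hist.counts):
            fh.write(f"{edge:g}\t{hist.counts[edge]}\n")


def write_threshold_report(thresholds: Iterable[tuple[Threshold, int]], path: str | Path) -> None:
    """Write the per-pair threshold report.

    ``thresholds`` yields (threshold, n_matches) tuples; columns are
    ``code_a  code_b  status  cutoff  n_matches  peak_support``.
    """
    with open(path, "w") as fh:
        fh.write("code_a\tcode_b\tstatus\tcutoff\tn_matches\tpeak_support\n")
        for th, n_matches in thresholds:
            cutoff = "" if th.cutoff is None else f"{th.cutoff:g}"
            a = th.pair.a if th.pair else ""
            b = th.pair.b if th.pair else ""
            fh.write(f"{a}\t{b}\t{th.status}\t{cutoff}\t{n_matches}\t{th.peak_support}\n")
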