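"""Donor/recipient resolution, per-sequence verdicts, and summary tables.

A candidate flagged by the identity cutoff may be a contaminant — or it may
be the contaminant's legitimate source (the donor), since both sides of a
near-100% match look the same in the histogram.  The direction is resolved
by re-searching each candidate against all non-candidate assemblies and
inspecting the top hits (``n_top`` = 3, matching ``-max_target_seqs 3``):

* any of the top hits from the candidate's own family, or from a taxon
  closer than ``close_branches`` edges in the consensus tree, rescues the
  sequence (``excluded_close_taxon``) — a genuine sequence finds its own
  relatives;
* top hits exclusively from distant taxa verify the sequence as a
  contaminant, with the best hit's library as the inferred donor;
* no evidence at all leaves the sequence ``unresolved_possible`` — it might
  occur as a contaminant but is verified only on positive distant-hit
  evidence.

Only verified contaminants are removed when a library is split into clean
and contaminant FASTA files; rescued and unresolved sequences stay in the
clean file and are counted in the summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .formats import AlnHit, Phylogeny, SampleMeta, TranscriptSeq, sample_code_from_id
from .pairs import PairKey
from .threshold import Candidate

logger = logging.getLogger(__name__)

STATUS_CLEAN = "clean"
STATUS_VERIFIED = "verified_contaminant"
STATUS_EXCLUDED = "excluded_close_taxon"
STATUS_POSSIBLE = "unresolved_possible"


@dataclass
class Verdict:
    """Final status of one sequence after the re-search step."""

    seq_id: str
    sample: str
    status: str
    donor_sample: str | None = None
    partner_seq_id: str | None = None
    evidence: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class LibrarySummary:
    sample: str
    n_total: int
    n_contaminant: int
    n_clean: int
    n_possible: int
    n_contaminant_in_others: int


def _research_rank(hit: AlnHit) -> tuple:
    return (-hit.bitscore, hit.evalue, -hit.pct_identity, hit.subject_id)


def prepare_research_hits(
    hits: Iterable[AlnHit],
    cand: Candidate,
) -> list[AlnHit]:
    """Select and order the re-search evidence for one candidate.

    Keeps hits whose query is the candidate, drops subjects from the
    candidate's own library (a sequence trivially matches itself), and sorts
    best-first.  Subjects from all other libraries remain searchable — that
    is what lets the re-search name the true donor of a contaminant.
    """
    rel = []
    for h in hits:
        if h.query_id != cand.seq_id:
            continue
        ss = sample_code_from_id(h.subject_id)
        if ss == cand.sample:
            continue
        rel.append(h)
    rel.sort(key=_research_rank)
    return rel


def classify_candidate(
    cand: Candidate,
    research_hits: Sequence[AlnHit],
    samples: dict[str, SampleMeta],
    phylo: Phylogeny | None,
    close_branches: int = 2,
    n_top: int = 3,
) -> Verdict:
    """Resolve one candidate into a verdict from its top re-search hits.

    ``research_hits`` must be sorted best-first with own-library subjects
    removed (see :func:`prepare_research_hits`).  A hit whose subject id has
    no parseable library code is skipped with a warning.
    """
    cand_family = None
    if cand.sample in samples:
        cand_family = samples[cand.sample].family.strip().casefold()
    considered: list[AlnHit] = []
    for h in research_hits:
        if sample_code_from_id(h.subject_id) is None:
            logger.warning("re-search hit subject %r has no parseable sample code; skipped", h.subject_id)
            continue
        considered.append(h)
        if len(considered) == n_top:
            break
    if not considered:
        return Verdict(cand.seq_id, cand.sample, STATUS_POSSIBLE, partner_seq_id=cand.partner_seq_id)
    evidence = [(sample_code_from_id(h.subject_id), h.pct_identity) for h in considered]
    for subj_sample, _ in evidence:
        if cand_family is not None and subj_sample in samples:
            if samples[subj_sample].family.strip().casefold() == cand_family:
                return Verdict(
                    cand.seq_id, cand.sample, STATUS_EXCLUDED,
                    partner_seq_id=cand.partner_seq_id, evidence=evidence,
                )
        if phylo is not None and cand.sample in phylo and subj_sample in phylo:
            if phylo.distance(cand.sample, subj_sample) < close_branches:
                return Verdict(
                    cand.seq_id, cand.sample, STATUS_EXCLUDED,
                    partner_seq_id=cand.partner_seq_id, evidence=evidence,
                )
    donor = evidence[0][0]
    return Verdict(
        cand.seq_id, cand.sample, STATUS_VERIFIED,
        donor_sample=donor, partner_seq_id=cand.partner_seq_id, evidence=evidence,
    )


def dedupe_candidates(candidates: Iterable[Candidate]) -> list[Candidate]:
    """Collapse candidates flagged in several pairs to one per sequence.

    Keeps the occurrence with the highest identity (ties: lexicographic
    partner id), so the re-search partner recorded is the closest one.
    """
    best: dict[str, Candidate] = {}
    for c in candidates:
        prev = best.get(c.seq_id)
        if prev is None or (-c.identity, c.partner_seq_id) < (-prev.identity, prev.partner_seq_id):
            best[c.seq_id] = c
    return [best[k] for k in sorted(best)]


def classify_candidates(
    candidates: Iterable[Candidate],
    research_hits: Iterable[AlnHit],
    samples: dict[str, SampleMeta],
    phylo: Phylogeny | None,
    close_branches: int = 2,
    n_top: int = 3,
) -> dict[str, Verdict]:
    """Classify every (de-duplicated) candidate; returns verdicts by seq_id."""
    cands = dedupe_candidates(candidates)
    hits_by_query: dict[str, list[AlnHit]] = {}
    for h in research_hits:
        hits_by_query.setdefault(h.query_id, []).append(h)
    verdicts: dict[str, Verdict] = {}
    for cand in cands:
        rel = prepare_research_hits(hits_by_query.get(cand.seq_id, []), cand)
        verdicts[cand.seq_id] = classify_candidate(
            cand, rel, samples, phylo, close_branches=close_branches, n_top=n_top
        )
    return verdicts


def assign_verdicts(
    records: Sequence[TranscriptSeq],
    classified: dict[str, Verdict],
) -> list[Verdict]:
    """Give every sequence of a library exactly one verdict.

    Non-candidate sequences are clean; candidates take their classification.
    A classification referencing a sequence not in the library is an error.
    """
    ids = {r.seq_id for r in records}
    sample_codes = {r.sample_code for r in records}
    unknown = {
        sid for sid, v in classified.items()
        if sid not in ids and v.sample in sample_codes
    }
    if unknown:
        raise ValueError(f"classified candidate(s) not present in library: {sorted(unknown)[:5]}")
    out = []
    for r in records:
        if r.seq_id in classified:
            out.append(classified[r.seq_id])
        else:
            out.append(Verdict(r.seq_id, r.sample_code, STATUS_CLEAN))
    return out


def split_library(
    records: Sequence[TranscriptSeq],
    verdicts: Sequence[Verdict],
) -> tuple[list[TranscriptSeq], list[TranscriptSeq]]:
    """Partition a library into (clean, contaminant) record lists.

    Only verified contaminants go to the contaminant file; rescued and
    unresolved sequences stay clean.  Input order is preserved within each
    file and counts are conserved.
    """
    status_by_id = {v.seq_id: v.status for v in verdicts}
    missing = [r.seq_id for r in records if r.seq_id not in status_by_id]
    if missing:
        raise ValueError(f"missing verdict for record(s): {missing[:5]}")
    clean, contam = [], []
    for r in records:
        if status_by_id[r.seq_id] == STATUS_VERIFIED:
            contam.append(r)
        else:
            clean.append(r)
    return clean, contam


def summarize_libraries(
    verdicts_by_library: dict[str, Sequence[Verdict]],
) -> tuple[list[LibrarySummary], pd.DataFrame, list[tuple[str, str]]]:
    """Build per-library counts, the contamination matrix, and the pair list.

    Matrix cell (r, c) counts verified contaminants in library r whose donor
    is c (contaminated rows, contaminating columns; no diagonal).  The pair
    list is written contaminant-first: (contaminant seq id, orthologous
    contaminating partner seq id).
    """
    donated: dict[str, int] = {}
    for verdicts in verdicts_by_library.values():
        for v in verdicts:
            if v.status == STATUS_VERIFIED and v.donor_sample:
                donated[v.donor_sample] = donated.get(v.donor_sample, 0) + 1

    summaries: list[LibrarySummary] = []
    cells: dict[tuple[str, str], int] = {}
    pair_list: list[tuple[str, str]] = []
    for code in sorted(verdicts_by_library):
        verdicts = verdicts_by_library[code]
        n_ver = sum(1 for v in verdicts if v.status == STATUS_VERIFIED)
        n_pos = sum(1 for v in verdicts if v.status == STATUS_POSSIBLE)
        n_clean = len(verdicts) - n_ver - n_pos  # clean + rescued-close-taxon
        summaries.append(
            LibrarySummary(
                sample=code,
                n_total=len(verdicts),
                n_contaminant=n_ver,
                n_clean=n_clean,
                n_possible=n_pos,
                n_contaminant_in_others=donated.get(code, 0),
            )
        )
        for v in verdicts:
            if v.status == STATUS_VERIFIED:
                cells[(code, v.donor_sample)] = cells.get((code, v.donor_sample), 0) + 1
                if v.partner_seq_id:
                    pair_list.append((v.seq_id, v.partner_seq_id))

    rows = sorted({r for r, _ in cells})
    cols = sorted({c for _, c in cells})
    matrix = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for (r, c), n in cells.items():
        matrix.loc[r, c] = n
    matrix.index.name = "contaminated"
    matrix.columns.name = "contaminating"
    return summaries, matrix, pair_list


def write_summary(summaries: Iterable[LibrarySummary], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("code\tn_total\tn_contaminant\tn_clean\tn_possible\tn_contaminant_in_others\n")
        for s in summaries:
            fh.write(
                f"{s.sample}\t{s.n_total}\t{s.n_contaminant}\t{s.n_clean}\t"
                f"{s.n_possible}\t{s.n_contaminant_in_others}\n"
            )


def write_pair_list(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contaminant_seq_id\tpartner_seq_id\n")
        for contam, partner in pairs:
            fh.write(f"{contam}\t{partner}\n")


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")
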