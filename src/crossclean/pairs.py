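"""Enumerate library pairs for the all-vs-all contamination search.

Closely related libraries legitimately share near-identical sequences, so
comparing them would flag ordinary orthologs as contamination.  Two rules
keep such pairs out of the search: libraries from the same taxonomic family
are never compared, and neither are libraries separated by ``max_branches``
(default 2) or fewer edges on the consensus phylogeny.  Under the edge-count
metric sister leaves sit 2 apart, so the default excludes the closest
relatives in the tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable

from .formats import Phylogeny, SampleMeta

logger = logging.getLogger(__name__)

REASON_SAME_FAMILY = "same_family"
REASON_TREE_DISTANCE = "tree_distance"
REASON_NONE = "none"


@dataclass(frozen=True)
class PairKey:
    """Unordered pair of library codes, stored in lexicographic order."""

    a: str
    b: str

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"a pair requires two distinct codes (got {self.a!r} twice)")
        if self.a > self.b:
            lo, hi = self.b, self.a
            object.__setattr__(self, "a", lo)
            object.__setattr__(self, "b", hi)

    def __iter__(self):
        return iter((self.a, self.b))

    def other(self, code: str) -> str:
        if code == self.a:
            return self.b
        if code == self.b:
            return self.a
        raise KeyError(f"{code!r} is not a member of pair {self.a}-{self.b}")


@dataclass
class ExclusionDecision:
    pair: PairKey
    excluded: bool
    reason: str  # same_family | tree_distance | none
    tree_distance: int | None = None


def tree_distance(phylo: Phylogeny, a: str, b: str) -> int:
    """Edge count on the unique leaf-to-leaf path between codes a and b."""
    return phylo.distance(a, b)


def _same_family(sa: SampleMeta, sb: SampleMeta) -> bool:
    return sa.family.strip().casefold() == sb.family.strip().casefold()


def decide_exclusion(
    pair: PairKey,
    samples: dict[str, SampleMeta],
    phylo: Phylogeny | None,
    max_branches: int = 2,
) -> ExclusionDecision:
    """Apply the same-family and close-in-tree exclusion rules to one pair.

    The decision is symmetric in the pair.  When a code is missing from the
    tree the tree criterion is skipped (the family rule still applies) and a
    warning is emitted.
    """
    sa, sb = samples[pair.a], samples[pair.b]
    dist: int | None = None
    if phylo is not None:
        if pair.a in phylo and pair.b in phylo:
            dist = phylo.distance(pair.a, pair.b)
        else:
            absent = [c for c in pair if c not in phylo]
            logger.warning(
                "code(s) %s absent from phylogeny; tree criterion skipped for pair %s-%s",
                ",".join(absent),
                pair.a,
                pair.b,
            )
    if _same_family(sa, sb):
        return ExclusionDecision(pair, True, REASON_SAME_FAMILY, dist)
    if dist is not None and dist <= max_branches:
        return ExclusionDecision(pair, True, REASON_TREE_DISTANCE, dist)
    return ExclusionDecision(pair, False, REASON_NONE, dist)


def eligible_pairs(
    samples: dict[str, SampleMeta],
    phylo: Phylogeny | None,
    max_branches: int = 2,
) -> tuple[list[PairKey], list[ExclusionDecision]]:
    """Partition all C(n,2) canonical pairs into eligible and excluded.

    Returns the eligible pairs plus the exclusion decisions for the excluded
    ones (mirroring the release's list of close pairs that were not compared).
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to form pairs")
    eligible: list[PairKey] = []
    excluded: list[ExclusionDecision] = []
    for a, b in combinations(sorted(samples), 2):
        decision = decide_exclusion(PairKey(a, b), samples, phylo, max_branches)
        if decision.excluded:
            excluded.append(decision)
        else:
            eligible.append(decision.pair)
    return eligible, excluded


def write_excluded_pairs(decisions: Iterable[ExclusionDecision], path: str | Path) -> None:
    """Write the excluded-pairs report: ``code_a  code_b  reason  tree_distance``."""
    with open(path, "w") as fh:
        fh.write("code_a\tcode_b\treason\ttree_distance\n")
        for d in decisions:
            dist = "" if d.tree_distance is None else str(d.tree_distance)
            fh.write(f"{d.pair.a}\t{d.pair.b}\t{d.reason}\t{dist}\n")
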