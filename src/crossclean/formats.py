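"""Readers, writers and record types shared across the pipeline.

Every external format the pipeline touches comes through here: multi-record
FASTA assemblies, 12-column tab-separated similarity-search tables (the BLAST
``outfmt 6`` dialect, which also carries converted LAST output), the sample
metadata table, and the single-tree Newick consensus phylogeny.  Downstream
modules never re-parse files themselves; they consume the dataclasses defined
below.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

SAMPLE_CODE_RE = re.compile(r"^[A-Z]{4}$")

#: Separators accepted between the 4-letter library code and the rest of a
#: scaffold identifier (both occur in the wild).
CODE_SEPARATORS = ("_", "-")


class FormatError(ValueError):
    """Base class for malformed input files."""


class ParseError(FormatError):
    """A file could not be parsed (names the offending line where possible)."""


class ValidationError(FormatError):
    """Parsed content violates an invariant (duplicate codes, bad leaf names...)."""


def sample_code_from_id(seq_id: str) -> str | None:
    """Extract the 4-letter library code leading a scaffold identifier.

    The code is the first four characters and must be followed by a ``_`` or
    ``-`` separator (a bare 4-letter id is also accepted).  Returns ``None``
    when the identifier does not follow the naming scheme.
    """
    head = seq_id[:4]
    if not SAMPLE_CODE_RE.match(head):
        return None
    if len(seq_id) == 4 or seq_id[4] in CODE_SEPARATORS:
        return head
    return None


@dataclass
class SampleMeta:
    """One library: its 4-letter code plus taxonomic context."""

    code: str
    species: str
    family: str
    clade: str

    def __post_init__(self) -> None:
        if not SAMPLE_CODE_RE.match(self.code):
            raise ValidationError(f"invalid sample code {self.code!r} (expected [A-Z]{{4}})")


@dataclass
class TranscriptSeq:
    """One assembled transcript (scaffold/contig) from a library."""

    seq_id: str
    sequence: str
    sample_code: str | None = None

    def __post_init__(self) -> None:
        if self.sample_code is None:
            self.sample_code = sample_code_from_id(self.seq_id)


@dataclass
class AlnHit:
    """One row of 12-column tabular similarity-search output.

    Coordinates are 1-based inclusive as in tabular BLAST; reversed subject
    coordinates encode the minus strand.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float


def read_fasta(path: str | Path) -> list[TranscriptSeq]:
    """Read a FASTA file into :class:`TranscriptSeq` records, order preserved.

    The header up to the first whitespace becomes ``seq_id``.  Records whose
    identifier does not begin with a valid 4-letter code are kept with
    ``sample_code`` unset and a warning is logged.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ParseError(f"{path}: line {lineno}: sequence data before first '>' header")
            break
    records: list[TranscriptSeq] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ts = TranscriptSeq(seq_id=rec.id, sequence=str(rec.seq))
        if ts.sample_code is None:
            logger.warning("%s: record %r has no parseable 4-letter sample code", path, rec.id)
        records.append(ts)
    return records


def write_fasta(records: Iterable[TranscriptSeq], path: str | Path) -> None:
    """Write records as standard FASTA with 60-column wrapping."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.seq_id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def parse_tabular_hits(path: str | Path) -> list[AlnHit]:
    """Parse a 12-column tab-separated hit table (BLAST outfmt-6 dialect).

    ``#``-prefixed comment lines and blank lines are skipped.  Rows retain
    input order.  A wrong column count or a non-numeric numeric field raises
    :class:`ParseError` naming the row.
    """
    path = Path(path)
    hits: list[AlnHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}: row {lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                hit = AlnHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}: row {lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_tabular_hits(hits: Iterable[AlnHit], path: str | Path) -> None:
    """Write hits as a 12-column tab-separated table (inverse of the parser)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        repr(h.pct_identity),  # shortest repr: parses back bit-equal
                        str(h.aln_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        repr(h.evalue),
                        repr(h.bitscore),
                    ]
                )
                + "\n"
            )


SAMPLE_TABLE_COLUMNS = ("code", "species", "family", "clade")


def read_sample_table(path: str | Path) -> dict[str, SampleMeta]:
    """Read the sample metadata TSV (header ``code  species  family  clade``).

    Duplicate codes are rejected; headers are mandatory (no positional mode),
    since a silently swapped column is the classic failure for these tables.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t")
        missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in header]
        if missing:
            raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")
        idx = {c: header.index(c) for c in SAMPLE_TABLE_COLUMNS}
        samples: dict[str, SampleMeta] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < len(header):
                raise ParseError(f"{path}: row {lineno}: expected {len(header)} columns")
            code = fields[idx["code"]].strip()
            if code in samples:
                raise ValidationError(f"{path}: duplicate sample code {code!r}")
            samples[code] = SampleMeta(
                code=code,
                species=fields[idx["species"]].strip(),
                family=fields[idx["family"]].strip(),
                clade=fields[idx["clade"]].strip(),
            )
    return samples


def write_sample_table(samples: dict[str, SampleMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SAMPLE_TABLE_COLUMNS) + "\n")
        for code in sorted(samples):
            s = samples[code]
            fh.write(f"{s.code}\t{s.species}\t{s.family}\t{s.clade}\n")


class Phylogeny:
    """A consensus phylogeny whose leaves are 4-letter library codes.

    Only the topology is used: the distance between two libraries is the
    number of edges on the unique leaf-to-leaf path of the tree as written
    (branch lengths are ignored).
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.leaf_index: dict[str, dendropy.Node] = {}
        labels = []
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon is not None else leaf.label
            labels.append(label)
            self.leaf_index[label] = leaf
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValidationError(f"duplicate leaf name(s) in tree: {', '.join(sorted(dupes))}")

    @property
    def leaf_names(self) -> set[str]:
        return set(self.leaf_index)

    def __contains__(self, code: str) -> bool:
        return code in self.leaf_index

    def distance(self, a: str, b: str) -> int:
        """Topological distance: edge count on the path between leaves a and b."""
        if a not in self.leaf_index:
            raise KeyError(f"code {a!r} is not a leaf of the phylogeny")
        if b not in self.leaf_index:
            raise KeyError(f"code {b!r} is not a leaf of the phylogeny")
        if a == b:
            return 0
        steps_up: dict[int, tuple[dendropy.Node, int]] = {}
        node = self.leaf_index[a]
        depth = 0
        while node is not None:
            steps_up[id(node)] = (node, depth)
            node = node.parent_node
            depth += 1
        node = self.leaf_index[b]
        depth = 0
        while node is not None:
            if id(node) in steps_up:
                return steps_up[id(node)][1] + depth
            node = node.parent_node
            depth += 1
        raise ValidationError(f"leaves {a!r} and {b!r} share no common ancestor")


def _tree_from(source: str, **kwargs) -> Phylogeny:
    try:
        tree = dendropy.Tree.get(
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            **kwargs,
        )
    except Exception as exc:  # dendropy raises several parse exception types
        if "Duplicate" in type(exc).__name__ or "duplicate" in str(exc).lower():
            raise ValidationError(f"{source}: duplicate leaf names in tree: {exc}") from exc
        raise ParseError(f"{source}: could not parse Newick tree: {exc}") from exc
    return Phylogeny(tree)


def read_newick(path: str | Path) -> Phylogeny:
    """Read a single-tree Newick file into a :class:`Phylogeny` (topology only)."""
    path = Path(path)
    return _tree_from(str(path), path=str(path))


def parse_newick_string(newick: str) -> Phylogeny:
    """Parse an in-memory Newick string (used by the simulator and tests)."""
    return _tree_from("<string>", data=newick)
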