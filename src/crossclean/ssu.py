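"""Sample validation from 18S/SSU rRNA searches against a lineage-annotated
reference set.

The 18S rRNA gene is highly expressed and taxonomically informative, so a
library's assembled 18S-like scaffolds are a sensitive check of what
organism(s) were actually sequenced.  Each assembly is searched against an
SSU reference set (e.g. SILVA); short or weak alignments (< 300 bp or
e-value > 1e-9) tend to match several distantly related species and are
ignored.  The surviving hit with the lowest e-value assigns each scaffold a
taxonomic origin; a sample is *validated* when at least one scaffold is
assigned to the expected family, and flagged as *worrisome contamination*
when any scaffold is assigned to a plant family other than the expected one.
A sample with no surviving assignment is neither — usually a failure to
assemble the 18S sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .formats import AlnHit, ParseError, SampleMeta, sample_code_from_id

logger = logging.getLogger(__name__)

#: Default minimum alignment length (bp) for a usable SSU hit.
DEFAULT_MIN_LEN = 300
#: Default maximum e-value for a usable SSU hit.
DEFAULT_MAX_EVALUE = 1e-9

#: Clade labels whose presence in a reference lineage marks it as a plant.
DEFAULT_PLANT_CLADES = frozenset(
    {"viridiplantae", "chlorophyta", "streptophyta", "embryophyta"}
)


@dataclass
class SsuHit:
    """One SSU search hit of an assembly scaffold against a reference."""

    scaffold_id: str
    sample: str | None
    ref_id: str
    ref_family: str
    ref_lineage: str
    aln_length: int
    evalue: float
    pct_identity: float


@dataclass
class SampleValidation:
    """Per-sample verdict of the SSU check."""

    sample: str
    validated: bool
    worrisome: bool
    assigned_families: list[tuple[str, int]] = field(default_factory=list)
    n_ssu_scaffolds: int = 0


def read_ref_lineages(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read the reference-lineage TSV ``ref_id  family  lineage``.

    Reference families come from this curated table rather than free-text
    reference descriptions, whose formats vary by database release.
    """
    path = Path(path)
    lineages: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#") or (lineno == 1 and line.startswith("ref_id")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}: row {lineno}: expected 3 columns (ref_id, family, lineage)")
            lineages[fields[0]] = (fields[1], fields[2])
    return lineages


def annotate_ssu_hits(
    hits: Iterable[AlnHit],
    lineages: dict[str, tuple[str, str]],
) -> list[SsuHit]:
    """Attach reference lineage annotations to raw tabular SSU hits."""
    out = []
    for h in hits:
        if h.subject_id not in lineages:
            logger.warning("SSU reference %r has no lineage annotation; hit skipped", h.subject_id)
            continue
        family, lineage = lineages[h.subject_id]
        out.append(
            SsuHit(
                scaffold_id=h.query_id,
                sample=sample_code_from_id(h.query_id),
                ref_id=h.subject_id,
                ref_family=family,
                ref_lineage=lineage,
                aln_length=h.aln_length,
                evalue=h.evalue,
                pct_identity=h.pct_identity,
            )
        )
    return out


def filter_ssu_hits(
    hits: Iterable[SsuHit],
    min_len: int = DEFAULT_MIN_LEN,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> list[SsuHit]:
    """Drop short or weak alignments; both thresholds are inclusive.

    Alignments under ``min_len`` bp or with e-value above ``max_evalue``
    often match several distantly related species and carry no reliable
    taxonomic signal.  Order is preserved and filtering is idempotent.
    """
    return [h for h in hits if h.aln_length >= min_len and h.evalue <= max_evalue]


def assign_scaffold_taxon(hits: Sequence[SsuHit]) -> SsuHit | None:
    """Pick the assignment hit for one scaffold: lowest e-value wins.

    Ties are broken by the larger identity x length product, then by
    reference id, so the choice is deterministic under input permutation.
    Returns ``None`` for an empty hit set (scaffold unclassified).
    """
    if not hits:
        return None
    return min(hits, key=lambda h: (h.evalue, -(h.pct_identity * h.aln_length), h.ref_id))


def assign_scaffolds(hits: Iterable[SsuHit]) -> dict[str, SsuHit]:
    """Group filtered hits by scaffold and assign each its best reference."""
    by_scaffold: dict[str, list[SsuHit]] = {}
    for h in hits:
        by_scaffold.setdefault(h.scaffold_id, []).append(h)
    return {sid: assign_scaffold_taxon(hs) for sid, hs in by_scaffold.items()}


def is_plant_lineage(lineage: str, plant_clades: frozenset[str] = DEFAULT_PLANT_CLADES) -> bool:
    tokens = {t.strip().casefold() for t in lineage.split(";")}
    return bool(tokens & plant_clades)


def validate_sample(
    sample: SampleMeta,
    assignments: Sequence[SsuHit],
    plant_clades: frozenset[str] = DEFAULT_PLANT_CLADES,
) -> SampleValidation:
    """Judge one sample from its scaffold-level SSU assignments.

    ``validated``: some scaffold is assigned to the expected family.
    ``worrisome``: some scaffold is assigned to a *plant* family different
    from the expected one (non-plant assignments are reported but never set
    the flag).  Zero surviving assignments give neither flag.
    """
    expected = sample.family.strip().casefold()
    fam_counts: dict[str, int] = {}
    validated = False
    worrisome = False
    for h in assignments:
        fam_counts[h.ref_family] = fam_counts.get(h.ref_family, 0) + 1
        if h.ref_family.strip().casefold() == expected:
            validated = True
        elif is_plant_lineage(h.ref_lineage, plant_clades):
            worrisome = True
    families = sorted(fam_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return SampleValidation(
        sample=sample.code,
        validated=validated,
        worrisome=worrisome,
        assigned_families=families,
        n_ssu_scaffolds=len(assignments),
    )


def validate_all(
    samples: dict[str, SampleMeta],
    assignments: dict[str, SsuHit],
    plant_clades: frozenset[str] = DEFAULT_PLANT_CLADES,
) -> list[SampleValidation]:
    """Validate every sample from the pooled scaffold assignments."""
    by_sample: dict[str, list[SsuHit]] = {code: [] for code in samples}
    for h in assignments.values():
        if h is None or h.sample not in by_sample:
            continue
        by_sample[h.sample].append(h)
    return [
        validate_sample(samples[code], by_sample[code], plant_clades)
        for code in sorted(samples)
    ]


def write_validation_reports(
    validations: Sequence[SampleValidation],
    assignments: dict[str, SsuHit],
    sample_path: str | Path,
    scaffold_path: str | Path,
) -> None:
    """Write the two accessory SSU reports.

    File 1 (per sample): validated / worrisome flags and assigned families.
    File 2 (per scaffold): each 18S-like scaffold and the reference it
    matched, with the filter-relevant alignment statistics.
    """
    with open(sample_path, "w") as fh:
        fh.write("code\tvalidated\tworrisome\tn_ssu_scaffolds\tassigned_families\n")
        for v in validations:
            fams = ",".join(f"{fam}:{n}" for fam, n in v.assigned_families)
            fh.write(
                f"{v.sample}\t{str(v.validated).lower()}\t{str(v.worrisome).lower()}\t"
                f"{v.n_ssu_scaffolds}\t{fams}\n"
            )
    with open(scaffold_path, "w") as fh:
        fh.write("scaffold_id\tref_id\tref_family\tevalue\taln_length\n")
        for sid in sorted(assignments):
            h = assignments[sid]
            if h is None:
                continue
            fh.write(f"{h.scaffold_id}\t{h.ref_id}\t{h.ref_family}\t{h.evalue:g}\t{h.aln_length}\n")
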