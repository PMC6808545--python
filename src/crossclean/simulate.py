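"""Synthetic contaminated-library generator with exact ground truth.

Emulates the generative situation the contamination screen targets: a set of
transcriptome libraries from diverged species whose matched sequences peak
at the species' pairwise identity, with one library carrying a spike of
near-identical copies from a donor library.  Divergence is substitution-only
(no indels), so the percent identity of every emitted hit row is the exact
position-wise identity of the two sequences and no real aligner is needed;
e-values and bitscores in emitted rows are synthetic monotone functions of
identity x length and only their ordering is meaningful.

The default scenario mirrors a classic cross-contamination case: one
heavily contaminated recipient (*Deutzia scabra* OTAN, spiked from *Gunnera
manicata* XMQO) among otherwise clean libraries, with the donor accompanied
by a same-family relative so the donor/recipient re-search rule has the
taxonomic context it relies on.

Everything is driven by one seeded generator: identical configuration
(including seed) gives byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .formats import (
    AlnHit,
    SampleMeta,
    TranscriptSeq,
    write_fasta,
    write_sample_table,
    write_tabular_hits,
)
from .pairs import PairKey

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: (code, species, family) for the default scenario, in order:
#: donor, recipient, donor's same-family companion.
DEFAULT_TAXA = (
    ("XMQO", "Gunnera manicata", "Gunneraceae"),
    ("OTAN", "Deutzia scabra", "Hydrangeaceae"),
    ("GUNT", "Gunnera tinctoria", "Gunneraceae"),
)

_PLANT_LINEAGE = "Eukaryota;Archaeplastida;Viridiplantae;Streptophyta;Embryophyta"
#: A plant family foreign to every default sample, used for worrisome spikes.
FOREIGN_SSU_FAMILY = "Poaceae"


@dataclass
class SimConfig:
    """Parameters of one simulated scenario.

    ``divergence_identity`` is the expected pairwise percent identity between
    orthologs of any two libraries; ``contamination_fraction`` the proportion
    of the donor's transcripts copied into the recipient; ``noise_rate`` the
    per-base substitution probability applied to each contaminant copy
    (sample-handling damage, sequencing/assembly error).
    """

    n_libraries: int = 3
    n_transcripts: int = 2000
    length_range: tuple[int, int] = (300, 3000)
    divergence_identity: float = 85.0
    contamination_fraction: float = 0.05
    noise_rate: float = 0.005
    seed: int = 0
    donor: str = "XMQO"
    recipient: str = "OTAN"
    taxa: tuple[tuple[str, str, str], ...] = DEFAULT_TAXA
    tree: str | None = None
    worrisome_samples: tuple[str, ...] = ()
    ssu_fail_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.contamination_fraction < 1:
            raise ValueError("contamination_fraction must be in (0, 1)")
        if not 0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must be in [0, 0.5)")
        if not 50 < self.divergence_identity < 100:
            raise ValueError("divergence_identity must be in (50, 100)")
        if self.n_libraries != len(self.taxa):
            self.taxa = _extend_taxa(self.taxa, self.n_libraries)
        codes = [t[0] for t in self.taxa]
        if self.donor not in codes or self.recipient not in codes:
            raise ValueError("donor and recipient must be among the configured taxa")

    @property
    def codes(self) -> list[str]:
        return [t[0] for t in self.taxa]

    def newick(self) -> str:
        """Default topology: donor and companion are sisters, extras ladder on."""
        if self.tree is not None:
            return self.tree
        codes = self.codes
        donor, recipient = self.donor, self.recipient
        companion = next(
            (c for c, _, fam in self.taxa
             if c != donor and fam == dict((t[0], t[2]) for t in self.taxa)[donor]),
            None,
        )
        core = [c for c in codes if c not in {donor, recipient, companion}]
        clause = f"({donor},{companion})" if companion else donor
        tree = f"({clause},{recipient})"
        for extra in core:
            tree = f"({tree},{extra})"
        return tree + ";"


def _extend_taxa(taxa, n: int):
    """Pad the taxon list with clean, distantly related extra libraries."""
    taxa = list(taxa)
    i = 0
    while len(taxa) < n:
        code = f"Q{chr(ord('A') + i // 26)}{chr(ord('A') + i % 26)}A"
        taxa.append((code, f"Extraspecies {code.lower()}", f"Extrafamily{i}"))
        i += 1
    return tuple(taxa[:n])


@dataclass
class TruthLabel:
    seq_id: str
    is_contaminant: bool
    donor_sample: str | None = None
    ortholog_of: str | None = None


@dataclass
class SimResult:
    """Everything one scenario produces, in memory."""

    config: SimConfig
    samples: dict[str, SampleMeta]
    tree_newick: str
    libraries: dict[str, list[TranscriptSeq]]
    truth: dict[str, TruthLabel]
    pair_hits: dict[PairKey, list[AlnHit]]
    research_hits: list[AlnHit]
    ssu_hits: list[AlnHit]
    ssu_lineages: dict[str, tuple[str, str]]


# ---------------------------------------------------------------------------
# sequence-level primitives


def _random_bases(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate``, uniformly over the
    three alternative bases (every substitution changes the base)."""
    out = arr.copy()
    if rate <= 0:
        return out
    mask = rng.random(arr.shape[0]) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return out


def _to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def _from_str(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    arr = lut[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    return arr


def pct_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Exact position-wise percent identity of two equal-length sequences."""
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length (substitution-only model)")
    return float((a == b).mean() * 100.0)


def _branch_rate(divergence_identity: float) -> float:
    """Per-branch substitution rate from a shared ancestor such that two
    independently derived copies match at ``divergence_identity`` percent.

    Sites match when neither branch substitutes, or both substitute to the
    same alternative: p = (1-r)^2 + r^2/3; solved for r.
    """
    p = divergence_identity / 100.0
    disc = 4.0 - (16.0 / 3.0) * (1.0 - p)
    return (2.0 - math.sqrt(disc)) / (8.0 / 3.0)


def generate_library(code: str, cfg: SimConfig, rng: np.random.Generator) -> list[TranscriptSeq]:
    """Generate one library of uniform-random transcripts (no divergence
    structure); ids follow the ``CODE_serial_species`` grammar."""
    species = dict((t[0], t[1]) for t in cfg.taxa).get(code, f"Species {code.lower()}")
    lo, hi = cfg.length_range
    records = []
    for i in range(cfg.n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        arr = _random_bases(rng, length)
        records.append(
            TranscriptSeq(seq_id=_seq_id(code, i + 1, species), sequence=_to_str(arr))
        )
    return records


def make_ortholog(
    seq: TranscriptSeq, target_identity: float, rng: np.random.Generator
) -> TranscriptSeq:
    """Derive a diverged ortholog by independent per-site substitution.

    Substitutions occur at rate ``(100 - target_identity) / 100`` and always
    change the base, so the realized identity is Binomial(L, target/100)/L —
    computable exactly by position-wise comparison, no alignment needed.
    """
    if not 50 < target_identity <= 100:
        raise ValueError("target_identity must be in (50, 100]")
    rate = (100.0 - target_identity) / 100.0
    arr = _mutate(_from_str(seq.sequence), rate, rng)
    return TranscriptSeq(seq_id=seq.seq_id, sequence=_to_str(arr), sample_code=seq.sample_code)


def _seq_id(code: str, serial: int, species: str) -> str:
    return f"{code}_{serial}_{species.replace(' ', '-')}"


def _fake_scores(identity: float, length: int) -> tuple[float, float]:
    """Synthetic (evalue, bitscore): monotone in identity x length only."""
    score = identity / 100.0 * length
    bitscore = round(score * 2.0, 1)
    evalue = 10.0 ** (-min(180.0, score / 10.0))
    return evalue, bitscore


def _hit_row(qid: str, sid: str, identity: float, length: int) -> AlnHit:
    mism = int(round(length * (100.0 - identity) / 100.0))
    evalue, bitscore = _fake_scores(identity, length)
    return AlnHit(
        query_id=qid,
        subject_id=sid,
        pct_identity=round(identity, 2),
        aln_length=length,
        mismatches=mism,
        gap_opens=0,
        q_start=1,
        q_end=length,
        s_start=1,
        s_end=length,
        evalue=evalue,
        bitscore=bitscore,
    )


# ---------------------------------------------------------------------------
# scenario assembly


def simulate(cfg: SimConfig) -> SimResult:
    """Run the full generative scenario for one configuration."""
    rng = np.random.default_rng(cfg.seed)
    codes = cfg.codes
    species_of = {c: s for c, s, _ in cfg.taxa}
    samples = {
        c: SampleMeta(code=c, species=s, family=f, clade="Embryophyta") for c, s, f in cfg.taxa
    }

    # Shared ancestors; every library is an independently mutated copy, so
    # each pair of libraries diverges at ~divergence_identity percent.
    lo, hi = cfg.length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_transcripts)
    ancestors = [_random_bases(rng, int(L)) for L in lengths]
    rate = _branch_rate(cfg.divergence_identity)

    arrays: dict[str, list[np.ndarray]] = {}
    libraries: dict[str, list[TranscriptSeq]] = {}
    for code in codes:
        arrs = [_mutate(a, rate, rng) for a in ancestors]
        arrays[code] = arrs
        libraries[code] = [
            TranscriptSeq(_seq_id(code, i + 1, species_of[code]), _to_str(a))
            for i, a in enumerate(arrs)
        ]

    # One directed contamination event: donor -> recipient.
    k = math.ceil(cfg.contamination_fraction * cfg.n_transcripts)
    spike_idx = np.sort(rng.choice(cfg.n_transcripts, size=k, replace=False))
    truth: dict[str, TruthLabel] = {}
    spike_records: list[tuple[int, TranscriptSeq, np.ndarray]] = []
    for j, i in enumerate(spike_idx):
        i = int(i)
        copy = _mutate(arrays[cfg.donor][i], cfg.noise_rate, rng)
        sid = _seq_id(cfg.recipient, cfg.n_transcripts + j + 1, species_of[cfg.recipient])
        rec = TranscriptSeq(sid, _to_str(copy))
        libraries[cfg.recipient].append(rec)
        spike_records.append((i, rec, copy))
        truth[sid] = TruthLabel(
            sid,
            is_contaminant=True,
            donor_sample=cfg.donor,
            ortholog_of=libraries[cfg.donor][i].seq_id,
        )
    for code in codes:
        for rec in libraries[code]:
            truth.setdefault(rec.seq_id, TruthLabel(rec.seq_id, is_contaminant=False))

    pair_hits = _emit_pair_tables(cfg, libraries, arrays, spike_records)
    research_hits = _emit_research_table(cfg, libraries, arrays, spike_records)
    ssu_hits, ssu_lineages = emit_ssu_fixtures(cfg, samples)

    return SimResult(
        config=cfg,
        samples=samples,
        tree_newick=cfg.newick(),
        libraries=libraries,
        truth=truth,
        pair_hits=pair_hits,
        research_hits=research_hits,
        ssu_hits=ssu_hits,
        ssu_lineages=ssu_lineages,
    )


def _emit_pair_tables(cfg, libraries, arrays, spike_records) -> dict[PairKey, list[AlnHit]]:
    """One hit row per related sequence pair, query on the canonical-a side.

    Each unordered library pair gets one row per ortholog pair; the
    donor-recipient pair additionally gets one row per spiked copy against
    its donor original, and other pairs involving the recipient get the
    spiked copies' background rows against that library's orthologs.
    """
    codes = cfg.codes
    tables: dict[PairKey, list[AlnHit]] = {}
    for ai in range(len(codes)):
        for bi in range(ai + 1, len(codes)):
            pair = PairKey(codes[ai], codes[bi])
            x, y = pair.a, pair.b
            rows = []
            for i in range(cfg.n_transcripts):
                ident = pct_identity(arrays[x][i], arrays[y][i])
                rows.append(
                    _hit_row(
                        libraries[x][i].seq_id,
                        libraries[y][i].seq_id,
                        ident,
                        arrays[x][i].shape[0],
                    )
                )
            if cfg.recipient in (x, y):
                other = pair.other(cfg.recipient)
                for i, rec, copy in spike_records:
                    if other == cfg.donor:
                        partner_id = libraries[cfg.donor][i].seq_id
                        ident = pct_identity(copy, arrays[cfg.donor][i])
                    else:
                        partner_id = libraries[other][i].seq_id
                        ident = pct_identity(copy, arrays[other][i])
                    qid, sid = (rec.seq_id, partner_id) if x == cfg.recipient else (partner_id, rec.seq_id)
                    rows.append(_hit_row(qid, sid, ident, copy.shape[0]))
            tables[pair] = rows
    return tables


def _emit_research_table(cfg, libraries, arrays, spike_records) -> list[AlnHit]:
    """Hits of every sequence against every related sequence in the other
    libraries — the input to the donor/recipient re-search step."""
    codes = cfg.codes
    rows: list[AlnHit] = []
    # ortholog relations, both directions
    for x in codes:
        for y in codes:
            if x == y:
                continue
            for i in range(cfg.n_transcripts):
                ident = pct_identity(arrays[x][i], arrays[y][i])
                rows.append(
                    _hit_row(libraries[x][i].seq_id, libraries[y][i].seq_id, ident, arrays[x][i].shape[0])
                )
    # spike relations, both directions
    for i, rec, copy in spike_records:
        for other in codes:
            if other == cfg.recipient:
                continue
            ident = pct_identity(copy, arrays[other][i])
            other_id = libraries[other][i].seq_id
            rows.append(_hit_row(rec.seq_id, other_id, ident, copy.shape[0]))
            rows.append(_hit_row(other_id, rec.seq_id, ident, copy.shape[0]))
    return rows


def emit_ssu_fixtures(
    cfg: SimConfig, samples: dict[str, SampleMeta]
) -> tuple[list[AlnHit], dict[str, tuple[str, str]]]:
    """Construct the 18S search table and reference-lineage annotations.

    Every sample (unless listed in ``ssu_fail_samples``) gets one strong
    18S-like scaffold hit to a reference of its own family; samples in
    ``worrisome_samples`` get an additional hit to a foreign plant family.
    """
    families = sorted({s.family for s in samples.values()} | {FOREIGN_SSU_FAMILY})
    lineages = {f"REF_{fam}": (fam, f"{_PLANT_LINEAGE};{fam}") for fam in families}
    hits: list[AlnHit] = []
    for code in sorted(samples):
        if code in cfg.ssu_fail_samples:
            continue
        fam = samples[code].family
        hits.append(_hit_row(f"{code}_9001_18S", f"REF_{fam}", 99.3, 1750))
        if code in cfg.worrisome_samples:
            hits.append(_hit_row(f"{code}_9002_18S", f"REF_{FOREIGN_SSU_FAMILY}", 98.1, 1600))
    return hits, lineages


# ---------------------------------------------------------------------------
# on-disk layout


def write_scenario(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write every simulated input the pipeline consumes.

    Layout: ``fasta/<CODE>.fasta``, ``hits/<A>__<B>.tsv``,
    ``research_hits.tsv``, ``ssu_hits.tsv`` + ``ssu_lineage.tsv``,
    ``sample_table.tsv``, ``tree.nwk`` and ``truth.tsv``.
    """
    outdir = Path(outdir)
    (outdir / "fasta").mkdir(parents=True, exist_ok=True)
    (outdir / "hits").mkdir(exist_ok=True)
    paths: dict[str, Path] = {}
    for code, records in result.libraries.items():
        p = outdir / "fasta" / f"{code}.fasta"
        write_fasta(records, p)
        paths[f"fasta:{code}"] = p
    write_sample_table(result.samples, outdir / "sample_table.tsv")
    paths["sample_table"] = outdir / "sample_table.tsv"
    (outdir / "tree.nwk").write_text(result.tree_newick + "\n")
    paths["tree"] = outdir / "tree.nwk"
    for pair, rows in result.pair_hits.items():
        p = outdir / "hits" / f"{pair.a}__{pair.b}.tsv"
        write_tabular_hits(rows, p)
        paths[f"hits:{pair.a}__{pair.b}"] = p
    write_tabular_hits(result.research_hits, outdir / "research_hits.tsv")
    paths["research_hits"] = outdir / "research_hits.tsv"
    write_tabular_hits(result.ssu_hits, outdir / "ssu_hits.tsv")
    paths["ssu_hits"] = outdir / "ssu_hits.tsv"
    with open(outdir / "ssu_lineage.tsv", "w") as fh:
        fh.write("ref_id\tfamily\tlineage\n")
        for ref_id in sorted(result.ssu_lineages):
            fam, lin = result.ssu_lineages[ref_id]
            fh.write(f"{ref_id}\t{fam}\t{lin}\n")
    paths["ssu_lineage"] = outdir / "ssu_lineage.tsv"
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("seq_id\tis_contaminant\tdonor\n")
        for sid in sorted(result.truth):
            t = result.truth[sid]
            fh.write(f"{sid}\t{str(t.is_contaminant).lower()}\t{t.donor_sample or ''}\n")
    paths["truth"] = outdir / "truth.tsv"
    return paths
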