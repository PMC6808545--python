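# crossclean

Cross-contamination detection and sample validation for *de novo*
transcriptome assemblies.

Large multi-species RNA-seq projects assemble hundreds of libraries side by
side, and some fraction of sequences inevitably ends up in the wrong
library — RNA carried over between adjacent samples, index mis-assignment,
or shared commensal organisms. For whole-transcriptome analyses a few such
sequences are noise; for single-gene-family phylogenetics one contaminant
sequence is a wrong species placement. `crossclean` is for groups producing
or reusing multi-library assembly sets who need per-sequence contamination
verdicts, per-sample identity checks, and completeness summaries, without
re-running the original sequencing project.

## The method

**Pairwise identity thresholding.** For each eligible pair of libraries
(i, j), every sequence's best cross-library match is binned by percent
identity. The resulting curve n(s) has a single mode at the identity level
set by how far the two species have diverged; a
cross-contaminated pair shows a second mode near s = 100, because a
contaminant is an almost exact copy of its donor. Scanning n(s) downward
from 100%, the cutoff s\* is the first local minimum — the first bin with
n(s) ≤ n(s + 1) and n(s) < n(s − 1) — provided the near-100% region holds at
least `min_peak_support` matches. All matches with s ≥ s\* are contamination
candidates in one or both libraries.

**Taxonomic pair exclusion.** Libraries from the same family, or separated
by ≤ 2 edges on the consensus phylogeny, legitimately share near-identical
sequences and are never compared.

**Donor/recipient resolution.** Each candidate is re-searched against all
other libraries and its top 3 hits inspected: ≥ 1 hit from the candidate's
own family (or a taxon closer than `close_branches` edges) rescues it as a
close-taxon match; hits exclusively from distant taxa verify it as a
contaminant, with the best hit's library as donor; no evidence leaves it
unresolved-possible. Only verified contaminants are removed when each
library is split into clean and contaminant FASTA files.

**Sample validation (18S/SSU).** Assemblies are searched against a
lineage-annotated SSU rRNA reference set; alignments under 300 bp or with
e-value above 1e−9 are ignored. The lowest-e-value surviving hit assigns
each 18S-like scaffold a taxonomic origin. A sample is *validated* when a
scaffold matches its expected family and *worrisome* when any scaffold
matches a different plant family.

**Completeness.** CEG abundance = 100 × (CEGs with a reciprocal-best hit) /
248; BUSCO abundance = 100 − missing%. Both are summarized as percentile
tables, with a configurable inclusion floor (default: exclude < 57.5% BUSCO
abundance).

A seeded simulator (`crossclean simulate`) generates multi-library scenarios
with substitution-only divergence, a directed contamination spike, SSU
fixtures, and exact truth labels, so the entire pipeline runs and is tested
at desk scale with no external data.

## Worked example

Simulate the default scenario at reduced size — three libraries of 300
transcripts at 85% pairwise ortholog identity, with 5% of *Gunnera
manicata* (XMQO) spiked into *Deutzia scabra* (OTAN) — and run the full
screen:

```sh
crossclean simulate --seed 3 --transcripts 300 --out scen
crossclean run-all --config run.cfg     # points at the files under scen/
cat out/thresholds.tsv
```

```
code_a  code_b  status   cutoff  n_matches  peak_support
GUNT    OTAN    no_peak          300        0
OTAN    XMQO    found    91      315        15
```

The clean pair GUNT–OTAN has no near-100% peak (no cutoff, nothing
flagged); the spiked pair thresholds at 91% identity, between the 85%
ortholog mode and the ~99.5% contamination peak, with 15 matches above it.
The XMQO–GUNT pair is absent: both are Gunneraceae, so it was excluded
(`out/excluded_pairs.tsv`). The summary resolves direction:

```
code  n_total  n_contaminant  n_clean  n_possible  n_contaminant_in_others
GUNT  300      0              300      0           0
OTAN  315      15             300      0           0
XMQO  300      0              300      0           15
```

All 15 spiked copies are verified as contaminants *in OTAN* with XMQO as
donor (the contamination matrix shows OTAN row, XMQO column = 15), while
the 15 donor originals in XMQO are rescued by their same-family companion
GUNT and stay clean — they are counted only as contaminants-in-others.
`out/split/OTAN.contam.fasta` holds exactly the 15 verified sequences.

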