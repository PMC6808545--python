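# Methods

## Detection model

The screen treats contamination as a two-mode mixture in the distribution
of best-match percent identities between two libraries. Orthologous
sequences of two species diverge by substitution and loss, so their
identity distribution has one mode at the pairwise identity set by the
species' evolutionary distance. A contaminant, by contrast, is a copy of a
sequence from another extraction — transferred RNA, a mis-assigned index
read, or a shared commensal — and differs from its source only by handling
damage, sequencing error, and assembly error, so it matches that source at
near-100% identity. When enough contaminants are present, the identity
histogram is bimodal and the valley between the modes is an operational
decision boundary.

The boundary is found by direct scan, not model fitting: after optional
moving-average smoothing, bins are walked downward from 100% and the
cutoff is the lower edge of the first bin whose count is less than or
equal to the bin above and strictly less than the bin below. Reasons for
preferring the scan over a mixture fit: it is assumption-free about the
shape of either mode, exactly reproducible, and cheap enough for an
all-vs-all pass over hundreds of libraries. The cost is that the scan is
only meaningful when a near-100% peak exists, so it is gated: if the bins
overlapping (99, 100] hold fewer than `min_peak_support` matches the pair
is reported `no_peak` and nothing is flagged. If the counts never rise
again below the peak (a unimodal near-100 pile, as for an unexcluded
conspecific pair) the pair is `degenerate` and likewise yields no cutoff —
flagging everything would be the only consistent alternative and is never
what the user wants.

Matches are per-query best hits, one per sequence in each direction, not
all alignments: the quantity of interest is how many *sequences* sit at
each identity, and multiple local alignments of one sequence pair would
multiply-count it. Ties in best-hit selection are broken by bitscore, then
e-value, then identity, then subject identifier, making the selection
invariant under permutation of the input rows.

## Taxonomic exclusion and the two branch-distance parameters

Closely related species legitimately share near-identical sequences, so
pairs from the same family, or separated by `max_branches` (default 2) or
fewer edges on the consensus phylogeny, are excluded from the pairwise
comparisons. Distance is the edge count on the leaf-to-leaf path of the
tree as written; two sister leaves are 2 apart, so the default excludes the
closest relatives. Family comparison is string equality after case-folding
and whitespace trimming — synonym resolution is deliberately out of scope;
the sample table is the authority.

The re-search step has its own parameter, `close_branches` (default 2,
strict comparison: a hit rescues only when its distance is *less than*
`close_branches`). The two defaults are intentionally independent rather
than harmonized: the pairwise exclusion is inclusive (≤ 2) while the
re-search rescue is strict (< 2). Under the leaf-to-leaf edge-count metric
no two distinct leaves are closer than 2, so at the default the re-search
rescue acts entirely through the same-family rule; users who want
tree-based rescue can raise `close_branches`. Both parameters are surfaced
in the CLI and `RunConfig`.

## Donor/recipient resolution

Both members of a near-100% match are candidates — the histogram cannot
tell which library the sequence belongs to. Direction comes from context:
each candidate is re-searched against the assemblies of all *other*
libraries (its own library is removed; the partner library remains
searchable, which is what lets the best hit name the true donor), and the
top `n_top` = 3 hits are read as evidence. A genuine sequence finds its own
relatives, so one same-family (or sub-`close_branches`) hit in the top 3
rescues it (`excluded_close_taxon`). Top hits exclusively from distant taxa
verify the candidate as a contaminant, with the best hit's library recorded
as donor (ties broken by identity, then lexicographic library code). A
candidate with no re-search evidence at all stays `unresolved_possible`:
verification requires positive distant-hit evidence, never its absence.

This resolution only works when a contaminant's donor has a close relative
somewhere in the library set; with no relatives, donor and recipient are
symmetric and the method cannot orient the pair. That is a property of the
method, not of this implementation, and it is why the simulator's default
taxonomy gives the donor a same-family companion library (see below).

Only `verified_contaminant` sequences are removed when a library is split
into clean and contaminant FASTA files; rescued and unresolved sequences
remain in the clean file and are accounted in the summary, where the
three-way count `n_contaminant + n_clean + n_possible = n_total` treats
rescued sequences as clean. A sequence flagged in several pairs is
classified once, keeping the highest-identity occurrence.

## SSU validation

Thresholds are inclusive — alignments of ≥ 300 bp with e-value ≤ 1e−9
survive — because the filter is defined by what is *ignored* (alignments
under 300 bp, e-values greater than 1e−9), so boundary values are kept.
Scaffold assignment is by minimal e-value, with ties broken by the
identity × length product and then reference id. Reference families come
from a curated three-column lineage table (`ref_id`, `family`, `lineage`)
rather than parsed reference descriptions, whose formats vary by database
release. Plant membership is decided by intersecting the semicolon-split
lineage with a clade list (default: Viridiplantae, Chlorophyta,
Streptophyta, Embryophyta); non-plant assignments are reported but never
set the worrisome flag, which concerns other *plant* families only. A
sample whose expected-family scaffolds coexist with one foreign plant
scaffold is both validated and worrisome — the two flags are independent
observations, not a single verdict.

## Completeness summaries

CEG abundance is 100 × hits/248 and BUSCO abundance is 100 − missing%;
both are exact formulas over externally produced report tables (running
CRB-BLAST or BUSCO is out of scope). Percentiles (default 5/25/50/75/95)
use linear interpolation between closest ranks; the convention is stated
here because percentile tables are commonly compared across tools that
disagree on it. BUSCO results are tabulated both as complete+fragment
abundance and as complete-only, matching the usual dual presentation. The
inclusion floor is a strict comparison: abundance exactly at the floor
(57.5% by default) is retained.

## Simulator

The generator emulates the situation the screen targets, with every
quantity exact by construction:

* Each library derives from shared ancestor transcripts by independent
  per-site substitution at a per-branch rate r solving
  (1 − r)² + r²/3 = d/100, so every library pair meets at the configured
  pairwise identity d (default 85%). Substitutions always change the base,
  drawn uniformly from the three alternatives.
* Divergence is substitution-only — no indels — so percent identity is a
  position-wise count and the emitted hit tables need no aligner. E-values
  and bitscores are synthetic monotone functions of identity × length;
  only their ordering carries meaning.
* One directed spike copies ⌈fraction × n⌉ donor transcripts into the
  recipient at `noise_rate` per-base noise (default 0.5%), re-identified
  under the recipient's code, with truth labels recording donor and source.
* Defaults (3 libraries × 2,000 transcripts of 300–3,000 bp, 85%
  divergence, 5% spike, 0.5% noise) are the study conditions used
  throughout the tests and the acceptance script. With divergence ≤ 90%
  and noise ≤ 1% the two identity modes are separated by several binomial
  standard deviations at every transcript length, so the scanned valley
  exists with overwhelming probability.
* The default taxonomy mirrors a classic contamination case — *Gunnera
  manicata* (XMQO) contaminating *Deutzia scabra* (OTAN) — and includes a
  same-family companion for the donor (*Gunnera tinctoria*, GUNT). The
  companion pair XMQO–GUNT is excluded from pairwise comparison by the
  family rule, exactly as close pairs are in real runs, while giving the
  re-search the close relative it needs to rescue donor originals. SSU
  fixtures give every sample a strong same-family 18S hit, with optional
  foreign-plant spikes and assembly-failure samples.

What the simulator does *not* model, and hence what passing tests do not
show about real data: indels and alignment ambiguity (real identity values
are alignment-dependent), chimeric or fragmented assembly, expression
variation (every transcript is present exactly once), more than one
contamination event per scenario by default, bacterial/fungal contaminants
without orthologs in any library, and real SSU reference heterogeneity.
The acceptance numbers are therefore statements about the method's
correctness under its own model, not field performance estimates.

## Numerical and degenerate-input choices

* Histogram bins are half-open [edge, edge + width) with identity 100
  assigned to the top bin; the scanner also accepts externally built
  histograms keyed with a 100 bin. Bin width must divide 100 evenly
  (default 1 point, matching per-percentage-value counting).
* Smoothing is off by default (window 1); a short odd-width moving average
  is available for small noisy pairs. The scan runs on smoothed counts but
  the peak-support gate uses raw counts.
* Matches exactly at the cutoff are flagged (≥, not >) — conservative
  toward detection; invert by nudging the cutoff if needed.
* Empty inputs: an empty hit table yields an empty match set, an empty
  histogram is `no_peak`, a library with no candidates is all-clean, and
  an empty SSU table yields header-only reports.
* A library code absent from the tree skips the tree criterion (family
  rule still applies) with a warning; a re-search hit whose subject id has
  no parseable 4-letter code is skipped with a warning.
* Sequence identifiers are `CODE_serial_description` with `_` or `-`
  accepted after the 4-letter code; the separator convention is an
  assumption of the naming grammar, not a guarantee of the format.

## Problem sizes

Tests and the acceptance script run the default scenario (3 × 2,000
transcripts) over ten seeded replicates, 1,000 random histograms for the
oracle comparison, and 1,000 trials of 10 kb orthologs for the divergence
statistics — sizes chosen so the full suite completes in well under a
minute per component on one CPU while keeping every statistical check
several standard deviations away from its pass boundary.

## Known limitations

* Donor assignment names the library of the best re-search hit; when the
  true donor is absent from the input set the named donor is merely the
  closest available relative.
* The first-local-minimum scan can sit one bin early when sparse noise
  creates a micro-valley above the true one; the `min_peak_support` gate
  suppresses the single-hit case but not all of them. Smoothing helps and
  slightly moves the cutoff; an inflection criterion on smoothed data
  would differ from the local-minimum criterion and is not implemented.
* Unresolved-possible counts depend on re-search coverage: sequences with
  no hits anywhere stay possible forever and are never subtracted from the
  clean file.
* The SSU check validates at family rank only; congeneric mislabels are
  invisible to it.
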