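# Methods

This note documents the models, algorithms and design choices behind
`treclineage`, in the order the pipeline runs.

## 1. Synthetic cohort model

### Germline reference

Synthetic V segments are random nucleotide sequences of 48–63 nt ending in a
TGT/TGC codon — the conserved 2nd-CYS junction anchor, placed as the last
codon of the segment so the sequenced V portion always contains it. Synthetic
J segments carry the conserved J-PHE "FGXG" motif (TTY GGN NNN GGN) at a fixed
anchor offset (default 18 nt), followed by a 12–18 nt tail. With this
geometry the minimal junction (zero N-insertion) is 24 nt, long enough that
accidental junction collisions between independently drawn clonotypes are
negligible; any collisions that do occur are detected against a global key
set, redrawn, and reported in the table metadata (`junction_collisions`).

The reference always contains segments named TRBV12-4 and TRBJ1-2 so that the
V-J-restricted overlap statistic works on synthetic data without
configuration. The constant-region primers are the two second-round 5′RACE
reverse primers of the laboratory protocol (TCRα `CAGGGTCAGGGTTCTGGAT`, TCRβ
`CACAGCGACCTCGGGTGGGAA`); the universal 5′ adapter is the SMART template-
switch primer sequence.

### Clone pools and planted sharing

A `SharingModel` describes a cohort: `patients` independent patients, each
with nine compartments (PB/LN/TI × naive/memory/Treg). Per compartment, a
pool of `clone_pool_size` clonotypes (default 1000) is built in two steps:

1. **Copies.** For every sharing edge (source → target) with fraction θ,
   ⌊θ · pool_size⌋ clonotypes are copied (without replacement) from the
   source compartment's pool, with their provenance recorded per clone.
   Sources are processed before targets (topological order; cyclic sharing
   specifications are rejected), and the total incoming θ per target must not
   exceed 1.
2. **Novel fill.** The remainder are novel clonotypes: a uniformly random V
   and J segment and a junction `V-suffix(Cys…) + N-insert + J-prefix(…Phe)`
   with insert length uniform on 0–12 nt. Frame and stop codons are left to
   chance, so a realistic share of clonotypes is nonproductive.

Clone sizes are i.i.d. draws from a discrete power law P(k) ∝ k^(−α)
truncated at the pool size (α = `powerlaw_alpha`, default 2.5 — a standard
repertoire clone-size assumption; the paperwork of the statistics consumes
only junction identity and counts, so no attempt is made at recombination
realism such as D segments). Sizes are then rescaled to sum exactly to
`cells_per_compartment` (default 5 × 10⁴, the order of cell input per sample
in comparable experiments), keeping every clone ≥ 1 cell; this mirrors
sequencing equal cell numbers per sample. The empirical log-log
rank-frequency slope of the resulting pools matches −1/(α−1) (fitted over the
top decile of ranks, where the curve is not flattened by size-1 ties).

**Default sharing edges.** The default model plants exactly the hypothesis
under test: θ = 0.13 from TI-naive and from PB-naive into TI-Treg, θ = 0.01
from PB-Treg, PB-memory and TI-memory into TI-Treg, and nothing else. With no
other edges there are no two-hop sharing paths, so the shared-unique fraction
of any (source, TI-Treg) pair is an unbiased estimator of its θ — the
property the overlap statistics are validated against. Any other structure
can be supplied as a `source->target: theta` map.

### Read emission

Each clonotype emits `round(count × depth_per_clonotype_cell)` reads (default
depth 1.0, i.e. one read per cell). A read is

```
barcode + universal adapter + V segment + junction insert + J segment
        + reverse-complemented constant-region primer site
```

(~160–170 nt with the default geometry), with i.i.d. substitution errors at
`error_rate` per base (default 10⁻³; indels are not modelled, keeping the
V/J-assignment test surface interpretable). Base qualities are constant at
the Phred equivalent of the error rate. Sample barcodes (default 8 nt) are
designed by seeded rejection sampling to pairwise Hamming distance ≥ 3, which
makes 1-mismatch demultiplexing unambiguous. Ground truth (sample and
clonotype of every read) is carried in the FASTQ description line.

Everything is deterministic for a fixed seed: one master `SeedSequence`
spawns per-patient generators, and read emission uses its own seeded
generator.

### What the simulator does *not* emulate

PCR amplification bias and chimeras, UMIs, paired-end structure, indel and
quality-dependent errors, within-cell α/β chain pairing, public/convergent
clonotypes shared across patients, and real germline allele diversity.
Passing tests on synthetic data therefore demonstrate the correctness of the
pipeline's logic and statistics under the stated error model — not that the
default alignment thresholds are optimal for any particular instrument or
protocol.

## 2. Read processing

Stages run per FASTQ, with exact read-count conservation
(`reads_in = assigned + undetermined`, and per sample
`reads = recovered + per-stage filter tallies`):

- **Demultiplex** — a read is assigned to the unique barcode within
  `max_mismatch` (default 1) of its prefix, else routed to "undetermined".
  The precondition `max_mismatch < min pairwise distance / 2` is enforced, so
  assignment is never ambiguous. At per-base error p the expected unassigned
  rate is the binomial tail P(≥ 2 errors in 8 nt).
- **Trim** — the fixed-length universal adapter is stripped; the read is cut
  at the rightmost match of a reverse-complemented constant-region primer
  (≤ 1 substitution). Reads with no detectable primer site are flagged
  `no_c_primer` but retained; reads shorter than adapter + primer are
  filtered `too_short`.
- **V/J assignment** — each germline segment is aligned to the read with a
  *fit* (semi-global) alignment: the segment end to end, read overhangs free.
  Scoring: match +2, mismatch −3, gap open −5, gap extend −2, where a gap of
  length k costs open + (k−1)·extend (Biopython's `PairwiseAligner`
  convention). The top-scoring V and J are called; the call fails
  (`passed=False`) if the top score is below
  `min_score_fraction × match × segment_length` (default 0.6 — tolerant of
  the simulated 0.5–1 % error rates) or ties the runner-up from a different
  gene. Score ties are ordered lexicographically by name so results are
  deterministic. The aligner is validated against an exhaustive Gotoh dynamic
  program in the test suite.
- **Junction extraction** — the CDR3 junction runs from the read position
  aligned to the V anchor codon start through the position aligned to the J
  anchor codon end, both inclusive. If either anchor maps into a gap or
  beyond the read, the read is filtered `anchor_missing`. Productivity =
  in-frame ∧ no stop ∧ starts C ∧ ends F; nonproductive clonotypes are
  retained by default (a `productive_only` flag exists).
- **Counting** — clonotypes are grouped by (v_call, j_call, junction),
  counts summed, and clonotypes below `min_count` (default 1, i.e. no
  abundance filter) dropped. Optional depth normalisation draws a fixed
  number of reads without replacement (multivariate hypergeometric).

Identical read sequences are collapsed before alignment and assignment
results are cached per unique trimmed sequence, so cost scales with sequence
diversity, not depth: an error-free 4.5 × 10⁵-read cohort collapses to ~10⁴
unique sequences and processes in well under a minute on one core.

Reads are assumed sense-strand (5′RACE libraries are oriented); there is no
reverse-complement rescue pass. All internal coordinates are 0-based
half-open; the junction is inclusive of both anchor codons.

## 3. Repertoire statistics

- **Gene usage** — read-weighted frequency of each V (or J) call;
  `order_genes` reorders a profile by a chosen reference profile's descending
  frequency for comparable plots.
- **Morisita-Horn** — computed over the union of clonotype keys (see README
  for the formula), evaluated in its frequency form
  2Σfᵢgᵢ / (Σfᵢ² + Σgᵢ²) with fᵢ = xᵢ/X, gᵢ = yᵢ/Y — algebraically identical
  to the count form but exactly 1.0 for identical count vectors (no last-ulp
  drift from the X·Y products). It is symmetric, scale-invariant, 0 iff no
  key is shared, 1 iff relative frequencies are identical; the implementation
  is checked against a naive double-loop oracle to 10⁻¹².
- **Similarity matrix and clustering** — all-pairs MH over named repertoires
  (labels sorted lexicographically), either at clonotype level (default) or
  on V-gene usage profiles (`level="vgene"`) — both readings of "repertoire
  similarity" are defensible, and the level used is recorded in the output.
  Clustering is agglomerative (average linkage by default; complete/single
  available) on distance 1 − MH, with deterministic tie-breaking via the
  sorted label order; the tree is exported as Newick with branch lengths
  from merge heights.
- **Overlap profile** — for every clonotype of a reference repertoire
  (ordered by its frequency), the relative frequency at which that clonotype
  occurs in each other repertoire.
- **V-J-restricted overlap** — both tables restricted to one rearrangement
  (default TRBV12-4/TRBJ1-2), sharing assessed on junction identity
  (nucleotide by default, amino-acid by flag). Reported are the shared
  unique-junction count, the fractions of each side's unique junctions that
  are shared (the two directions of the statistic), and read-weighted
  variants (summed frequency of shared junctions in each table) — whether a
  published overlap proportion is unique-sequence or read-weighted is often
  ambiguous, so both are always emitted. An empty restriction yields a
  flagged all-zero result rather than an error.
- **Cohort summary** — mean and SEM (sd with n−1 denominator, divided by
  √n) of each overlap direction across patients (n ≥ 2 required); group
  contrasts by two-sided Student's *t* test, Welch (unequal variance) by
  default with a pooled-variance flag. p-values are reported raw — no
  multiple-testing correction is applied, and they are labelled as such.

## 4. Workflow

`run_pipeline` executes simulate → process → stats (real mode: process →
stats on user-supplied FASTQ/FASTA/TSV paths), persisting every intermediate
(reference FASTA, reads FASTQ, barcode TSV, ground-truth and processed AIRR
tables, statistics TSVs, Newick dendrogram) plus a YAML report with per-stage
counts and every headline number; the report contains no timestamps, so
identical configs produce identical reports. Completed stages are appended to
a `MANIFEST`; re-running after a failure skips completed stages and reuses
the persisted stats headline, so a resumed run's report equals a clean
run's. Per-stage seeds are `(seed + stage_index) mod 2³¹` with simulate=1,
process=2, stats=3.

`validate_airr` checks the required AIRR Rearrangement columns, count
positivity, junction alphabet, agreement of `junction_aa` with the standard-
code translation, and consistency of the `productive` flag, returning every
violation rather than the first.

## 5. Numerical and testing choices

- Problem sizes in the test suite are chosen to keep the full run
  inexpensive while leaving the statistics well-powered: the exact
  round-trip test uses 1 patient × 9 compartments × 10³ clones at 5 × 10⁴
  reads/sample; planted-structure recovery uses 100 seeded replicates of
  5-patient cohorts at pool 10³ and 5 × 10⁴ cells; the demultiplexing error
  model is checked on > 10⁴ reads against the binomial tail within 3 SE.
- The power-law slope check fits the top decile of ranks; the planted-θ
  estimator is averaged over replicates and patients (its per-patient
  variance at ~20 restricted junctions per patient is large, as the
  worked example's SEMs show).
- Degenerate inputs have defined behaviour throughout: empty tables are
  valid (flagged) where a filter can empty them, and operations that are
  meaningless on empty input (usage, MH, similarity of < 2 repertoires,
  SEM of n < 2) raise `ValueError`/`InvalidConfiguration`.

## 6. Known limitations

Real-data reproduction of any published clonotype counts is not guaranteed:
the upstream laboratory pipeline (mapper, thresholds, clonotype assembly) is
not specified by the analyses this package reimplements, and deposited
archive data must be fetched and demultiplexed by the user. The alignment
stage handles substitutions well but, with the default scoring, short indels
near the anchors shift the extracted junction rather than being corrected;
there is no UMI-based error correction. The simulator's defaults define a
specific, well-understood test bed — conclusions about other protocols
require re-estimating error rates, barcodes and primer layout in the config.
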