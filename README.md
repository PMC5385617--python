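# treclineage

**TCR-repertoire clonotype lineage analysis** — a tested, reusable pipeline for
asking where a T-cell population comes from by comparing its T-cell-receptor
repertoire with those of candidate source populations.

The motivating question is the origin of regulatory T cells (Tregs) inside
tumors: if tumor-infiltrating (TI) Tregs are converted *in situ* from naive
CD4+ T cells recruited from blood, their TCR clonotypes should overlap those of
naive CD4+ cells far more than those of circulating Tregs or memory cells.
`treclineage` implements the complete desk side of that analysis:

1. **`synthetic`** — a cohort simulator: per patient, nine T-cell compartments
   (peripheral blood / draining lymph node / tumor × naive / memory / Treg),
   each a pool of clonotypes with power-law clone sizes, with *planted*
   cross-compartment clone sharing θ (the lineage ground truth), emitted as
   barcoded 5′RACE-style amplicon reads (FASTQ) with per-base substitution
   errors, plus ground-truth AIRR tables. Every downstream stage is testable
   without any external download.
2. **`processing`** — FASTQ → clonotype tables: barcode demultiplexing,
   universal-adapter and constant-region-primer trimming, V/J germline
   assignment by semi-global alignment, CDR3 junction extraction between the
   conserved V-Cys and J-Phe (FGXG) anchors, and counting of clonotypes keyed
   by (`v_call`, `j_call`, junction nucleotide sequence).
3. **`stats`** — the repertoire statistics: V/J gene usage, Morisita-Horn
   similarity with hierarchical clustering, per-clonotype overlap profiles,
   and V-J-restricted bidirectional shared-clonotype fractions with cohort
   mean ± SEM and Student's *t* tests.
4. **`workflow` / `treclineage` CLI** — one-command reproducible runs with a
   YAML config, per-stage seeds, a resume MANIFEST, and a machine-readable
   report. Real-data mode consumes user-supplied FASTQ (e.g. reads retrieved
   from a sequence archive), a germline FASTA and a barcode TSV; the tool
   never downloads data itself.

## The core statistic

For two repertoires with clonotype counts $x_i$, $y_i$ and totals
$X=\sum_i x_i$, $Y=\sum_i y_i$, the Morisita-Horn similarity is

$$\mathrm{MH} = \frac{2\sum_i x_i y_i}{\left(\sum_i x_i^2/X^2 + \sum_i y_i^2/Y^2\right) X\, Y}$$

— 0 for disjoint repertoires, 1 for identical relative frequencies, invariant
to uniform rescaling of either side, and abundance-weighted: shared clonotypes
count in proportion to their contribution to each repertoire. Repertoires are
clustered by average linkage on the distance $1-\mathrm{MH}$. Lineage sharing
between two populations is quantified as the bidirectional fractions of unique
clonotypes shared within a fixed V-J rearrangement (default TRBV12-4/TRBJ1-2),
which under the simulator's planted model is a direct estimator of θ.

## Worked example

A synthetic five-patient cohort with the default planted lineage model
(θ = 0.13 from tumor-site and blood naive CD4+ pools into TI Tregs, θ = 0.01
from blood Tregs and memory cells):

```bash
treclineage run --out demo --seed 7
```

or equivalently in Python:

```python
import treclineage as tl

cfg = tl.RunConfig(outdir="demo", seed=7, patients=5,
                   clone_pool_size=500, cells_per_compartment=5000,
                   error_rate=0.0)
report = tl.run_pipeline(cfg)
```

With these sizes (225 000 reads, 45 samples) the run takes about half a
minute and the report contains, among other things:

```
ranking: [['PB_naive', 0.0234], ['TI_naive', 0.0138], ['PB_memory', 0.0014]]
TI_naive: mean 0.1095 sem 0.0619 n 5
PB_naive: mean 0.1400 sem 0.0496 n 5
PB_Treg:  mean 0.0000 sem 0.0000 n 5
PB_memory: mean 0.0000 sem 0.0000 n 5
ttest: {'t': 2.824313, 'p_raw': 0.047619}
```

Reading this: among the nine pooled compartments, the TI-Treg repertoire is
most similar (Morisita-Horn) to blood and tumor **naive** CD4+ repertoires;
per patient, 11–14 % of unique TI-Treg TRBV12-4/TRBJ1-2 junctions are found in
the naive pools (recovering the planted θ = 0.13 within sampling error) versus
0 % in blood Tregs and memory cells, and the naive-vs-Treg contrast is
significant by Welch's *t* test. The dendrogram (`demo/stats/dendrogram.nwk`)
places TI_Treg inside the naive clade. All intermediates are persisted:
per-sample AIRR tables under `demo/processed/`, the similarity matrix, usage
and overlap TSVs under `demo/stats/`, and the full report in
`demo/report.yaml`.

## Scope notes

Clonotype identity is nucleotide-level (V gene, J gene, junction); amino-acid
level comparison is available as a flag. Nonproductive clonotypes are retained
by default (`--productive-only` to drop). No UMI handling, paired-end merging,
D-segment calling, PCR-bias modelling, or TCR-α/β pairing — see
`docs/methods.md` for the model, its assumptions, and known limitations.
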