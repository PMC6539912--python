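# Methods

## Scoring model

The per-base score assigns +min(n, 4) to every base inside a run of n
consecutive guanines, −min(n, 4) inside a cytosine run, and 0 otherwise.
Non-ACGT symbols score 0 and break runs; input is case-insensitive and U is
read as T. The capping at 4 encodes the observation that four stacked
guanines saturate the contribution of a run to quadruplex stability, while
the sign encodes skew: G-rich windows predict a quadruplex on the scanned
strand, C-rich windows on its complement. A window of width W (default
25 bp) scores the mean of its base scores; a window qualifies when
|mean| ≥ threshold (default 1.2). Qualifying same-sign windows that overlap
or touch are merged by interval union into one maximal PQS region, which is
then re-scored as the mean base score over its full extent. Opposite-sign
regions never merge, so a G-rich and a C-rich region may coexist at nearby
coordinates.

Two consequences of the merged-region convention are worth stating:

- A merged region's extent is wider than the motif that triggered it,
  because every window overlapping the motif that still clears the
  threshold is included. Region counts are therefore counts of merged
  regions, not of qualifying windows.
- Re-scoring over the merged extent can, in rare configurations, produce a
  region score marginally below the threshold even though every
  contributing window qualified (the union includes low-scoring edges from
  both ends). `bin_score` rejects such values per its contract; the census
  path (`bin_score_clamped`) counts these regions in the lowest score bin
  so that bin counts always sum to the PQS total.

Scores are computed from exact integer window sums (cumulative sums in
int64) divided by the window width, so implementation and brute-force
enumeration agree bit-for-bit; tests assert equality at 1e−12.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| window_size | 25 bp | sliding-window width |
| threshold | 1.2 | minimum \|mean score\| for a qualifying window |
| score_bins | [1.2,1.4), [1.4,1.6), [1.6,1.8), [1.8,2.0), [2.0,∞) | census intervals by score magnitude |
| flank | 100 bp | feature-neighborhood width for before/after zones |
| min_group_size | 10 | genomes required for a group to enter the Kruskal–Wallis test |
| α | 0.05 | significance cut-off |

Bins are left-closed/right-open; binning is by score magnitude, so a −1.4
region falls in [1.4, 1.6). Densities are reported as
f = 1000 × count / length (PQS per kbp). Chromosomes are treated as linear;
no window spans the origin of a circular chromosome (at W = 25 the missed
annulus is negligible at genome scale). Sequences shorter than W contribute
zero windows (with a warning) rather than an error, so plasmid-bearing
assemblies aggregate cleanly.

## Localization

Each feature defines three zones: *inside* (the annotated interval),
*before* and *after* (flanks of up to 100 bp, truncated at sequence
boundaries). Orientation is strand-aware by default — "before" is the 5′
flank, i.e. genomic right for minus-strand features — with a switch to
plain genomic left/right for sensitivity analysis; features of unknown
strand are oriented as plus-strand. A PQS belongs to every zone it overlaps
by ≥ 1 bp (the most inclusive rule; a boundary-spanning PQS counts once in
each zone it touches, never twice in one), and overlapping features are
counted independently, so one PQS may contribute to several cells of the
(feature class × zone) table. Cell frequency is 1000 × count / summed
truncated zone length; zero-length cells are omitted.

## Cohort statistics

Per-genome summaries use total assembly length (chromosomes + plasmids) and
GC% = 100 × (G+C)/length with ambiguous bases kept in the denominator.
Group summaries report median/shortest/longest genome length, unweighted
mean GC%, pooled PQS totals, and mean/min/max per-genome density. The mean
density is the **unweighted mean of per-genome frequencies** (the min/max
columns are per-genome quantities, so the mean is treated the same); a
pooled-counts/pooled-length alternative is available via `pooled_mean=True`.
The whole-dataset score-bin census, by contrast, uses pooled counts over
pooled length, matching its definition.

Group comparison is the Kruskal–Wallis rank test (scipy implementation,
tie-corrected H, chi-square approximation with k−1 df), applied after
dropping groups below the minimum size. All-tied input, where the tie
correction degenerates, is defined as H = 0, p = 1. No multiple-testing
correction is applied: one omnibus test per grouping level. A property
test verifies the implementation against an independent hand-rolled
mid-rank computation to 1e−9, and a Monte-Carlo check confirms type-I error
of 0.05 ± 0.02 under a simulated null at 1000 reps.

Per-bin frequency vectors are max-normalized (divide by the bin maximum)
and genomes with normalized value strictly greater than 0.5 are flagged;
an all-zero bin yields no flags.

## Synthetic data

The generator emulates bacterial chromosomes: i.i.d. backgrounds with
P(G) = P(C) = gc/2 over the empirical bacterial GC range (~20–75%), planted
G-rich tracts — by default (GGGGTGT)₈, whose long-tract mean score is
17/7 ≈ 2.43 — overwritten (not inserted) at uniform-random non-overlapping
positions so stated lengths stay exact, and NCBI-dialect feature tables
with the standard feature classes. Placement uses the gap method (sorted
uniform offsets plus cumulative item widths), which is uniform over feasible
non-overlapping placements and succeeds whenever the load fits, unlike
rejection sampling at high densities. Cohorts realize per-group planted
densities as Poisson counts at the requested per-kbp rate; each genome's
random stream derives from (cohort seed, genome index), so generation is
reproducible and independent of processing order.

What the background does and does not emulate: an i.i.d. sequence carries
the GC-dependence of PQS density (more and stronger calls at high GC) but
no dinucleotide structure, codon bias, or repeat families. One quantitative
consequence matters for interpreting tests: at 30% GC an i.i.d. background
genuinely contains qualifying 25-bp windows at ~2×10⁻⁵ per window, i.e.
roughly 20–30 merged calls per Mbp. These are real G-rich regions — actual
low-GC bacterial genomes show comparable or higher densities — so
"planted tracts are the only calls" holds only on cleaner backgrounds;
measured call rates are ~0 per Mbp at GC ≤ 0.15. Ground-truth-exactness
tests therefore use GC 0.15, while recovery (every plant covered by a call)
is tested at GC 0.30. Passing tests demonstrate scanner and bookkeeping
correctness on known constructions, not biological realism of the
background.

The acceptance script's default cohort — three groups of 12 genomes,
200 kbp each, GC 0.30/0.45/0.60, planted densities 0.05/0.25/0.50 per
kbp — was chosen to span the bacterial GC range with clearly distinct
group densities at a size that scans in seconds; genome lengths are far
below real chromosomes (0.3–20 Mbp) but every computed quantity is
length-normalized, so scale affects only sampling noise.

## Numerical and degenerate-input conventions

- Internal coordinates are 0-based half-open; written tables use 1-based
  inclusive coordinates (NCBI convention). Conversion happens only at I/O.
- Feature-table rows with unparsable coordinates are skipped and counted;
  reversed minus-strand coordinates are normalized to start < end.
- Output ordering is deterministic: PQS by (seq_id, start, strand), zone
  tables by first appearance of feature class, groups by manifest order.
- Per-genome failures during a cohort run are recorded and skipped; the
  run continues and reports them rather than aborting.
- A genome with no features yields an empty zone table with a warning; an
  empty manifest or zero-length genome is an error.

## Known limitations

- The merged-region counting convention is declared, not derived: whether
  published G4Hunter censuses count merged regions or raw qualifying
  windows is ambiguous, so absolute counts from other tools may differ by
  a few percent even at identical parameters.
- No loop-length grammar or topology prediction: the score is
  composition-based, and experimentally validated at room temperature, so
  thermophile counts may be overestimated near the threshold.
- Circularity, assembly QC, and phylogenetically corrected regression of
  density on GC are out of scope.
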