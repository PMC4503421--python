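# Methods

This note records the models implemented in `orfanage`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic-data
studies do and do not demonstrate.

## Coordinates and the deletion model

All coordinates are 1-based inclusive (GFF3 convention).  A deletion is a
pair `(left_retained, right_deleted)` — the last base kept before the gap
and the last base removed — so its length is `right_deleted −
left_retained` and the removed interval is `left_retained+1 ..
right_deleted`.  For the study geometry, (5,799; 15,339) gives 9,540 nt.
Against a deletion, an ORF is *fully deleted* iff it lies entirely inside
the removed interval, *retained* iff it does not overlap it, and
*truncated* otherwise; the three statuses partition any annotation.

Breakpoint coordinates of a deletion are only uniquely defined when the
junction carries no micro-homology: if the first deleted base equals the
first base after the gap (or symmetrically at the right edge), shifting
both breakpoints by one yields the identical variant sequence.  The fixture
generator therefore guarantees a homology-free junction by adjusting at
most two bases, both inside the deleted interval, making exact breakpoint
recovery a well-posed target.

## Headful packaging

A packaging *series* models one concatemer processed by a terminase: the
first cut is exactly at the `pac` position, and `k` headfuls of length
`L_h = round((1+r)·G)` (round half up) are cut sequentially, so headful `m`
starts at `pac + m·L_h (mod G)`.  The redundancy fraction `r` defaults to
0.03, the ~3% over-length packaging characteristic of T4-like phages.
Because a series covers the circle `k` times plus an extra arc of `k·r·G`
starting at `pac`, positions in that arc occur `k+1` times versus `k`
elsewhere — expected depth fold `(k+1)/k`, i.e. 2 for single-headful
series.  Genotype mixtures draw one genotype per series by weight; deletion
variants have shorter genomes and hence shorter headfuls at the same `r`.
The "variable loci" of later cuts are realized by the modular drift of
headful starts, not by randomizing `pac` — the simplest mechanism
consistent with sequential headful cutting.  Series are independent; the
spacing of independent initiations along one concatemer is not modelled.

Reads are paired-end: inserts uniform within each fragment (equal insert
counts per fragment), R1 the forward strand of the insert, R2 the reverse
complement of its other end, optional per-base substitution errors,
constant Q40 quality placeholders (the pipeline never uses qualities).  One
seeded generator stream drives genotype draws, insert placement and errors,
so runs are byte-reproducible.  No indel/quality error model, adapters,
optical duplicates or GC bias.

### Fragment-edge bias of the depth-ratio fold estimate

Inserts cannot extend past the ends of a packaged fragment, so coverage
ramps from 0 to full over roughly one insert length at both fragment ends.
For `k = 1` both copies of the redundant window sit exactly at the fragment
ends, so the plain in-window/out-window depth ratio has expectation about
`2 − ins/w` (insert length `ins`, window width `w = r·G`) rather than 2.
`expected_coverage` models these ramps analytically (using `insert_mean`
as the insert length) and is the oracle for Monte-Carlo depth profiles.
The canonical redundancy study (`gen_redundancy_scenario`: 50-kb genome,
`pac` 20,000, k=1, r=0.03, 200 series, ~100× of 100-nt reads) therefore
uses a minimal-insert overlapping-pair library (insert 102 ± 2 nt), keeping
the expected ratio ≈ 1.93–1.94, within a few percent of the ideal 2; with
a conventional 450-nt insert the same estimator would be biased down to
≈ 1.7.  The bias formula, not trial and error, fixed this choice.

## Mapping and deletion calling

The mapper is deliberately minimal and documented as unsuitable for real
data (real alignments can be imported as depth TSV or minimal M-only-CIGAR
SAM instead): a placement must have *both terminal k-mers* (k = 21) of the
read matching the circular reference exactly on one diagonal; candidates
are scored by ungapped full-length mismatch count; the best placement is
reported unless it ties with a distinct placement or falls below 80%
identity.  Both-end exact anchoring is what makes reads spanning a junction
absent from the reference reliably unmapped (their junction-adjacent base
mismatches by the no-micro-homology guarantee), so the depth signal inside
a deleted locus is exactly zero rather than smeared by mismatched
overhangs.  The cost is that a read with a sequencing error in its terminal
21 bases goes unmapped (~19% of 250-nt reads at error rate 0.005) — an
acceptable depth loss for deletion calling, and the documented reason this
mapper is for synthetic studies only.

Deletion candidates are maximal runs of depth ≤ `max_depth` (default 0 —
the signal of interest is the absolute absence of reads; a relative mode,
≤5% of median, exists for noisy imports) of length ≥ `min_run` (default
500 nt), ranked by length.  At any finite depth the zero run systematically
*overshoots* the true interval: the base just left of the gap is covered
only by reads ending exactly at the breakpoint (a ~Poisson(0.6) event at
150×), so the run boundary drifts outward by a geometric number of bases.
Rather than split-read or soft-clip logic, breakpoints are refined with
junction evidence: `refine_breakpoints` scores candidate junctions
`(L', R')` within a small search radius of the run boundaries against the
unmapped reads (`junction_support`: the 2×20-nt junction or its reverse
complement contained in a read with ≤ `max_mismatch` mismatches, found by
pigeonhole seeding) and returns the best-supported pair.  Under the
no-micro-homology guarantee the true junction is the unique maximiser.

Mixture frequency of wild type in a WT/deletion population is the mean
depth inside the deleted interval over the mean depth of the two 2-kb
flanks, clipped to [0, 1].  The raw ratio carries a ≤5% bias from unequal
genotype lengths (a series from the shorter genome concentrates the same
read count on fewer bases); this is documented, not corrected, and the
test-suite oracles centre on the biased expectation
`f/L_wt / (f/L_wt + (1−f)/L_var)`.

## Step detection

The terminal-redundancy step is fit as a circular two-change-point
piecewise-constant model maximising the two-segment Poisson log-likelihood
(depth is a small-count process, so Poisson rather than Gaussian), by
exhaustive search over window starts and arc widths on a grid (default
100 nt; arcs between 0.5% and 20% of the genome), followed by a single-base
re-search of the winning cell (the coverage ramp midpoint sits ~insert/2
inside the window, which otherwise lands the snapped boundary a full grid
cell away from `pac`).  Ties break toward the smaller window, then the
smaller start.  At grid 1 the coarse search is already exhaustive and the
refinement is skipped, so the detector is provably identical to brute-force
enumeration there (property-tested).  A constant profile returns fold 1
with a degenerate null window.

## Recruitment

Hit tables are the 12-column tabular dialect with an optional 13th `qlen`
column (otherwise query lengths come from a sidecar mapping); `sstart >
send` encodes minus-strand hits; the library id is the `LIBRARY|read`
prefix of the subject id.  Filtering keeps hits with alignment
percent-identity ≥ 40 and query coverage `(qend−qstart+1)/Q_L` ≥ 0.50,
both inclusive — identity is taken from the hit table's identity column
whatever residue type the search reported, and coverage is measured on the
query because the query is the ORF being recruited.  BRBH validation keeps
a hit iff the top reciprocal hit of its read region (max bitscore, then min
e-value, then lexicographic subject id — a tie-break this package fixes,
as no convention is standard) is the originating ORF; regions absent from
the reciprocal table fail validation and are counted separately.  No search
engine is executed; tables are inputs.

Abundance: `RGA = (N / Q_L / DB_S) × 10¹²` with `DB_S` in the denominator —
an abundance normalised per unit of database must decrease as the database
grows; the scale factor merely makes typical values order-1.  `N` counts
each read once per (ORF, read) by default (`per_read`); a `per_hit` count
is also reported.  Synteny: per read with ≥2 validated hits, hits
overlapping mutually by >50% collapse to the higher bitscore, the rest are
ordered by leftmost read coordinate, and each ordered adjacent pair adds
weight 1 to a directed edge (with a same-polarity tally); total weight
equals Σ max(0, hits_on_read − 1).  Mate taxonomy labels a read by the
taxonomic group of its mate's best hit per collapsed region: one group →
that group, several → `mixed`, no hits → `no_hit`.

## Statistics

The Student-t two-sided tail is `I_{df/(df+t²)}(df/2, ½)` with the
regularized incomplete beta evaluated by a modified-Lentz continued
fraction (300 iterations, 3e−15 termination), so the module has no
behavioural dependence on an external statistics library; scipy and
statsmodels appear only as oracles in tests.  Pearson reports `n` and
`df = n−2` separately (parenthetical sample-size notations are ambiguous),
with `t = r·√(df/(1−r²))`.  The two-sample t-test defaults to pooled
Student with Welch optional, and reports the fold difference of means
(larger/smaller) alongside.  Genotype frequencies get exact
Clopper–Pearson intervals (beta quantiles).  Salinity enrichment correlates
database size with per-library hit counts within each class (classes with
<3 libraries are skipped with a notice; constant counts surface a
zero-variance error, or a notice in reporting contexts) and can flag
libraries whose removal flips significance at α = 0.05 (leave-one-out).

## Synthetic data: what it emulates and what it does not

`gen_fixture` tiles 244 non-overlapping ORFs on a random 196-kb sequence
(GC 0.38): 16 upstream, the non-ORFan ORF017 straddling the left
breakpoint (hence truncated), 33 ORFan ORFs wholly inside the deleted
interval, and the remainder downstream; ORF lengths adapt to the available
pitch on smaller geometries.  `gen_metagenome` plants per-(ORF, library)
true counts as Poisson with mean `baseline_rate + β_class·DB_S` — linear
through the origin by default (freshwater β = 1.5e−8 per nt, brackish
5e−9, marine 0; DB sizes uniform on 1e8–1e9 nt), the simplest model
producing a database-size/hit-count correlation; `baseline_rate` (default
0) supports null-model calibration studies where counts must vary without
depending on DB size.  True orthologs draw identities on (40, 95] and
coverages on (0.5, 1] with 5% planted exactly at the 40.0/0.50 boundary to
pin the inclusive convention; decoys are planted below threshold; 10% of
true hits have their reciprocal search outscored by a decoy protein and 2%
lack a reciprocal entry; long-read (900-nt) libraries carry multi-ORF reads
(adjacent ORFan triples/pairs in shuffled order and polarity) for the
synteny graph; paired libraries get mates with planted taxonomy labels.
ORFan "proteins" are random translations — the pipeline is
composition-agnostic by design.  `gen_plaque_radii` draws two lognormal
samples (n = 34 per strain, CV 0.15) with a 6-fold mean ratio, wild type
smaller.

Passing tests on these generators demonstrate the *logic* of the pipeline
(filters, validation, counting, graph construction, statistics) exactly,
and its *estimators* within stated sampling intervals.  They do not
demonstrate performance on real data: real reads have indels, quality
structure and chimeras the simulator omits; real homology searches produce
score distributions unlike the planted ones; and absolute abundances are
generator conventions, since only relative/structural behaviour is
testable without the original databases.

## Problem sizes and numerics

The canonical studies are sized for a laptop-class run: the full 196-kb
fixture at 160× (≈ 119,000 reads of 250 nt) maps in a few seconds via the
k-mer index; the redundancy study uses a 50-kb genome at ~100×.  Property
tests for the step detector use ≤ 600-base profiles where brute force is
exact.  Numerical tolerances: incomplete-beta agreement with reference
implementations to 1e−12 absolute; Pearson two-pass equivalence to 1e−12
relative; likelihood comparisons in the step search use a 1e−9 slack so
ties resolve by the documented window-size rule rather than float jitter.
Degenerate inputs are defined behaviour: constant depth profiles (null
step), zero-variance vectors (errors), empty hit tables (empty outputs),
all-N runs (read placement refused).

## Known limitations

* The mapper is exact-anchor and ungapped; it is not a general aligner and
  must not be used on real reads (import real alignments instead).
* Deletions beginning at base 1 of the reference cannot be represented
  under the (last-retained, last-deleted) convention and are skipped by the
  caller.
* Annotation intervals may not wrap the circular origin; one reference
  sequence per run.
* The observed ~2–3-fold step in real data exceeds the single-headful
  prediction of 2; `k` and `r` are exposed, but no mechanism for >2-fold is
  invented.
* `estimate_mixture`'s genome-length bias is documented, not corrected.
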