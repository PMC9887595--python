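# Methods

## The model: trend-preserving biclusters

A bicluster B = (I, J) of an m×n expression matrix A is *trend-preserving*
when every pair of its rows is order-preserved or order-reversed over the
columns J: rows x and y are order-preserved when corresponding entries have
the same within-row ranks, and order-reversed when x and −y are
order-preserved.  This class contains the constant, row-constant,
column-constant, shift (x + c), scale (c·x, c > 0) and shift+scale patterns
as special cases, which is why it is the target class for co-expression
analysis: genes responding to the same signal need not share magnitudes,
only the ordering of their response across conditions.

The package implements the row-based search strategy appropriate for
*broader* matrices (many columns).  Narrow matrices (n ≤ 500) are better
served by column-based tools such as RecBic; the driver warns in that case
and proceeds, since the row-based procedure remains correct at any width.

## Qualitative representation

Each row is discretized independently into integer levels −r..r using only
within-row ranks (any strictly monotone transform of a row leaves its levels
unchanged):

* mid-rank fractions band the whole row equal-frequency into 2r+1 levels, so
  the median band maps to 0 and a constant row becomes all zeros;
* the extreme levels ±r are capped to the ⌈q·n⌉ most extreme entries per
  tail (tie-safe: entries tied with the cut are excluded), preserving q's
  QUBIC-family meaning of "fraction treated as strongly regulated".

Defaults q = 0.06, r = 15.  With r = 1 the scheme reduces to the classic
up/flat/down representation; the seeding stage, however, needs fine-grained
ordering, and a large flat middle band is actively harmful: level-0 columns
shared by a row pair form one giant equal-value clique, every dominance
chain passes through it, and seeds lose all contrast between implanted
structure and background.  Keeping all 2r+1 bands informative (rather than
collapsing the middle mass to 0) is therefore a deliberate design choice;
it also mirrors the observation that this strategy, unlike quantile-masking
tools, processes neutral genes rather than discarding them.  Equal input
values always receive equal levels, which the clique contraction below
relies on.

## Seed optimization

For rows r_i, r_j the pseudo-DAG G_ij has the columns as vertices and an
edge (s, t) exactly when (a_is, a_js) ≥ (a_it, a_jt) componentwise.  Edges
are bidirected iff the value pairs are equal; contracting each
equal-value-pair clique (vertex weight = clique size) leaves an acyclic
dominance order, and the maximum-weight directed path, bloomed back to
columns, is the optimum 2×L seed — the largest submatrix on which the two
rows are order-preserved.  Order-reversal is handled by repeating the
computation on (r_i, −r_j) and keeping the longer result (ties prefer the
order-preserved orientation), which realizes trend-preservation exactly.

The longest weighted path is computed by dynamic programming over the
unique value pairs sorted by (first component desc, second desc) — a
topological order — in O(u²) for u unique pairs.  Tie-breaks are fixed
(earliest vertex in sorted order wins both as predecessor and as chain end;
clique members bloom in ascending column order) so all results are
deterministic.  The inner loop is JIT-compiled with numba, with a pure-NumPy
fallback asserted to agree including tie-breaks.

Seeds are enumerated for all row pairs within k random, balanced row
subsets.  k = max(1, ⌊t_min/2⌋), where t_min is the smallest row count at
which a trend-preserving t×s submatrix is unexpected by chance — the
union-bound expectation C(m,t)·C(n,s)·(2/s!)^t falling below the
significance level p (default 0.05), with s = max(5, ⌈0.1·n⌉) the smallest
seed width considered significant.  By pigeonhole, any true bicluster with
≥ t_min rows places two of them in one subset, so it contributes at least
one seed.  For the simulated designs here t_min = 2, hence k = 1 and all
pairs are enumerated; the partition matters for much larger m.

## Extension

*Exact stage.*  The current bicluster's consensus is an auxiliary seed: an
integer vector ranking the path's columns (a contracted clique shares one
rank; off-path columns carry a sentinel).  Each round scores every outside
row by the longest chain of (consensus ranks, candidate row) over the
current columns — the same kernel as seeding, best over both orientations —
recruits the argmax (ties: smaller row index), shrinks J to the new chain,
and rebuilds the consensus.  The trajectory trades columns for rows;
the state maximizing min{|I|, |J|} (ties: larger |I|·|J|, then earlier) is
returned, and growth stops after three consecutive non-improving
recruitments rather than at the first, since plateaus are common.
Candidate scores are cached while (J, consensus) are unchanged, which makes
growth through a clean implant nearly linear-time.

*Tolerant stage.*  One pass with threshold α (default 0.9; α = 1 is
strictest).  A column is added when more than α of the core rows accept it
into one insertion window of the consensus; the window may skip consensus
columns totaling at most ⌊(1−α)·|J|⌋ — the same disagreement budget rows
get — because a single spurious consensus column (which can survive the
exact stage by chance) would otherwise split a genuinely agreeing column's
insertion gap across rows.  A row is added when its best-orientation chain
against the (column-extended) consensus covers more than α of the columns.
Columns are judged against the original core, then rows against the
column-extended core; nothing is ever removed.  A second fixed-point pass
was considered and rejected to keep the stage's behavior predictable.

## Scoring and output

The significance of a t×s bicluster is BS = −t·(ln(2nmt) − ln s!), computed
via log-gamma so large s cannot overflow; larger is more significant.  The
s! term grows much faster than the t factor, expressing that co-expression
across more conditions is stronger evidence.  A variant without the inner
factor t is available (`score_variant="text"`); the two orderings almost
never differ.

The driver pops seeds longest-first, extends each, purges every remaining
seed touching the discovered rows (a seed with even one endpoint inside a
found bicluster only re-extends into a fragment of it), and stops after 2·o
cores or seed exhaustion.  Output keeps the top o (default 50) by BS after
three filters:

* significance: BS > −ln(p), negligible for real blocks, removes the small
  cores that false seeds collapse to;
* width: blocks narrower than s_min = max(5, ⌈0.1·n⌉) columns are dropped —
  the BS chance model (2/s!)^t is far too optimistic for very narrow blocks
  assembled by the tolerant stage, and narrow biclusters are the
  column-based strategy's mandate, not this one's;
* redundancy: a candidate is dropped when its element-wise Jaccard with a
  kept block exceeds 0.9, or when over half of its cells are contained in a
  kept block (fragments re-formed through recruitment have low Jaccard but
  near-total containment).

## Synthetic data

The generator reproduces the simulation designs: an iid N(0,1) background
(600×600 at full scale), a configurable fraction (default 0.05) of each
row's entries duplicated from the same row to mimic tied values, and
implanted submatrices.  A trend implant fixes its first row and re-orders
every other row's own values into the fixed row's rank order, so implants
are exactly trend-preserving by construction; shift / scale / shift+scale /
row-constant / column-constant / constant implants are built from a shared
base profile with the stated per-row transforms.

Overlapping designs give consecutive implants a shared rows×cols region set
to a single constant.  For both implants to stay trend-preserving the tied
block must occupy the same rank interval in every row, which is only
generally feasible at an extreme of each implant's ordering: region
constants are placed just beyond the implants' value range (alternating
above/below for consecutive regions so a middle implant can pin one region
per end), with the offset magnitude drawn from the seeded RNG.  A constant
drawn from the bulk of N(0,1) cannot work — different rows would have
different numbers of values below it, so no common rank interval exists.

Row noise replaces ⌊level·s⌋ entries per implant row with fresh N(0,1)
draws; removing those entries restores the row's agreement with the
consensus, so the measured per-row noise level (fraction of entries whose
removal restores the trend) never exceeds the requested level.

What the generator does *not* emulate: count noise and library-size effects
of RNA-seq, correlated backgrounds, batch structure, or biclusters with
partially conflicting trends.  Passing these simulations therefore shows
the search machinery recovers planted rank structure under the stated noise
and overlap models, not that real-data performance is guaranteed.

## Study protocols and problem sizes

Two scales are built in.  Full scale mirrors the original experiments:
600×600 background, six 100×100 implants (three for the noise design),
overlap levels 0/30/40/50, four replicates (`scripts/full_design.py`).
Desk scale shrinks the background to 300×300 with three 60×60 implants and
overlaps scaled by the implant-size ratio 0.6 (0/18/24/30), two replicates
— the package's default study size, chosen so a complete trend + overlap +
noise study runs in a few minutes on one CPU while preserving the
background-to-implant proportions and the implant density of the original
design.  Measured at desk scale: trend design recovery = relevance = 1.0;
overlap design ≈ 0.99 at levels up to 40% with degradation appearing at
50%; noise design decreasing monotonically with level (≈1.0 at level 0).
One full-scale trend replicate reproduces the ≈0.99 recovery/relevance
headline; see the repository README for how to run it.

## Numerical and degenerate-input choices

* Constant rows discretize to all zeros; an all-constant matrix is one
  giant clique, every seed spans all columns, and the core grows to the
  whole matrix — the documented degenerate behavior.
* q·n < 1 leaves single-entry regulated tails and emits a warning.
* Missing cells are rejected at load time by default; optional row-median
  imputation exists because silent imputation changes ranks, which drive
  everything downstream.
* All randomness (row partition, simulation) flows from explicit integer
  seeds; a fixed seed makes the entire run, including output files,
  bit-reproducible.
* Logs are natural throughout.

## Known limitations

* The exact stage requires perfect agreement, so at noise levels ≥ 0.2 the
  surviving column set shrinks quickly and recovered blocks are partial;
  the tolerant stage recovers some of the loss but quality at noise 0.3 is
  poor.  Monotone degradation, not noise-0.3 accuracy, is the validated
  property.
* The BS chance model assumes continuous, untied values; it overstates
  significance for narrow blocks (hence the width floor) and is not
  calibrated against an empirical null.
* The greedy recruitment is sequential and single-threaded; seeds are
  independent and the loop parallelizes naturally, but no parallel path is
  implemented.
* The column-based strategy for narrow matrices is out of scope; the n ≤
  500 branch warns and runs the row-based search.
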