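# arbic

Trend-preserving biclustering of gene expression matrices — a row-based
search for submatrices whose genes rise and fall together across a subset of
conditions, together with the simulation and evaluation protocols to
validate it.

## The problem

Genes co-regulated by a shared signal are often correlated only under some
conditions, and rarely with matching magnitudes: one gene's response may be
a shifted, scaled, or even inverted version of another's.  The natural
target is the *trend-preserving* bicluster — a submatrix (I, J) in which
every pair of rows is order-preserved (identical within-row ranks across J)
or order-reversed (x and −y order-preserved).  This class generalizes
constant, shift, scale and shift+scale patterns and is the one tied most
directly to co-expression.

This package is for anyone analyzing bulk or single-cell expression
matrices with many conditions ("broader" matrices), and for methodologists
who need a reproducible simulation benchmark for trend-preserving
biclustering.

## The algorithm

For each pair of rows, the columns form a *pseudo-DAG* under the dominance
order: an edge (s, t) exists when the value pair at column s dominates the
pair at t componentwise.  Columns with equal value pairs form cliques;
contracting them (weight = clique size) leaves an acyclic graph whose
maximum-weight path, bloomed back to columns, is the optimum 2×L seed — the
largest submatrix on which the two rows agree in trend (the order-reversed
case is covered by negating one row).  Seeds are grown greedily: an
auxiliary rank vector summarizes the current consensus, candidate rows are
scored with the same longest-chain kernel, and the core bicluster maximizes
min{|I|, |J|}.  A tolerant pass then adds every row and column agreeing
with the consensus on more than a fraction α of its entries (default 0.9).
Output blocks are ranked by the significance score

    BS = −t · (ln(2·n·m·t) − ln s!)

for a t×s block in an m×n matrix (larger = more significant), with
near-duplicates and contained fragments suppressed.

Before any of this, each row is discretized by ranks into integer levels
−r..r (defaults r = 15, with the ±r extremes capped to the q = 0.06 most
extreme fraction per tail), so the search depends only on within-row
orderings, never magnitudes.

## Worked example

Implant three 60×60 trend-preserving biclusters into a 300×300 standard
normal background, run the pipeline, and score the output against the
ground truth:

```python
from arbic import run_arbic
from arbic.evaluate import recovery_relevance
from arbic.simulate import ImplantSpec, SimulationSpec, generate

spec = SimulationSpec(
    m=300, n=300,
    implants=[ImplantSpec(t=60, s=60) for _ in range(3)],
    rng_seed=7,
)
matrix, truth = generate(spec)

blocks = run_arbic(matrix, rng_seed=1)
for i, b in enumerate(blocks, 1):
    print(f"BC{i}: {b.n_rows} genes x {b.n_cols} conditions, BS = {b.score:.1f}")

recovery, relevance = recovery_relevance(truth, blocks)
print(f"recovery = {recovery:.3f}, relevance = {relevance:.3f}")
```

prints

```
BC1: 60 genes x 60 conditions, BS = 10346.0
BC2: 60 genes x 60 conditions, BS = 10346.0
BC3: 60 genes x 60 conditions, BS = 10346.0
recovery = 1.000, relevance = 1.000
```

Exactly the three implanted blocks are reported (all three share one BS
because they share one shape), and none of the background is: recovery is
the average best element-wise Jaccard of each true block against the
predictions, relevance the same in the other direction, so 1.000/1.000
means a perfect reconstruction.

The same run is available from the shell:

```
arbic simulate --spec spec.yaml --out-matrix m.tsv --out-truth t.json
arbic run -f m.tsv --seed 1 --out blocks.txt --out-json blocks.json
arbic evaluate --truth t.json --pred blocks.json
```

Input matrices are tab-delimited text (header row of condition names, one
gene per row), the format shared by the QUBIC family of tools.

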