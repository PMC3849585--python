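# Methods

## Correlation graphs

Profiles are correlated with the sample Pearson coefficient on the natural
(anti-logged) intensity scale; no probe filtering is applied before
correlation. Thresholds are one-sided — an edge requires `r >= t`, never
`|r| >= t` — so anti-correlated pairs never form edges, and ties at exactly
`r == t` are included. Three thresholds matter, all overridable:

| parameter        | default | role                                        |
|------------------|---------|---------------------------------------------|
| save threshold   | 0.70    | pairs persisted to the `.pearson` edge file |
| gene graph       | 0.75    | probeset-to-probeset graph edges            |
| sample graph     | 0.90    | sample-to-sample graph edges                |

The engine standardizes each profile once (centered, unit norm) and forms
the correlation matrix in `chunk_size x chunk_size` blocks (default 2000),
so peak memory is bounded by the chunk size rather than the number of
probesets squared; the emitted edge set is exactly the set a naive double
loop produces, independent of chunking and of row order (edges are stored
as lexicographically ordered unordered pairs, sorted). Zero-variance
profiles have undefined correlations and are excluded from edge generation;
the exclusion count is logged. Accumulation is in double precision.

Graphs contain only the endpoints of surviving edges: probesets correlated
with nothing at the threshold are absent, which is why a coexpression graph
typically covers a minority of the array.

## Markov clustering

MCL is implemented from scratch on sparse column-stochastic matrices:
self-loops are added (weight = each node's maximum incident edge weight;
the alternative `unit` is available), columns are normalized, and the
iteration alternates *expansion* (matrix power, default 2) and *inflation*
(element-wise power, default 2.2, then column renormalization), pruning
entries below `1e-5` each round. Convergence is declared when the max-norm
change falls below `1e-8` (default cap 200 iterations; non-convergence is
interpreted anyway and flagged). Clusters are read from the attractor
structure: rows with a positive diagonal are attractors, attractors sharing
flow form a system, and each node joins the system receiving the largest
share of its column mass (ties resolved toward the system containing the
lexicographically smallest attractor, making the output deterministic and
invariant to node relabeling up to that tie-break). Edge weights
(correlations) are used as similarities by default; pruning is the main
source of divergence between MCL implementations and is therefore explicit
and configurable.

Clusters are numbered 1, 2, ... by decreasing size (ties broken by
smallest member id); only clusters with strictly more than 6 nodes receive
numbers, and nodes of smaller clusters stay unassigned. The collapsed
cluster diagram keeps clusters of strictly more than 10 members, one node
per cluster sized by membership, with edges carrying the exact count of
underlying inter-cluster correlations. The strict inequalities are
deliberate and tested at the boundary.

## Resampling null for chance correlations

The chance of two *unrelated* profiles correlating at `r >= 0.75` is
estimated empirically rather than from the t distribution, because
natural-scale intensities are heavy-tailed and per-sample intensity
structure inflates the tail far beyond Gaussian theory. A pseudo-probeset
draws, independently for each sample, one observed value from that sample's
column (uniform over rows, with replacement) — preserving every column's
marginal exactly while destroying cross-sample structure. The simulation
draws N independent *pairs* of pseudo-probesets (default 10^6) rather than
all-vs-all among fewer pseudo-probesets, so hits are independent Bernoulli
trials and the tail fraction has a plain binomial error model. Pairs with
undefined correlation (zero variance) are redrawn and counted. The report
states the simulated tail fraction, the observed tail fraction (real pairs
at or above the threshold over all defined real pairs), and the expected
count of chance pairs (simulated fraction x total pairs), each labeled
explicitly; no further combination of the two fractions is applied. On iid
Gaussian input the simulated tail at `r = 0.75` with a few hundred samples
is analytically below 10^-28, so the correct simulated count is exactly
zero — a calibration the acceptance checks enforce.

## Term enrichment

Enrichment per cluster uses the hypergeometric upper tail `P(X >= k)`
(through `scipy.stats.hypergeom.sf`, which is accurate deep into the tail),
where `k` of the cluster's `n` genes carry a term held by `K` of the `N`
background genes. Probesets are collapsed to genes before testing — a gene
counts once per cluster however many probesets map to it — to avoid
pseudo-replication. Benjamini–Hochberg correction (via statsmodels) is
applied within each cluster across its tested terms, mirroring a
one-cluster-at-a-time testing workflow; a global family is available as an
option. Rows with adjusted `P < 0.05` are flagged and each cluster's report
is truncated to the 10 smallest adjusted p-values. Annotations are supplied
as a flat (term, gene) table; no ontology-graph propagation is performed,
so p-values are interpretable only relative to the annotation actually
supplied.

## Synthetic atlases

The generator emulates a normalized primary-cell atlas: `n_cell_types x
replicates_per_type` samples (each cell type treated as one contributing
series), planted modules whose genes share a cell-type-restricted activity
profile, and background genes with no shared structure. Gene `g` of module
`m` takes `x[g, s] = scale_g * a_m(celltype(s)) * (1 + eps)` with
`eps ~ N(0, noise_sd)` and truncation at zero. Defaults: 10 cell types x 4
replicates, 5 modules of 50 genes, 500 background genes, `noise_sd = 0.1`
(10% coefficient of variation, typical of replicate arrays), activity
baseline 1 with active cell types elevated around 8-fold, gene scales
around 100 intensity units. Choices worth noting:

* **Multiplicative noise** on the natural scale mimics intensity data
  better than additive Gaussian noise and keeps values non-negative after
  truncation.
* **Lognormal marginals** (gamma optional) for activities and gene scales
  make the data heavy-tailed on purpose: pseudo-probeset resampling on such
  an atlas yields a chance tail orders of magnitude above the Gaussian
  analytic tail, exercising the reason an empirical null exists.
* **Identifiability of planted truth.** A candidate module activity profile
  is redrawn if it correlates at `r >= 0.6` (across cell types) with an
  already-planted module. Two modules with near-collinear profiles are a
  single coexpression module in any meaningful sense, and keeping them as
  separate "truth" would make the generator's labels unrecoverable in
  principle. The 0.6 ceiling sits safely below the 0.75 graph threshold.
* What the generator does **not** emulate: probe-level effects, batch or
  laboratory effects across series, correlated background structure, and
  donor genetic variation. Passing the recovery checks therefore shows the
  pipeline recovers clean planted structure at realistic noise; it does not
  show robustness to confounded real-world atlases.

With these conditions the `r >= 0.75` graph contains exactly the module
genes, MCL at inflation 2.2 recovers the planted partition (adjusted Rand
index 1.0 on the standard fixture), and background genes remain isolated.

## Numerical and interface choices

* Correlations are clipped to `[-1, 1]` after block products to absorb
  rounding; the `.pearson` file stores 6 decimals, expression files 6
  significant digits (both round-trip stably at that precision).
* Replicate averaging is the arithmetic mean on the natural scale, grouped
  by (series, cell class), column order by first occurrence.
* The outlier screen flags samples whose median correlation to same-class
  samples falls below a floor; single-sample classes are skipped with a
  warning, and a floor of zero flags nothing. It is a deliberately simple
  surrogate for chip-level QC, which is out of scope.
* GEO series matrices are commonly deposited on log2 scale, so the reader
  takes an explicit `antilog2`/`log2` transform flag instead of guessing;
  nothing is anti-logged by default.
* The pipeline config merges user YAML over defaults; the null-simulation
  section is named `null_model` because a bare `null:` key is parsed by
  YAML as the null value. Threshold ordering (graph >= save) is validated
  before any computation.
* Problem sizes in the test suite and acceptance script (hundreds of genes,
  tens of samples, 10^5–10^6 null pairs) are chosen so the full suite runs
  in seconds while every check retains its statistical meaning; all sizes
  scale up through the same interfaces.

## Known limitations

* MCL cluster counts on large real graphs are sensitive to the pruning
  scheme and to whether edge weights are used; agreement with other MCL
  implementations at the level of exact cluster counts is not guaranteed.
* The enrichment stage tests only the terms supplied; without ontology
  propagation, sparse annotations understate enrichment of broad terms.
* The empirical null preserves column marginals but not any within-column
  dependence beyond them; structured technical artifacts shared across
  probesets within a sample are by construction part of the "chance" tail.
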