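# Methods

## The fingerprint representation

`snfkit` operates on a ternary region-by-study matrix rather than pooled
effect sizes. The coding is deliberately conservative: heterogeneous
preprocessing, smoothing, thresholds and volumetric models across
morphometry studies make absolute effect sizes incomparable, so a cell
records only whether a region was reported significantly decreased
(−1), increased (+1), or not reported abnormal (0). Absence of a report
is encoded by omission at the observation level — a zero observation is
rejected — so the matrix captures reported convergence structure, not a
fully sampled anatomical landscape.

Construction rules:

- Multiple same-sign observations in one (region, study) cell — e.g.
  several significant clusters inside one atlas region — consolidate to
  a single entry.
- Opposite-sign observations in one cell have no canonical resolution;
  the default policy is to raise an error, with an explicit
  majority-vote override that still rejects exact ties. Silent
  resolution would hide a substantive disagreement in the source data.
- Left and right instances of a structure are distinct regions when the
  source reports laterality; `BILATERAL` is reserved for findings
  reported as bilateral or without a side.
- All-zero rows are legal (an atlas-complete matrix has many) but
  flagged as warnings by validation; metrics treat them as
  never-abnormal regions.

## Networks

Regions map to one or more of seven canonical systems: default mode
(DMN), salience (SAL), frontoparietal control (FPN), limbic/memory
(LIM), sensorimotor/dorsal-attention (SMN), interhemispheric/callosal
(CAL) and brainstem/cerebellar (BSC). Multi-membership is preserved and
regions count with full weight in every network they belong to — network
sums therefore double-count dual-membership regions by design, and no
fractional splitting is attempted. For single-label uses (node
colouring, cluster agreement) a region's *dominant* network is its first
membership in a priority order, default `DMN > LIM > SAL > FPN > SMN >
CAL > BSC`. Alternative groupings are ordinary loadable scheme files,
not code changes.

## Convergence metrics

For network k: load `L_k` (non-zero entries over its regions),
distinct abnormal regions `N_k`, per-region index `A_k = L_k/N_k`, and
mean direction `D_k` (signed mean of non-zero entries). `A_k` is
undefined when `N_k = 0` and `D_k` when `L_k = 0`; both are carried as
NaN and serialised as the literal `NA`, never 0 — a zero would fabricate
a "mixed direction" or "no burden" signal. When defined,
`1 ≤ A_k ≤ |S|` and `−1 ≤ D_k ≤ 1`. Table ranking is by descending
`A_k` with ties broken by scheme order, so outputs are deterministic.
`L_k/|R_k|` is recoverable from the emitted `load` and `region_count`
columns for users who prefer the all-assigned denominator.

## Co-alteration graph

`C(r1, r2)` counts studies reporting both regions abnormal, ignoring
direction (a decrease co-occurring with an increase is still
co-alteration). The graph keeps edges with `C ≥ τ`; the default `τ = 2`
demands replication in two independent studies — `τ = 1` admits
idiosyncratic single-study co-reporting, while `τ ≥ 3` is very sparse at
typical corpus sizes (tens of studies or fewer). Conventions:

- Nodes are restricted to regions abnormal in at least one study;
  never-abnormal regions cannot bear edges and would deflate density.
  This choice is recorded in the graph object (`abnormal_only`).
- Self-loops are excluded; the diagonal of C (per-region abnormal-study
  count) is kept on the matrix object.
- A "module" is operationalised as a connected component of the
  thresholded graph — the simplest definition with no tuning
  parameters. A weighted greedy-modularity alternative is provided
  (`greedy_modules`) but is not the default.
- The threshold sweep reports edge counts, densities, component
  partitions and the persistence of a designated seed set (whether it
  lies inside a single component) per τ. Edge sets are nested in τ and
  densities non-increasing by construction.

## PCA

PCA is applied after row-wise centering (each region's mean across
studies subtracted), emphasising relative abnormality profiles over
absolute reporting frequency. The covariance is formed in the
region-by-region Gram shape, `Σ = X̃X̃ᵀ/(|S|−1)`, and eigendecomposed
directly; region scores use the principal-coordinate convention
`v_i √λ_i`. This is an exact PCA by singular-value duality: the non-zero
eigenvalues of the Gram form equal those of the conventional |S|×|S|
feature covariance (exposed as `feature_covariance` and tied to the Gram
route by a test at 1e-8). Because the rows are centered, the all-ones
study vector is a null direction and at most |S|−1 eigenvalues are
non-zero.

Numerical conventions: the `|S|−1` normalisation is used throughout;
eigenvector signs are fixed by making the largest-magnitude loading
positive (first occurrence on a magnitude tie); degenerate eigenvalues
keep their post-sort index order; eigenvalues below 1e-9 are treated as
zero. One consequence of normalising the Gram matrix before scoring is
that full-rank score distances equal centered-row distances divided by
√(|S|−1) — the embedding geometry is a uniform rescaling of the profile
geometry, which is what the tests assert.

## Hierarchical clustering

Ward linkage over Euclidean distances between region rows, computed by
the Lance–Williams recurrence with a deterministic tie-break (the
lexicographically smallest active cluster pair among minimal
distances). The recurrence is implemented in the package rather than
delegated, because ternary data produce exact distance ties and a
pinned tie-break is needed for reproducible merge trees; the scipy
implementation serves as an independent oracle in the tests. Tied merge
distances genuinely admit several valid Ward trees with different
height multisets, so cross-implementation agreement is asserted on
tie-free continuous inputs (agreement ~1e-15), while ternary behaviour
is pinned by exhaustive small cases (the three-point example is checked
against direct evaluation of the Ward objective over all merge orders)
and determinism tests.

Clustering operates on raw ternary rows by default, with a flag to use
the centered matrix for consistency with the PCA view; both modes are
tested. Flat partitions cut the merge sequence and renumber clusters by
smallest leaf index; agreement with dominant-network labels is the
adjusted Rand index (computed via scikit-learn, cross-checked against a
direct contingency-table evaluation). Dendrograms export to Newick with
branch lengths `parent height − child height`, giving an ultrametric
tree that round-trips its topology through standard parsers.

## Synthetic generator

The generator plants a known network partition and draws each
(region, study) cell independently: non-zero with probability
`p_k · η_s` (network detectability times study sensitivity), and
negative with probability `q_k` given non-zero, so `E[D_k] = 1 − 2q_k`.
`η` may be a scalar, a per-study vector, or a (network × study) matrix;
the matrix form creates network-exclusive study panels used for
planted-module recovery. Draws are positionally seeded: one seed yields
a bitwise-identical matrix.

This is the simplest model consistent with the ternary coding, and the
validation scenarios state what it emulates and what it does not. It
captures network-structured reporting rates and directional biases; it
does **not** model correlated reporting within a study (beyond the
panel structure), publication/reporting bias, study quality or sample
size weighting, or anatomical spatial correlation. Recovery tests
passing therefore show the estimators and graph machinery are correct
under the stated model, not that real literatures satisfy it.

Validation problem sizes, chosen as the smallest that put the moment
estimators well inside their binomial error bands: parameter recovery
uses 2 networks × 10 regions × 500 studies with `p = (0.8, 0.2)`,
`q = (0.9, 0.5)` (tolerance 0.05 on both estimates); module recovery
uses two 10-region networks, 30 studies in exclusive 15-study panels,
`p = 0.9`, `q = 0.9`, requiring adjusted Rand ≥ 0.9 between τ = 2 graph
components and the planted partition in at least 18 of 20 seeds.

## The packaged mTBI corpus

The fixture is a best-effort reconstruction of a ten-study T1-weighted
mTBI synthesis: 35 regions × 10 studies, 45 non-zero cells, shipped as
plain CSV/TSV (matrix, region metadata, study metadata) plus a
provenance table tagging every non-zero cell with its source-sentence
tag and confidence. Reconstruction choices:

- Nine studies are coded from explicit per-study region enumerations;
  the tenth had no region-level enumeration and its column is a
  plausibility reconstruction (midline grey-matter and callosal
  decreases), flagged `RECONSTRUCTED_LOW_CONFIDENCE` in both study
  metadata and provenance.
- Consolidation granularity (e.g. one study's generic "subcortical grey
  matter" folded into the bilateral thalamus region) was chosen so the
  distinct-region count is exactly 35.
- White-matter tract findings are separate WM regions assigned to the
  nearest cortical system for association tracts (e.g. superior
  longitudinal fasciculus → FPN), brainstem for projection tracts to
  the pons, and CAL for callosal tissue.
- The only positive entries are the two right dorsal cingulate volume
  increases; all other findings are decreases.

The fixture supports qualitative regression checks (DMN and LIM in the
top three per-region indices; a precuneus–hippocampus–thalamus module at
τ = 2). Cell-level contents of unenumerated studies are not authoritative
and nothing quantitative is claimed for them.

## I/O and determinism

Dialects are pinned: comma-separated matrices and result tables,
tab-separated metadata and edge lists, UTF-8, LF endings, `.` decimal
separator, floats at fixed 9-digit precision, missing values as `NA`.
Given identical inputs and configuration the report pipeline's outputs
are byte-identical across runs; edge lists and GraphML nodes are written
in sorted order to avoid dict-order artefacts. Logging goes to standard
error only. On a stage failure the partially written outputs of that run
are removed and the error re-raised naming the stage.

## Known limitations

- The matrix reflects reported findings only; unreported regions are
  indistinguishable from tested-but-null regions.
- No inferential statistics are attached to metrics or edges (no
  permutation nulls, no confidence intervals) — the framework
  summarises convergence, it does not test it.
- The aggregate is study-level: nothing here is an individual-level
  diagnostic model.
- Ward trees on ternary data are reproducible only relative to the
  pinned tie-break; other valid tie-breaks can yield different (equally
  optimal) trees.
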