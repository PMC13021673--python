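# snfkit

Structural network fingerprint analysis of region-by-study MRI
abnormality matrices.

## The problem

Structural T1-weighted MRI findings in conditions such as mild traumatic
brain injury (mTBI) are heterogeneous: individual morphometry studies
(VBM, volumetry, grey/white-matter probability maps, tensor-based
morphometry) each report a handful of significant regions, with
inconsistent direction and anatomy. `snfkit` is for researchers who want
to synthesise such region-level findings across studies *without*
pooling effect sizes or peak coordinates: it keeps each study's regional
profile, the direction of every finding, and the mapping of regions onto
canonical large-scale brain networks, and asks whether abnormalities
converge on network structure rather than scattering at random.

## The model

The core object is a ternary fingerprint matrix `X ∈ {−1, 0, +1}^{|R|×|S|}`
over atlas regions `R` and studies `S`:

    X(r, s) = −1  region r significantly decreased in study s
    X(r, s) = +1  region r significantly increased in study s
    X(r, s) =  0  region r not reported abnormal in study s

Each region belongs to one or more canonical networks (DMN, SAL, FPN,
LIM, SMN, CAL, BSC), giving region sets `R_k = {r : k ∈ N(r)}`. For each
network `k` the toolkit computes

- total abnormal load `L_k = Σ_{r∈R_k} Σ_s |X(r, s)|`,
- distinct abnormal regions `N_k = |{r ∈ R_k : ∃s, X(r, s) ≠ 0}|`,
- abnormality-per-region index `A_k = L_k / N_k`,
- mean direction `D_k = (1/L_k) Σ Σ X(r, s)` (−1 pure loss, +1 pure gain),

a direction-blind co-alteration matrix
`C(r1, r2) = Σ_s I[X(r1, s) ≠ 0 ∧ X(r2, s) ≠ 0]` thresholded at `τ` (default
2 co-reporting studies) into an undirected graph, a Gram-matrix PCA of
the row-centered profiles (`Σ = X̃X̃ᵀ/(|S|−1)`, scores `v_i√λ_i`), and a
Ward dendrogram of region profiles with an adjusted-Rand comparison
against network labels. A planted-network Bernoulli generator with known
`(p_k, q_k)` supports recovery testing, and a packaged 35-region ×
10-study mTBI corpus ships as plain CSV/TSV with per-cell provenance.

## Worked example

```sh
snfkit fixture --out corpus
snfkit report --matrix corpus/mtbi_matrix.csv \
              --regions corpus/mtbi_regions.tsv \
              --studies corpus/mtbi_studies.tsv --out report
cat report/metrics.csv
```

```
network,region_count,load,distinct_regions,per_region_index,mean_direction,rank
DMN,10,14,10,1.400000000,-0.714285714,3
SAL,5,5,5,1.000000000,-0.600000000,4
FPN,8,12,8,1.500000000,-1.000000000,1
LIM,8,12,8,1.500000000,-1.000000000,2
SMN,6,6,6,1.000000000,-1.000000000,5
CAL,1,1,1,1.000000000,-1.000000000,6
BSC,3,3,3,1.000000000,-1.000000000,7
```

Reading the table: the limbic/memory and frontoparietal networks show
the highest abnormality-per-region index (1.5 — their abnormal regions
are re-reported across studies half again as often as once), with the
DMN close behind (1.4) and carrying the largest total load (14 abnormal
entries over 10 regions). Every network's mean direction is negative —
predominantly volume loss — with the DMN's −0.71 pulled toward zero by
the two isolated cingulate volume *increases* in the corpus. At the
default threshold `τ = 2` the co-alteration graph keeps three replicated
edges (`report/edges.tsv`):

```
source	target	weight
hippocampus_b	precuneus_b	2
hippocampus_b	thalamus_b	2
mid_frontal_r	sup_frontal_r	2
```

whose largest connected module `{precuneus, hippocampus, thalamus}` is
the DMN–limbic–thalamic core; lowering `τ` to 1 inflates the graph to
119 edges (density 0.20) while that core stays connected. The first
principal component explains 31.2 % of the profile variance
(`report/eigen.csv`), and the full run summary (graph, sweep, PCA and
clustering numbers) lands in `report/run_summary.json`.

The same operations are available as a library:

```python
import snfkit as sk

matrix, scheme = sk.mtbi_fixture()
table = sk.metrics_table(matrix, scheme)
graph = sk.build_graph(sk.coalteration_matrix(matrix), tau=2, scheme=scheme)
```

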