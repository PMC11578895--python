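# Methods

This note documents the models implemented in atlaskit, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical conventions. It states no empirical number that the test
suite or `scripts/acceptance.py` does not itself compute.

## Network propagation (snp2cell engine)

### Model

The propagation substrate is a typed tripartite graph of transcription
factors, regulatory regions (enhancers/peaks carrying genomic intervals)
and target genes, with non-negative edge importances. Propagation treats
the graph as **undirected**: edges are symmetrized and importance-weighted,
and the transition matrix is column-normalized by weighted degree
(`T_ij = w_ij / deg_j`). Undirected random walk with restart is the
standard network-propagation choice and lets region nodes bridge TF↔gene
signal in both directions; nodes without a positively weighted edge get a
uniform column so the walk never loses mass.

Given a seed vector normalized to sum 1, the propagated score is the fixed
point of `q = r·s + (1−r)·T·q`, found by power iteration to an L1 change
below `tol` (default 1e-8). Because `T` is column-stochastic and the seed
sums to one, `Σq = 1` exactly at the fixed point — conservation is a
checkable invariant, and the power iteration is verified against the dense
solve of `(I − (1−r)T) q = r·s` in the tests.

### Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `restart_prob` | 0.15 | PageRank damping convention (0.85); controls diffusion range |
| `tol` | 1e-8 | L1 convergence of power iteration; ~110 iterations at r = 0.15 |
| `n_perm` | 1000 | permutation count of the published operating point |
| `z_thresh` | 2.0 | subnetwork threshold of the published operating point |
| `perm_mode` | `all` | uniform shuffle of seed values over all nodes (zeros included) |

The permutation null shuffles the raw seed values across all network nodes
and re-propagates; per-node permutation mean/SD give `z`, and empirical
`p = (1 + #{perm ≥ obs}) / (1 + n_perm)`. A degenerate null (`σ_perm = 0`,
e.g. a constant seed) yields `z = 0` rather than ±∞, so min-combination is
never poisoned by a degenerate node. A degree-binned shuffle
(`perm_mode="degree_binned"`) is available because the free shuffle has a
known degree bias: hubs accumulate mass under almost any permutation, so
their z-scores are conservative. The free shuffle remains the default as
the plainest reading of a uniformly permuted null.

Permuted propagations are batched (all permutation columns iterate
simultaneously), which is why 1,000 permutations on desk-scale networks
take seconds.

### SNP scoring and mapping

- SNP score `s = −log10(p)`: the standard GWAS signal scale. Effect-size
  columns are accepted by the reader but unused.
- LD weighting: within a block, `s'_i = Σ_j r²_ij s_j / Σ_j r²_ij` over the
  members present. This is a convex combination (bounded by the block's
  score range) and is the identity under an identity r² matrix. Variants
  outside every block keep `s' = s`.
- Mapping: GWAS positions are 1-based, intervals 0-based half-open; a SNP
  at position p overlaps `[start, end)` iff `start ≤ p−1 < end`. Gene
  bodies are padded by `window_bp = 10 kb` (configurable) on both sides;
  regions use their own intervals. Per-node aggregation is **max** over
  assigned SNPs (avoids length bias for wide intervals; `sum`/`mean` are
  options). TF nodes are seeded only via a gene annotation of the same id.

### Marker scores, combination, subnetworks

Cluster marker scores are two-sided rank-sum tests of each gene in-cluster
vs rest on median-total-normalized log1p counts, BH-adjusted within the
cluster; the score is `−log10(p_adj)` for up-regulated genes, else 0,
capped at 300 (the practical limit of float64 p-values). Clusters under 3
cells are excluded. Any non-negative per-gene score can be substituted.

Trait and cluster propagations are combined per node by the **minimum** of
the two z-scores — a node is enriched for the pair only if it is enriched
for both — then thresholded at `z > z_thresh`; connected components of the
surviving nodes (undirected) are reported ranked by mean combined score.
The combined vector may contain negative values; it is a score vector, not
a propagation seed (propagation seeds are validated non-negative).

## ISS-Patcher

Both modalities are subset to the shared panel (sorted gene intersection)
and normalized **separately per modality**: per-cell scaling to the
modality's median panel total, log1p, per-gene z-scoring. Zero-variance
genes become zero columns (tolerance 1e-12 on the log scale) and so
contribute nothing to distances. Euclidean distance on this z-scored log
space is the induced metric; neighbour search is **exact** (blocked
pairwise distances with a stable tie-break by reference cell order), which
is the correctness reference any approximate backend must reproduce on
≥ 99% of cells.

Imputation is the arithmetic mean of the k = 15 neighbours' **raw** counts
— deliberately not re-normalized, so imputed values live on the reference
count scale and always lie within the neighbours' per-gene count range.
Labels transfer by majority vote with confidence = winning fraction; ties
break by smaller summed neighbour distance, then lexicographically, making
the output deterministic.

When the ISS matrix is exactly the panel-restricted reference, k = 1
matching returns each cell itself (distance 0), reproducing labels and raw
counts exactly — the self-mapping identity checked in the tests.

## OrganAxis

Raster convention: origin top-left, x right, y down, pixel (row j, col i)
centred at `((i+0.5), (j+0.5))·pixel_size` µm. The hex grid has rows along
x at the spot spacing (15 µm), alternate rows offset by spacing/2, and row
pitch `spacing·√3/2`, so every nearest-centre distance equals the spacing
exactly.

Label migration takes the pixels whose centres fall within a disc of
radius **spot radius / 4** (1.875 µm for 15-µm spots) around the spot
centre and assigns the **lower median** of the sorted integer labels
(background 0 included) — the lower median guarantees the result is an
actually-occurring label, never an interpolated non-label. If the pixel
size exceeds the disc (coarse rasters), the nearest pixel is used with a
warning. Spots outside the image are background.

Distance features per annotated structure: level 0 uses the mean of the
ten nearest annotated-pixel distances (all pixels when fewer than ten),
level 1 the single nearest distance; both rules are assignable per call.
The axis between an origin and a target structure is
`d_o / (d_o + d_t)`: 0 on the origin, 1 on the target, monotone along the
perpendicular between two parallel structures, and parameter-free. Spots
at distance 0 from both structures get 0.5 with a warning. Visium spots
inherit the nearest grid spot's label/distances/axis when within
`max_dist` (default 15 µm, one grid spacing); farther spots stay
unannotated.

Rigid-motion invariance of the axis holds for motions that preserve the
pixel lattice (multiples of 90° plus whole-pixel translations, applied to
image and grid together); arbitrary-angle rotation of a label raster
resamples the labels and is not a rigid motion of the discrete scene.

## Synthetic generators

All generators are deterministic functions of (spec, seed); the CLI's
`simulate` derives per-stage child seeds from one master seed by fixed
offsets.

- **GRN**: tripartite TF→region→gene edges, preferential attachment for
  background structure, importances in (0.1, 1]. The planted module
  emulates a single eRegulon: one TF bound to every module region, each
  module gene driven by up to three module regions (region:gene ≈ 1:2),
  so the module is densely connected the way a real regulatory program is.
  Default scale: 8 TFs, 60 regions, 120 genes, module of 20.
- **GWAS**: 3 SNPs per gene/region (toy genome: regions on chr1, genes on
  chr2, 200 background SNPs on chr3). Background p ~ U(0,1); SNPs on
  planted nodes p ~ Beta(0.1, 1), the standard stylized enrichment with
  tunable strength. LD blocks: consecutive variants, constant within-block
  r² = 0.5, unit diagonal.
- **Expression**: negative-binomial counts (θ = 10, per-gene means
  U(1, 8)); each of 5 clusters (60 reference / 40 ISS cells) up-regulates
  its 15 markers by fold change 5, and every gene additionally carries a
  per-cluster lognormal factor with log-sd `0.8·ln(fold_change)`, because
  distinct lineages differ transcriptome-wide, not only in curated
  markers. Setting fold change to 1 removes all separation (silhouette
  ≈ 0). The ISS matrix is an independent draw from the same cluster means
  restricted to the 155-gene panel — never a copy of reference cells — so
  recovery tests cannot be trivialized by the self-mapping identity. The
  generator exposes both a noisy held-out count draw and the ground-truth
  per-cell means; imputation quality is measured against the means, since
  correlation against a second noisy draw is bounded by NB sampling noise
  rather than by imputation error.
- **Label image**: non-overlapping bands/discs on an 80×100 px, 1 µm/px
  canvas — two level-1 bands ("suture", "bone") for the axis and a level-0
  disc ("condensation") for mean-of-ten distances. Overlapping shapes are
  rejected so ground truth stays unambiguous.

### What the fixtures do and do not show

The generators produce strongly structured, well-separated data: distinct
cell types, clean LD blocks, noiseless rasters. Passing tests therefore
demonstrate that the algorithms recover structure that is present — exact
solver behaviour, correct geometry, correct neighbour sets, calibrated
permutation p-values — not that real atlas data will yield 100% label
accuracy or near-unity imputation correlations; real transcriptomes
contain many genes with little cell-type information whose imputed values
cannot correlate with truth, real LD is not block-constant, and real
annotations carry boundary noise. Problem sizes (hundreds of nodes and
cells) were chosen so the full suite and the acceptance script run in
seconds; all algorithms are size-agnostic.

## Numerical conventions and edge cases

- Duplicate network edges collapse by summing importance; self-loops and
  dangling endpoints are hard errors, never silently dropped.
- Duplicate GWAS variants keep the smallest p (warned); p outside (0, 1]
  is dropped at read (warned) and rejected at construction.
- `−log10(p)` is capped at 300 where adjusted p-values can underflow.
- Empirical p-values use the add-one estimator, so they are never 0.
- Zero-variance genes: z-score 0 (tolerance 1e-12 on the log scale).
- Median of integer labels: lower median on even counts.
- All file formats are plain text (TSV/CSV/BED/JSON/MTX) except the label
  raster (single-channel PNG with a JSON legend).
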