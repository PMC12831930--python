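# Methods

## The gene-side pipeline

Given a cells×genes count matrix, the pipeline mirrors a conventional
cell-side workflow with the roles of rows and columns swapped:

1. **Normalisation.** Counts are scaled to a common library size
   (`target_sum`, default 10 000) per cell and log1p-transformed. This is
   the ecosystem-standard transform; the gene-side construction assumes
   only that some variance-stabilised layer exists.
2. **z-scores.** Each gene's normalised expression is standardised over
   cells with the population standard deviation; genes constant across all
   cells are mapped to all-zero z-scores rather than NaN. These z-scores
   are the currency of everything downstream (features, landscapes).
3. **Variable-gene selection.** Genes are ranked by variance of
   log-normalised expression (descending, ties broken by gene id so the
   selection is reproducible); the top `n_hvg` (default 2000) enter the
   gene space. A dispersion-standardised criterion can be substituted by
   selecting genes externally and passing the list directly to
   `gene_features`.
4. **Gene features.** The z-score matrix restricted to the selected genes
   is transposed — genes as observations, cells as features — and reduced
   to `n_components` (default 30) principal components. Component signs
   are fixed by making each component's largest-magnitude loading
   positive, so the output is bit-reproducible. By construction this is
   exactly the dual of the cell-side PCA convention, and the test suite
   checks the equivalence against an independent PCA of the transposed
   matrix.
5. **Programme clustering.** An exact Euclidean kNN graph (k = 20) is
   built in feature space, symmetrised (edge if either direction is
   present, unit weights), and partitioned with Louvain modularity
   optimisation at `resolution` (default 1.0). Labels are renumbered by
   decreasing community size with ties broken by smallest member gene id,
   making the labelling invariant to gene input order. Leiden is available
   behind `method="leiden"` when igraph/leidenalg are installed.
6. **Embedding.** UMAP (`n_neighbors=15`, `min_dist=0.1`, fixed
   `random_state`) maps the features to 2-D. A second exact kNN graph with
   k = 20 is then rebuilt *in the 2-D coordinates*; this embedding-space
   graph — not the feature-space one — is what the agreement statistic and
   Moran's I use, because those statistics interrogate the map the analyst
   is looking at.

One integer seed drives the whole run; each stochastic step draws its own
substream via stable hashing of a step name, so adding a step never
perturbs another step's stream.

## Statistics

All Monte-Carlo p-values use the add-one convention
p = (1 + #extreme)/(n_perm + 1): p is never zero and the floor is
1/(n_perm + 1) (0.001 at n_perm = 999), which is also how significance at
"p ≤ 0.001" should be read in any output of this package.

**Median complement distance (mcd).** For gene set S on the embedding,
mcd(S) = median over g ∉ S of min_{s∈S} ‖x_g − x_s‖. The default
("complement") variant treats large observed values as evidence of
clustering (tail greater) against a null of uniformly redrawn sets of the
same intersected size. The mirrored reading — median over members of the
nearest-complement distance, tail less — is exposed as
`variant="member"`; it is calibrated under the null like the default, but
note that a compact set occupying its *own* region of the map makes the
member-side statistic large, not small, so the member variant does not
flag such sets significant. The default variant is therefore the
recommended screen. Collection screens derive an independent RNG
substream per set from (seed, set name), so results do not depend on
collection order, and skip sets whose intersection with the embedded
genes falls below `min_size` (default 5). The collection-level summary is
the exact binomial upper tail P(X ≥ k), X ~ Bin(N, α).

**Overrepresentation.** One-sided hypergeometric upper tail for each gene
cluster × gene set overlap within the embedded-gene universe;
Benjamini–Hochberg q-values are reported alongside raw p across all
pairs.

**Moran's I.** Weights are the symmetrised binary k = 20 embedding kNN
adjacency, row-standardised. The permutation null shuffles the per-gene
values over the fixed graph, tail greater. The analytic null mean
−1/(n−1) is used only as a test-suite cross-check; no normal-approximation
p-values are offered.

**Annotation agreement.** With annotation sets ann(g) (a gene may carry
many), A = Σ over directed kNN edges g→h of |ann(g) ∩ ann(h)|. The null
permutes node identities uniformly over the fixed topology — provably the
same null as shuffling annotation sets across genes (the suite checks the
equivalence seed-by-seed) — preserving degree sequence and annotation
multiset exactly. Directed counting follows from each gene contributing
its k out-neighbours; an undirected variant (each unordered pair once) is
available via `directed=False`. Internally A is computed by gathering the
gene co-annotation matrix B·Bᵀ over the edge list, which makes thousands
of randomisations cheap; the naive triple loop serves as the oracle in
tests. If every gene carries identical annotations the null sd is zero:
the empirical p is still returned and the z-score property raises instead
of dividing by zero.

**Pair-distance tests.** The statistic is the median embedding distance
over the retained pairs (both genes embedded; drops are logged). Nulls
regenerate the pair list: `shuffle` permutes second partners among
themselves (re-drawing any self-pair by local swaps, preserving the
partner multiset), `first_vs_random` keeps the first gene and draws the
partner uniformly, `both_random` draws both uniformly without
replacement, and `random_sets` draws gene sets matching the observed
complex sizes and emits all within-set pairs. The median-of-distances
with a Monte-Carlo null was chosen over a rank-sum test because the null
pair lists are not exchangeable samples from a common population (the
shuffle null, for instance, fixes the ligand multiset); a rank-sum
alternative can be applied to the exported long-format distances if
desired. p is one-sided (tail less: close pairs are the signal). Null
draws may repeat a pair — that is faithful to the resampling scheme —
whereas observed tables read from disk are de-duplicated and self-pairs
dropped.

**Landscapes and the relation table.** z̄_{g,K} is the mean z-score of
gene g over the cells of group K; since z-scores are centred over all
cells, the group-size-weighted sum of a gene's landscape values is zero
(asserted to 1e-8 in tests). The programme → cell-group Sankey weight is
Σ_{g∈G} max(z̄_{g,K}, 0): only above-average expression links a programme
to a group. This clipping is this package's own convention (an unclipped
variant is available via `clip_negative=False`); with signed means a
programme's strong absence in one group would cancel its presence in
another, which is not what a flow diagram should show. Sankey export
writes rows with weight strictly above the threshold (default 0), so
all-zero links never clutter the file.

## The synthetic generator

`simulate()` draws counts from a negative binomial with variance
m + φ·m² (dispersion φ = 0.5 by default, i.e. shape 1/φ = 2), emulating
scRNA-seq overdispersion; a Poisson simulator would understate the noise
the pipeline must tolerate. Defaults: 1200 genes (800 background, 4
programmes × 100 genes), 5 cell types × 80 cells, baseline mean 0.5,
programme genes up-regulated `effect`=4× in the cell types where their
programme is active. Programme 0 is active in two cell types — the
cell-cycle-like programme cutting across types that motivates a gene-side
analysis — while the last programme is additionally boosted
`condition_shift`=2× in cells labelled "infected" (half of each type),
giving the per-condition landscapes something real to show. Cells carry
no library-size heterogeneity, batch structure or ambient RNA, and
programme membership is hard (a gene belongs to exactly one programme);
passing positive controls on these data demonstrates the statistics
recover clean planted structure at realistic overdispersion, not that the
pipeline is robust to the full messiness of real tissue.

Pipeline runs on synthetic data select `n_hvg` = 400 = the number of
programme genes, mirroring the 2000-of-~20 000 selection of a real
analysis: variance selection is itself part of what is being tested,
since programme genes are the variable ones by construction.
Programme-recovery ARI is computed over the clustered (HVG-selected)
genes, excluding genes whose truth is "background": background genes
carry no planted structure, so how a partition slices them is
uninformative; any that leak through HVG selection keep the single truth
label "background" if included via `restrict_to_programmes=False`.

## Numerical and degenerate-input choices

- Matrix Market files are 1-based on disk, 0-based in memory; orientation
  is inferred from the id-file lengths and a square matrix with equally
  many gene and cell ids is rejected as ambiguous rather than guessed.
- kNN search is exact (full distance matrix, stable argsort), with
  distance ties broken by point index; approximate neighbours are out of
  scope at the ~2000-gene scale this targets.
- Zero-total cells normalise to all-zero rows with a warning; constant
  genes z-score to zero; constant landscape values make Moran's I raise
  `UndefinedStatisticError`.
- All floating-point TSV output uses 12 significant digits, "." decimals,
  UTF-8; JSON round-trips are exact for integers and to better than 1e-12
  for floats.

## Known limitations

- UMAP determinism holds for a fixed seed, platform and umap-learn
  version; coordinates are not comparable across versions.
- The Louvain partition at resolution 1.0 fixes the programme granularity;
  exploring resolutions is the user's job (the CLI exposes the knob).
- mcd p-values are conditional on the embedding: they quantify clustering
  *on this map*, not a generative claim about the data, and inherit any
  distortion UMAP introduces.
- Spatial-transcriptomics data and interactive visualisation are out of
  scope; exports are static TSV/PNG.
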