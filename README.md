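# genespace

Gene-side analysis for single-cell (and bulk) expression data.

A standard scRNA-seq workflow treats **cells** as observations described by
the genes they express: cells are normalised, embedded with UMAP and
clustered into cell types. `genespace` exploits the duality hiding in the
same matrix: **transpose it**, so genes become the observations described
by their expression across cells. The identical machinery — PCA, a kNN
graph, Louvain community detection, UMAP — then clusters genes into
co-expression **programmes** and lays them out on a 2-D **gene map**.
Programmes found this way can cut across cell types (a cell-cycle
programme shared by several cycling populations, for example), which a
cell-centric analysis cannot see directly.

The package is for computational biologists who want to ask whether
functional structure is encoded in such a gene map, with permutation
statistics rather than eyeballing:

- **Gene-set colocalisation (mcd).** For a gene set *S* on the map, the
  *median complement distance* is the median over genes *g* ∉ *S* of the
  distance from *g* to its nearest member of *S*. A compact, segregated
  set pushes this up; the null redraws sets of the same size uniformly,
  and p = (1 + #{null ≥ observed}) / (n_perm + 1). An exact binomial test
  P(X ≥ k), X ~ Bin(N, α) summarises how many sets of a collection
  cleared α by chance.
- **Expression landscapes.** Per-gene z-scores (over cells) averaged
  within each cell cluster or condition give a landscape z̄_{g,K} over the
  map; Moran's I on the symmetrised k=20 kNN graph
  (I = (n/ΣW)·Σwᵢⱼ(xᵢ−x̄)(xⱼ−x̄)/Σ(xᵢ−x̄)²) with a value-permutation null
  quantifies its spatial coherence. Landscape differences and a
  programme × cell-type relation (Sankey) table link programmes to the
  cells that run them.
- **Annotation agreement.** The count A of annotations shared across
  neighbouring gene pairs in the kNN graph, against a null that permutes
  node identities over the fixed topology; reported as an empirical p and
  as z = (A − μ_null)/σ_null.
- **Pair-distance tests.** Median map distance between ligand–receptor or
  complex-subunit pairs against shuffled-partner, random-gene and
  random-gene-set nulls (tail: smaller is closer).
- **Cluster enrichment.** Hypergeometric overrepresentation of gene sets
  in gene programmes, with Benjamini–Hochberg correction.

A negative-binomial simulator with planted programmes (one shared by two
cell types, one condition-responsive) provides ground truth for all of the
above, so the whole pipeline is testable without external data.

## Worked example

```python
import genespace as gs

matrix, meta, truth = gs.simulate(seed=1)          # 400 cells x 1200 genes
space = gs.build_gene_space(matrix, n_hvg=400, seed=1)

print("gene programmes found:", space.clustering.n_clusters)
print("recovery ARI: %.3f" % gs.recovery_ari(truth, space.clustering))

sets = gs.truth_gene_sets(truth)
res = gs.mcd_permutation_test(space.embedding, sets["prog_0"], n_perm=999, seed=0)
print("prog_0 mcd=%.2f (null %.2f +/- %.2f)  p=%.3f"
      % (res.observed, res.null_mean, res.null_sd, res.p_value))

ann = gs.build_annotation_map(sets, space.embedding.gene_ids)
agree = gs.agreement_test(space.embedding.knn, ann, n_rand=999, seed=0)
print("agreements: observed=%d  null %.1f +/- %.1f  z=%.2f  p=%.3f"
      % (agree.observed, agree.null_mean, agree.null_sd, agree.z_score, agree.p_value))
```

prints

```
gene programmes found: 4
recovery ARI: 1.000
prog_0 mcd=14.90 (null 0.16 +/- 0.01)  p=0.001
agreements: observed=8000  null 1984.7 +/- 51.9  z=115.99  p=0.001
```

The four planted programmes are recovered exactly (adjusted Rand index
1.0 against truth). Programme 0's genes sit so tightly on the map that the
rest of the genome is pushed to a median distance of 14.9 from the set —
two orders of magnitude above the random-set null — and none of the 999
null draws reaches it, so p lands on its floor of 1/1000. Neighbouring
genes share annotations 8000 times, 116 standard deviations above the
node-permutation null. Moran's I of each cell-type landscape on this map
lies above 0.92, permutation p = 0.001 throughout.

The same steps are available from a shell:

```sh
genespace simulate --seed 1 --out sim/
genespace build --counts sim/counts.mtx --genes sim/genes.tsv \
                --cells sim/cells.tsv --n-hvg 400 --seed 1 --out gs/
genespace mcd-screen --embedding gs/embedding.tsv --gmt sim/truth.gmt \
                     --n-perm 999 --seed 0 --out screen.tsv
```

plus `landscape`, `sankey`, `morans`, `agreement`, `pair-test`,
`complex-test`, `overrep` and `import-modules` (see `genespace --help`).
Real data enters as a Matrix Market counts triplet (or dense TSV), a cell
metadata TSV, GMT gene sets and two-column TSV pair tables.

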