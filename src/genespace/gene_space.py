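"""The gene-side dual of the standard single-cell workflow.

A conventional analysis treats cells as observations described by genes.
Transposing the expression matrix swaps those roles: genes become the
observations, described by their (z-scored) expression across cells. The
same machinery then applies — PCA for features, a kNN graph, Louvain
community detection for gene programmes, and UMAP for a 2-D gene map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .io import ExpressionMatrix
from .seeds import derive_seed

logger = logging.getLogger(__name__)

DEFAULT_TARGET_SUM = 10_000.0
DEFAULT_N_HVG = 2000
DEFAULT_N_COMPONENTS = 30
DEFAULT_K = 20


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class KnnGraph:
    """Directed k-nearest-neighbour graph over named genes.

    `neighbors[i]` holds the indices of the min(k, n−1) nearest genes to
    gene i (self excluded), nearest first, distance ties broken by index.
    """

    gene_ids: list
    neighbors: np.ndarray
    k: int

    def __post_init__(self):
        self.neighbors = np.asarray(self.neighbors, dtype=int)
        n = len(self.gene_ids)
        if self.neighbors.shape != (n, min(self.k, n - 1)):
            raise ValueError("neighbor array shape inconsistent with gene count and k")
        if np.any(self.neighbors == np.arange(n)[:, None]):
            raise ValueError("self-edge in kNN graph")

    @property
    def n_nodes(self) -> int:
        return len(self.gene_ids)

    def edges(self) -> np.ndarray:
        """Directed edge list as an (n·k, 2) array of node indices."""
        n, k = self.neighbors.shape
        src = np.repeat(np.arange(n), k)
        return np.column_stack([src, self.neighbors.ravel()])

    def out_degrees(self) -> np.ndarray:
        return np.full(self.n_nodes, self.neighbors.shape[1])


@dataclass
class GeneEmbedding:
    """2-D gene coordinates plus the kNN graph rebuilt in those coordinates."""

    gene_ids: list
    coords: np.ndarray
    knn: KnnGraph
    k: int

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.gene_ids), 2):
            raise ValueError("coords must be |genes|×2")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite embedding coordinates")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index_of(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.asarray([lookup[g] for g in genes], dtype=int)

    def subset_indices(self, genes) -> np.ndarray:
        """Indices of the embedded genes among `genes`, keeping embedding order."""
        members = set(genes)
        return np.asarray(
            [i for i, g in enumerate(self.gene_ids) if g in members], dtype=int
        )


@dataclass
class GeneClustering:
    """Gene → programme label partition from community detection."""

    labels: dict
    resolution: float
    seed: int

    def __post_init__(self):
        got = sorted(set(self.labels.values()))
        if got != list(range(len(got))):
            raise ValueError("cluster labels must be contiguous integers from 0")

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def members(self, label: int) -> set:
        return {g for g, lab in self.labels.items() if lab == label}

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, name="cluster")


# ---------------------------------------------------------------------------
# normalisation and feature construction
# ---------------------------------------------------------------------------

def normalize(matrix: ExpressionMatrix, target_sum: float = DEFAULT_TARGET_SUM) -> ExpressionMatrix:
    """Library-size normalise to `target_sum` per cell, then log1p.

    Cells with zero total count get an all-zero normalised row and a warning.
    """
    totals = matrix.counts.sum(axis=1)
    zero = totals == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} cell(s) have zero total count", stacklevel=2)
    safe = np.where(zero, 1.0, totals)
    normalized = np.log1p(matrix.counts * (target_sum / safe)[:, None])
    normalized[zero, :] = 0.0
    return matrix.with_layer(normalized=normalized)


def zscore_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-scores of normalised expression over cells (population sd).

    Genes constant across all cells map to all-zero z-scores.
    """
    if matrix.normalized is None:
        raise ValueError("normalized layer required; call normalize() first")
    x = matrix.normalized
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    constant = sd == 0
    safe_sd = np.where(constant, 1.0, sd)
    z = (x - mean) / safe_sd
    z[:, constant] = 0.0
    return matrix.with_layer(zscores=z)


def select_variable_genes(matrix: ExpressionMatrix, n: int = DEFAULT_N_HVG) -> list:
    """Top-`n` genes by variance of normalised expression, ties by gene id."""
    if matrix.normalized is None:
        raise ValueError("normalized layer required; call normalize() first")
    if n > matrix.n_genes:
        raise ValueError(f"n={n} exceeds the {matrix.n_genes} genes available")
    variances = matrix.normalized.var(axis=0)
    order = sorted(range(matrix.n_genes), key=lambda i: (-variances[i], matrix.gene_ids[i]))
    return [matrix.gene_ids[i] for i in order[:n]]


def gene_features(
    matrix: ExpressionMatrix,
    hvg_list,
    n_components: int = DEFAULT_N_COMPONENTS,
) -> np.ndarray:
    """PCA features for genes-as-observations.

    The z-score matrix restricted to `hvg_list` is transposed so genes are
    rows and cells are columns, then reduced to
    d = min(n_components, |hvg|, |cells|) principal components. The sign of
    each component is fixed by making its largest-magnitude loading
    positive, so output is bit-reproducible.
    """
    if matrix.zscores is None:
        raise ValueError("zscores layer required; call zscore_genes() first")
    if len(hvg_list) < 2:
        raise ValueError("need at least 2 genes")
    col = {g: i for i, g in enumerate(matrix.gene_ids)}
    idx = [col[g] for g in hvg_list]
    x = matrix.zscores[:, idx].T  # genes × cells
    d = min(n_components, x.shape[0], x.shape[1])
    pca = PCA(n_components=d, svd_solver="full")
    scores = pca.fit_transform(x)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(d):
        i_max = int(np.argmax(np.abs(pca.components_[j])))
        if pca.components_[j, i_max] < 0:
            scores[:, j] *= -1.0
    return scores


# ---------------------------------------------------------------------------
# kNN graph and clustering
# ---------------------------------------------------------------------------

def build_knn(points: np.ndarray, k: int) -> np.ndarray:
    """Exact Euclidean kNN indices, (n, k); ties broken by index, self excluded."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if k < 1 or k >= n:
        raise ValueError(f"k must satisfy 1 <= k < n; got k={k}, n={n}")
    dist = cdist(points, points)
    np.fill_diagonal(dist, np.inf)
    # stable argsort keeps index order on equal distances
    order = np.argsort(dist, axis=1, kind="stable")
    return order[:, :k]


def knn_graph(gene_ids, points: np.ndarray, k: int) -> KnnGraph:
    k_eff = min(k, len(gene_ids) - 1)
    return KnnGraph(gene_ids=list(gene_ids), neighbors=build_knn(points, k_eff), k=k)


def _symmetrized_nx(graph: KnnGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_nodes))
    g.add_edges_from(map(tuple, graph.edges()))
    return g


def cluster_genes(
    adjacency: KnnGraph,
    resolution: float = 1.0,
    seed: int = 0,
    method: str = "louvain",
) -> GeneClustering:
    """Partition genes into programmes by modularity optimisation.

    The directed kNN graph is symmetrised (edge if either direction is
    present, weight 1) and clustered with Louvain (or Leiden when the
    optional igraph/leidenalg extra is installed). Labels are renumbered by
    decreasing cluster size; deterministic for a fixed seed.
    """
    if adjacency.n_nodes == 0:
        raise ValueError("empty graph")
    g = _symmetrized_nx(adjacency)
    if method == "louvain":
        communities = nx.community.louvain_communities(
            g, resolution=resolution, seed=seed
        )
    elif method == "leiden":
        import igraph
        import leidenalg

        ig = igraph.Graph(n=g.number_of_nodes(), edges=list(g.edges()))
        part = leidenalg.find_partition(
            ig,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
        )
        communities = [set(c) for c in part]
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    # renumber by decreasing size; ties by smallest gene id, so the labelling
    # does not depend on the order genes were fed in
    communities = sorted(
        communities,
        key=lambda c: (-len(c), min(adjacency.gene_ids[i] for i in c)),
    )
    labels = {}
    for lab, comm in enumerate(communities):
        for node in comm:
            labels[adjacency.gene_ids[node]] = lab
    return GeneClustering(labels=labels, resolution=resolution, seed=seed)


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def embed_genes(
    features: np.ndarray,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    gene_ids=None,
    knn_k: int = DEFAULT_K,
) -> GeneEmbedding:
    """UMAP the gene feature matrix to 2-D and rebuild a kNN graph there.

    The kNN graph attached to the embedding is computed from the 2-D
    coordinates with k = min(knn_k, n−1); it is the graph used by the
    annotation-agreement and Moran's I machinery downstream.
    """
    import umap

    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise ValueError("non-finite feature values")
    n = features.shape[0]
    if n < 4:
        raise ValueError("need at least 4 genes to embed")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, n - 1),
        min_dist=min_dist,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", module="sklearn")
        coords = np.asarray(reducer.fit_transform(features), dtype=float)
    graph = knn_graph(gene_ids, coords, knn_k)
    return GeneEmbedding(gene_ids=list(gene_ids), coords=coords, knn=graph, k=knn_k)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class GeneSpaceResult:
    """Everything the gene-side pipeline produces, in one bundle."""

    hvg: list
    features: np.ndarray
    feature_knn: KnnGraph
    clustering: GeneClustering
    embedding: GeneEmbedding
    matrix: ExpressionMatrix = field(repr=False, default=None)


def build_gene_space(
    matrix: ExpressionMatrix,
    n_hvg: int = DEFAULT_N_HVG,
    n_components: int = DEFAULT_N_COMPONENTS,
    k: int = DEFAULT_K,
    resolution: float = 1.0,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    target_sum: float = DEFAULT_TARGET_SUM,
    method: str = "louvain",
) -> GeneSpaceResult:
    """Run the full gene-side pipeline from raw counts.

    normalise → z-score → select HVGs → PCA on the transposed matrix →
    kNN in feature space → Louvain programmes → UMAP embedding (with its
    own kNN in 2-D coordinates). One root seed drives named substreams for
    the stochastic steps.
    """
    if matrix.normalized is None:
        matrix = normalize(matrix, target_sum=target_sum)
    if matrix.zscores is None:
        matrix = zscore_genes(matrix)
    n_hvg = min(n_hvg, matrix.n_genes)
    hvg = select_variable_genes(matrix, n=n_hvg)
    features = gene_features(matrix, hvg, n_components=n_components)
    feature_knn = knn_graph(hvg, features, k)
    clustering = cluster_genes(
        feature_knn, resolution=resolution, seed=derive_seed(seed, "cluster"), method=method
    )
    embedding = embed_genes(
        features,
        seed=derive_seed(seed, "umap"),
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        gene_ids=hvg,
        knn_k=k,
    )
    return GeneSpaceResult(
        hvg=hvg,
        features=features,
        feature_knn=feature_knn,
        clustering=clustering,
        embedding=embedding,
        matrix=matrix,
    )


# ---------------------------------------------------------------------------
# TSV round-trips for embedding/clustering artefacts
# ---------------------------------------------------------------------------

def write_embedding_tsv(embedding: GeneEmbedding, path) -> None:
    frame = pd.DataFrame(
        {"gene": embedding.gene_ids,
         "x": embedding.coords[:, 0],
         "y": embedding.coords[:, 1]}
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_embedding_tsv(path, k: int = DEFAULT_K) -> GeneEmbedding:
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str})
    gene_ids = list(frame["gene"])
    coords = frame[["x", "y"]].to_numpy(dtype=float)
    return GeneEmbedding(
        gene_ids=gene_ids, coords=coords, knn=knn_graph(gene_ids, coords, k), k=k
    )


def write_clustering_tsv(clustering: GeneClustering, path) -> None:
    frame = pd.DataFrame(
        {"gene": list(clustering.labels), "cluster": list(clustering.labels.values())}
    )
    frame.to_csv(path, sep="\t", index=False)


def clustering_from_assignments(assignments: dict) -> GeneClustering:
    """Normalise arbitrary gene → module labels into a GeneClustering.

    External tools emit string or sparse module labels; these are remapped
    to contiguous integers ordered by decreasing module size (ties by
    label) so downstream scoring and plotting treat them like native
    programmes.
    """
    if not assignments:
        raise ValueError("empty module assignment")
    sizes: dict = {}
    for lab in assignments.values():
        sizes[lab] = sizes.get(lab, 0) + 1
    order = sorted(sizes, key=lambda lab: (-sizes[lab], str(lab)))
    remap = {lab: i for i, lab in enumerate(order)}
    labels = {g: remap[lab] for g, lab in assignments.items()}
    return GeneClustering(labels=labels, resolution=float("nan"), seed=-1)


def read_clustering_tsv(path, resolution: float = float("nan"), seed: int = -1) -> GeneClustering:
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str, "cluster": int})
    labels = dict(zip(frame["gene"], frame["cluster"]))
    return GeneClustering(labels=labels, resolution=resolution, seed=seed)


def write_graph_tsv(graph: KnnGraph, path) -> None:
    """Directed edge list TSV: source gene, target gene."""
    edges = graph.edges()
    ids = np.asarray(graph.gene_ids, dtype=object)
    frame = pd.DataFrame({"source": ids[edges[:, 0]], "target": ids[edges[:, 1]]})
    frame.to_csv(path, sep="\t", index=False)
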