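"""Geometric clustering statistics on the gene embedding.

A gene set whose members huddle together on the 2-D gene map pushes most
other genes far from the set: the median, over genes outside the set, of
the distance to the nearest set member (the median complement distance,
mcd) is then large relative to what a random subset of the same size
achieves. A permutation test against such random subsets yields a p-value
per gene set; an exact binomial test summarises a whole collection; a
hypergeometric test relates gene sets to gene clusters; and Moran's I with
a permutation null measures the spatial autocorrelation of any per-gene
value (e.g. a mean z-score landscape) on the embedding's kNN graph.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.spatial.distance import cdist
from scipy.stats import binom, hypergeom
from statsmodels.stats.multitest import multipletests

from .exceptions import UndefinedStatisticError
from .gene_space import GeneEmbedding, GeneClustering
from .results import PermTestResult, permutation_result
from .seeds import derive_seed

DEFAULT_N_PERM = 1000
DEFAULT_MIN_SET_SIZE = 5


# ---------------------------------------------------------------------------
# median complement distance
# ---------------------------------------------------------------------------

def _member_indices(embedding: GeneEmbedding, gene_set) -> np.ndarray:
    idx = embedding.subset_indices(gene_set)
    if idx.size == 0:
        raise ValueError("gene set has empty intersection with embedded genes")
    if idx.size == embedding.n_genes:
        raise ValueError("gene set covers all embedded genes; complement is empty")
    return idx


def _mcd_from_indices(coords: np.ndarray, member_idx: np.ndarray) -> float:
    mask = np.zeros(coords.shape[0], dtype=bool)
    mask[member_idx] = True
    nearest = cdist(coords[~mask], coords[mask]).min(axis=1)
    return float(np.median(nearest))


def median_complement_distance(embedding: GeneEmbedding, gene_set) -> float:
    """Median over non-members of the distance to the nearest set member.

    Variant "member" instead takes the median over members of the distance
    to the nearest non-member; see :func:`mcd_permutation_test`.
    """
    return _mcd_from_indices(embedding.coords, _member_indices(embedding, gene_set))


def _mcd_member_variant(coords: np.ndarray, member_idx: np.ndarray) -> float:
    mask = np.zeros(coords.shape[0], dtype=bool)
    mask[member_idx] = True
    nearest = cdist(coords[mask], coords[~mask]).min(axis=1)
    return float(np.median(nearest))


def mcd_permutation_test(
    embedding: GeneEmbedding,
    gene_set,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    variant: str = "complement",
    keep_null: bool = False,
) -> PermTestResult:
    """Permutation test for geometric clustering of a gene set.

    The null draws uniform gene subsets of the same (intersected) size.
    For the default "complement" variant a tightly clustered set makes the
    complement-to-set distances large, so the tail is `greater`; the
    "member" variant (median over members of nearest-complement distance)
    shrinks under clustering, so its tail is `less`.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    member_idx = _member_indices(embedding, gene_set)
    if variant == "complement":
        stat, tail = _mcd_from_indices, "greater"
    elif variant == "member":
        stat, tail = _mcd_member_variant, "less"
    else:
        raise ValueError(f"unknown mcd variant {variant!r}")
    observed = stat(embedding.coords, member_idx)
    rng = np.random.default_rng(seed)
    n, m = embedding.n_genes, member_idx.size
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = stat(embedding.coords, rng.choice(n, size=m, replace=False))
    return permutation_result(
        f"mcd_{variant}", observed, null, tail=tail, seed=seed, keep_null=keep_null
    )


def screen_gene_sets(
    embedding: GeneEmbedding,
    collection,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    variant: str = "complement",
) -> pd.DataFrame:
    """mcd permutation test for every set in a collection.

    Sets are first intersected with the embedded genes; sets smaller than
    `min_size` (or lacking a complement) are kept in the table with a
    `skip_reason` and no p-value. Each retained set gets an independent RNG
    substream derived from (seed, set name), so the table is reproducible
    and order-independent.
    """
    embedded = set(embedding.gene_ids)
    rows = []
    for name, members in collection.items():
        inter = len(embedded & set(members))
        row = {"set": name, "size": inter, "mcd": np.nan, "p_value": np.nan,
               "skip_reason": ""}
        if inter < min_size:
            row["skip_reason"] = f"intersection {inter} < min_size {min_size}"
        elif inter == embedding.n_genes:
            row["skip_reason"] = "set covers all embedded genes"
        else:
            res = mcd_permutation_test(
                embedding, members, n_perm=n_perm,
                seed=derive_seed(seed, "mcd", name), variant=variant,
            )
            row["mcd"] = res.observed
            row["p_value"] = res.p_value
        rows.append(row)
    return pd.DataFrame(rows)


def binomial_meta_test(n_significant: int, n_total: int, alpha: float = 0.05) -> float:
    """Exact upper-tail binomial P(X ≥ n_significant), X ~ Bin(n_total, alpha).

    Used to ask whether more gene sets reached p ≤ alpha in a screen than
    chance alone would produce.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 <= n_significant <= n_total:
        raise ValueError("need 0 <= n_significant <= n_total")
    return float(binom.sf(n_significant - 1, n_total, alpha))


# ---------------------------------------------------------------------------
# overrepresentation of gene sets in gene clusters
# ---------------------------------------------------------------------------

def overrepresentation_test(cluster_genes, gene_set, universe) -> float:
    """Upper-tail hypergeometric p for the overlap of a cluster and a gene set."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    cluster = set(cluster_genes)
    if not cluster <= universe:
        raise ValueError("cluster genes must be a subset of the universe")
    members = set(gene_set) & universe
    overlap = len(cluster & members)
    return float(hypergeom.sf(overlap - 1, len(universe), len(members), len(cluster)))


def overrepresentation_table(
    clustering: GeneClustering, collection, universe=None
) -> pd.DataFrame:
    """Hypergeometric p for every cluster × set pair, with Benjamini–Hochberg q."""
    if universe is None:
        universe = set(clustering.labels)
    rows = []
    for label in range(clustering.n_clusters):
        cluster = clustering.members(label) & set(universe)
        for name, members in collection.items():
            inter = set(members) & set(universe)
            rows.append({
                "cluster": label,
                "set": name,
                "cluster_size": len(cluster),
                "set_size": len(inter),
                "overlap": len(cluster & inter),
                "p_value": overrepresentation_test(cluster, members, universe),
            })
    table = pd.DataFrame(rows)
    if len(table):
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

def embedding_weights(embedding: GeneEmbedding) -> scipy.sparse.csr_matrix:
    """Row-standardised symmetric binary weights from the embedding kNN graph."""
    edges = embedding.knn.edges()
    n = embedding.n_genes
    a = scipy.sparse.coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    ).tocsr()
    sym = ((a + a.T) > 0).astype(float)
    deg = np.asarray(sym.sum(axis=1)).ravel()
    inv = scipy.sparse.diags(np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0))
    return (inv @ sym).tocsr()


def morans_i_from_weights(values: np.ndarray, weights: scipy.sparse.spmatrix) -> float:
    """Classical Moran's I: (n/ΣW)·(Σ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄))/(Σ(xᵢ−x̄)²)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("Moran's I undefined for constant values")
    xc = x - x.mean()
    w_sum = weights.sum()
    return float((n / w_sum) * (xc @ (weights @ xc)) / (xc @ xc))


def morans_i(embedding: GeneEmbedding, values: np.ndarray) -> float:
    """Moran's I of per-gene values on the embedding's kNN weight graph."""
    values = np.asarray(values, dtype=float)
    if values.size != embedding.n_genes:
        raise ValueError("values must align with embedded genes")
    return morans_i_from_weights(values, embedding_weights(embedding))


def morans_i_permutation_test(
    embedding: GeneEmbedding,
    values: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    keep_null: bool = False,
) -> PermTestResult:
    """Permutation test for positive spatial autocorrelation (tail greater).

    The null permutes the values across genes, keeping the graph fixed;
    with n_perm = 999 the smallest reportable p is 0.001.
    """
    values = np.asarray(values, dtype=float)
    if values.size != embedding.n_genes:
        raise ValueError("values must align with embedded genes")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    weights = embedding_weights(embedding)
    observed = morans_i_from_weights(values, weights)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = morans_i_from_weights(rng.permutation(values), weights)
    return permutation_result(
        "morans_i", observed, null, tail="greater", seed=seed, keep_null=keep_null
    )
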