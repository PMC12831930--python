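"""Shared fixtures.

The full synthetic pipeline (simulate → normalise → z-score → HVG → PCA →
kNN → Louvain → UMAP) is expensive enough to share: it is built once per
seed and cached for the whole session. Small deterministic embeddings for
unit tests are built directly from coordinates, bypassing UMAP.
"""

from __future__ import annotations

import numpy as np
import pytest

import genespace as gs


def embedding_from_coords(coords, k: int = 20, gene_ids=None) -> gs.GeneEmbedding:
    """A GeneEmbedding over given 2-D coordinates (no UMAP involved)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    return gs.GeneEmbedding(
        gene_ids=list(gene_ids),
        coords=coords,
        knn=gs.knn_graph(gene_ids, coords, k),
        k=k,
    )


@pytest.fixture(scope="session")
def pipeline_cache():
    """seed -> (matrix, meta, truth, GeneSpaceResult), built on demand."""
    cache = {}

    def get(seed: int):
        if seed not in cache:
            matrix, meta, truth = gs.simulate(seed=seed)
            space = gs.build_gene_space(matrix, n_hvg=400, seed=seed)
            cache[seed] = (matrix, meta, truth, space)
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def planted(pipeline_cache):
    """The seed-1 planted-programme dataset and its fitted gene space."""
    return pipeline_cache(1)


@pytest.fixture(scope="session")
def uniform_embedding():
    """300 genes scattered uniformly: a structureless null gene map."""
    rng = np.random.default_rng(0)
    return embedding_from_coords(rng.uniform(0, 10, size=(300, 2)))
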