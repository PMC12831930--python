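"""Embedding-distance tests for related gene pairs.

Ligand–receptor partners, or genes encoding subunits of the same protein
complex, should sit close on the gene map if the map encodes function.
The test statistic is the median embedding distance over the observed
pairs, compared with Monte-Carlo nulls that regenerate the pair list:

- ``shuffle``        : permute the second partners among themselves
- ``first_vs_random``: keep the first gene, draw the partner uniformly
- ``both_random``    : draw both genes uniformly (distinct) per pair
- ``random_sets``    : draw gene sets matching the complex sizes and take
                       all within-set pairs (complex test only)

Small observed medians are evidence of colocalisation (tail less).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gene_space import GeneEmbedding
from .io import PairTable, make_pair_table
from .results import perm_p_value
from .seeds import derive_seed

logger = logging.getLogger(__name__)

NULL_MODELS = ("shuffle", "first_vs_random", "both_random", "random_sets")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def restrict_pairs(embedding: GeneEmbedding, pairs: PairTable) -> PairTable:
    """Keep only pairs with both genes embedded; log what was dropped."""
    embedded = set(embedding.gene_ids)
    kept = [(a, b) for a, b in pairs.pairs if a in embedded and b in embedded]
    n_dropped = len(pairs.pairs) - len(kept)
    if n_dropped:
        logger.info("dropped %d pair(s) with unembedded genes", n_dropped)
    return PairTable(kept, role_a=pairs.role_a, role_b=pairs.role_b,
                     n_dropped_self=pairs.n_dropped_self, strict=pairs.strict)


def pair_distances(embedding: GeneEmbedding, pairs: PairTable) -> np.ndarray:
    """Euclidean embedding distance per pair (pairs must be embedded)."""
    retained = restrict_pairs(embedding, pairs)
    if len(retained) == 0:
        raise ValueError("no pair has both genes in the embedding")
    ia = embedding.index_of([a for a, _ in retained.pairs])
    ib = embedding.index_of([b for _, b in retained.pairs])
    return np.linalg.norm(embedding.coords[ia] - embedding.coords[ib], axis=1)


# ---------------------------------------------------------------------------
# null pair generators
# ---------------------------------------------------------------------------

def null_shuffle_partner(pairs: PairTable, embedding: GeneEmbedding,
                         seed: int) -> PairTable:
    """Permute second partners among themselves; self-pairs are re-drawn.

    The multiset of second partners is preserved exactly.
    """
    firsts = [a for a, _ in pairs.pairs]
    seconds = np.asarray([b for _, b in pairs.pairs], dtype=object)
    rng = np.random.default_rng(seed)
    shuffled = seconds[rng.permutation(len(seconds))]
    for _ in range(1000):
        bad = np.flatnonzero(np.asarray(firsts, dtype=object) == shuffled)
        if bad.size == 0:
            break
        # swap each offending slot's partner with a random other slot
        for i in bad:
            j = int(rng.integers(len(shuffled)))
            shuffled[i], shuffled[j] = shuffled[j], shuffled[i]
    else:
        raise RuntimeError("could not avoid self-pairs while shuffling partners")
    return PairTable(list(zip(firsts, shuffled)), role_a=pairs.role_a,
                     role_b=f"shuffled_{pairs.role_b}", strict=False)


def null_random_gene(pairs: PairTable, embedding: GeneEmbedding, seed: int,
                     mode: str = "both_random") -> PairTable:
    """Random-gene nulls; see module docstring for the two modes."""
    rng = np.random.default_rng(seed)
    genes = np.asarray(embedding.gene_ids, dtype=object)
    n = len(genes)
    out = []
    if mode == "first_vs_random":
        for a, _ in pairs.pairs:
            b = genes[int(rng.integers(n))]
            while b == a:
                b = genes[int(rng.integers(n))]
            out.append((a, str(b)))
    elif mode == "both_random":
        for _ in pairs.pairs:
            i, j = rng.choice(n, size=2, replace=False)
            out.append((str(genes[i]), str(genes[j])))
    else:
        raise ValueError(f"unknown random-gene mode {mode!r}")
    return PairTable(out, role_a="random_a", role_b="random_b", strict=False)


def null_random_sets(complex_sizes, embedding: GeneEmbedding, seed: int) -> PairTable:
    """All within-set pairs of uniformly drawn gene sets of the given sizes."""
    sizes = [int(s) for s in complex_sizes]
    if any(s < 2 for s in sizes):
        raise ValueError("complex sizes must be >= 2")
    rng = np.random.default_rng(seed)
    genes = np.asarray(embedding.gene_ids, dtype=object)
    out = []
    for s in sizes:
        chosen = genes[rng.choice(len(genes), size=s, replace=False)]
        for i in range(s):
            for j in range(i + 1, s):
                out.append((str(chosen[i]), str(chosen[j])))
    # C(s,2) pairs per set; duplicates across independently drawn sets are kept
    return PairTable(out, role_a="set_member_a", role_b="set_member_b",
                     strict=False)


def expand_complexes(complexes: dict, universe=None):
    """Within-complex unordered pairs, de-duplicated across complexes.

    `universe` (e.g. the embedded genes) restricts each complex first;
    complexes reduced below 2 members are skipped with a log message.
    Returns (PairTable, list of surviving complex sizes) — the sizes feed
    the ``random_sets`` null.
    """
    out, sizes = [], []
    for name, members in complexes.items():
        members = set(members) if universe is None else set(members) & set(universe)
        if len(members) < 2:
            logger.info("complex %s skipped: fewer than 2 members in universe", name)
            continue
        ordered = sorted(members)
        sizes.append(len(ordered))
        for i in range(len(ordered)):
            for j in range(i + 1, len(ordered)):
                out.append((ordered[i], ordered[j]))
    table = make_pair_table(out, role_a="subunit_a", role_b="subunit_b")
    return table, sizes


# ---------------------------------------------------------------------------
# the test
# ---------------------------------------------------------------------------

@dataclass
class PairDistanceReport:
    """Observed pair distances and their comparison with each null model."""

    observed: np.ndarray
    statistic: float  # median observed distance
    null_medians: dict  # null model name -> array of null medians
    p_values: dict  # null model name -> add-one p (tail less)
    pooled_null: dict = field(repr=False, default=None)  # name -> pooled distances
    n_rand: int = 0
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def violin_frame(self) -> pd.DataFrame:
        """Long-format (group, distance) table for violin-style plots."""
        rows = [("observed", float(d)) for d in self.observed]
        for name, dists in (self.pooled_null or {}).items():
            rows.extend((name, float(d)) for d in dists)
        return pd.DataFrame(rows, columns=["group", "distance"])

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "n_pairs": int(len(self.observed)),
            "n_rand": int(self.n_rand),
            "seed": int(self.seed),
            "p_values": {k: float(v) for k, v in self.p_values.items()},
            "null_median_means": {
                k: float(np.mean(v)) for k, v in self.null_medians.items()
            },
            "meta": self.meta,
        }


def pair_distance_test(
    embedding: GeneEmbedding,
    pairs: PairTable,
    null_models=("shuffle", "both_random"),
    n_rand: int = 1000,
    seed: int = 0,
    complex_sizes=None,
    random_mode: str = "both_random",
    keep_pooled: bool = True,
) -> PairDistanceReport:
    """Median pair distance against the requested null models.

    For each null model the pair list is regenerated `n_rand` times and the
    null medians collected; p = (1 + #{null median ≤ observed})/(n_rand+1).
    `complex_sizes` is required when "random_sets" is requested.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    retained = restrict_pairs(embedding, pairs)
    observed = pair_distances(embedding, retained)
    statistic = float(np.median(observed))

    def generate(model: str, draw_seed: int) -> PairTable:
        if model == "shuffle":
            return null_shuffle_partner(retained, embedding, draw_seed)
        if model in ("first_vs_random", "both_random"):
            return null_random_gene(retained, embedding, draw_seed, mode=model)
        if model == "random_sets":
            if complex_sizes is None:
                raise ValueError("random_sets null needs complex_sizes")
            return null_random_sets(complex_sizes, embedding, draw_seed)
        raise ValueError(f"unknown null model {model!r}; choose from {NULL_MODELS}")

    null_medians, p_values, pooled = {}, {}, {}
    for model in null_models:
        medians = np.empty(n_rand)
        pool = []
        for r in range(n_rand):
            null_pairs = generate(model, derive_seed(seed, "pairs", model, r))
            d = pair_distances(embedding, null_pairs)
            medians[r] = np.median(d)
            if keep_pooled and r < 50:  # enough for a violin, bounded memory
                pool.append(d)
        null_medians[model] = medians
        p_values[model] = perm_p_value(statistic, medians, tail="less")
        if keep_pooled:
            pooled[model] = np.concatenate(pool)
    meta = {"null_models": list(null_models), "random_mode": random_mode}
    if complex_sizes is not None:
        meta["complex_sizes"] = [int(s) for s in complex_sizes]
    return PairDistanceReport(
        observed=observed,
        statistic=statistic,
        null_medians=null_medians,
        p_values=p_values,
        pooled_null=pooled if keep_pooled else None,
        n_rand=n_rand,
        seed=seed,
        meta=meta,
    )
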