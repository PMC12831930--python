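"""Synthetic count data with planted gene programmes.

The generator emulates the structure the method targets: a cells×genes
negative-binomial count matrix in which blocks of genes (programmes) are
jointly up-regulated in particular cell types, one programme is shared by
two cell types (a cell-cycle-like programme cutting across types), and one
programme responds to an experimental condition. Ground truth is recorded
so planted structure can be scored after the full pipeline.

Counts are NB with mean m and variance m + dispersion·m², i.e. shape
r = 1/dispersion. The mean is base_mean, multiplied by `effect` where the
gene's programme is active in the cell's type, and by `condition_shift`
for the condition-responsive programme in "infected" cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CellMetadata, ExpressionMatrix, PairTable
from .seeds import derive_seed

BACKGROUND = "background"
CONDITIONS = ("control", "infected")


@dataclass
class SimTruth:
    """Ground truth of a simulation: labels, activity map and parameters."""

    gene_programme: dict  # gene id -> programme label or "background"
    cell_type: dict  # cell id -> cell type label
    celltype_programmes: dict  # cell type -> set of active programme labels
    condition: dict  # cell id -> condition label
    condition_programme: str  # programme boosted in "infected" cells
    params: dict
    seed: int

    def programme_members(self, programme: str) -> set:
        return {g for g, p in self.gene_programme.items() if p == programme}

    @property
    def programmes(self) -> list:
        return sorted({p for p in self.gene_programme.values() if p != BACKGROUND})


def _activity_map(n_programmes: int, n_celltypes: int) -> dict:
    """Programme → cell types; programme 0 spans two types (cell-cycle-like)."""
    if n_celltypes < 2:
        raise ValueError("need at least 2 cell types")
    active = {f"type_{t}": set() for t in range(n_celltypes)}
    active["type_0"].add("prog_0")
    active["type_1"].add("prog_0")
    for p in range(1, n_programmes):
        t = (p + 1) % n_celltypes
        active[f"type_{t}"].add(f"prog_{p}")
    return active


def simulate(
    n_genes: int = 1200,
    n_background: int = 800,
    n_programmes: int = 4,
    genes_per_programme: int = 100,
    n_celltypes: int = 5,
    cells_per_type: int = 80,
    base_mean: float = 0.5,
    effect: float = 4.0,
    dispersion: float = 0.5,
    condition_shift: float = 2.0,
    seed: int = 0,
):
    """Draw a planted-programme dataset.

    Returns (ExpressionMatrix, CellMetadata, SimTruth); deterministic for a
    fixed seed.
    """
    if n_background + n_programmes * genes_per_programme != n_genes:
        raise ValueError(
            "n_background + n_programmes*genes_per_programme must equal n_genes"
        )
    for name, value in [("base_mean", base_mean), ("effect", effect),
                        ("dispersion", dispersion),
                        ("condition_shift", condition_shift)]:
        if value <= 0:
            raise ValueError(f"{name} must be positive")

    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    gene_programme = {}
    for i, g in enumerate(gene_ids):
        if i < n_programmes * genes_per_programme:
            gene_programme[g] = f"prog_{i // genes_per_programme}"
        else:
            gene_programme[g] = BACKGROUND

    cell_ids, cell_type, condition = [], {}, {}
    for t in range(n_celltypes):
        for j in range(cells_per_type):
            c = f"cell_{t * cells_per_type + j:04d}"
            cell_ids.append(c)
            cell_type[c] = f"type_{t}"
            condition[c] = CONDITIONS[j % 2]

    activity = _activity_map(n_programmes, n_celltypes)
    condition_programme = f"prog_{n_programmes - 1}"

    means = np.empty((len(cell_ids), n_genes))
    prog_of_gene = np.asarray([gene_programme[g] for g in gene_ids], dtype=object)
    for ci, c in enumerate(cell_ids):
        active = activity[cell_type[c]]
        row = np.full(n_genes, base_mean)
        is_active = np.isin(prog_of_gene, sorted(active))
        row[is_active] *= effect
        if condition[c] == "infected":
            row[prog_of_gene == condition_programme] *= condition_shift
        means[ci] = row

    rng = np.random.default_rng(derive_seed(seed, "counts"))
    r = 1.0 / dispersion  # NB shape; var = m + dispersion*m^2
    counts = rng.negative_binomial(r, r / (r + means)).astype(float)

    matrix = ExpressionMatrix(cell_ids=cell_ids, gene_ids=gene_ids, counts=counts)
    meta = CellMetadata(
        cell_ids=cell_ids,
        cell_cluster=[cell_type[c] for c in cell_ids],
        condition=[condition[c] for c in cell_ids],
    )
    truth = SimTruth(
        gene_programme=gene_programme,
        cell_type=cell_type,
        celltype_programmes=activity,
        condition=condition,
        condition_programme=condition_programme,
        params={
            "n_genes": n_genes, "n_background": n_background,
            "n_programmes": n_programmes,
            "genes_per_programme": genes_per_programme,
            "n_celltypes": n_celltypes, "cells_per_type": cells_per_type,
            "base_mean": base_mean, "effect": effect,
            "dispersion": dispersion, "condition_shift": condition_shift,
        },
        seed=seed,
    )
    return matrix, meta, truth


def truth_gene_sets(truth: SimTruth) -> dict:
    """One gene set per planted programme (background excluded)."""
    return {p: truth.programme_members(p) for p in truth.programmes}


def truth_pairs(truth: SimTruth, n_pairs: int, seed: int = 0) -> PairTable:
    """Random within-programme gene pairs — positive controls for pair tests."""
    rng = np.random.default_rng(derive_seed(seed, "truth_pairs"))
    programmes = truth.programmes
    members = {p: sorted(truth.programme_members(p)) for p in programmes}
    pairs = []
    seen = set()
    guard = 0
    while len(pairs) < n_pairs:
        guard += 1
        if guard > 100 * n_pairs:
            raise ValueError("cannot draw enough distinct within-programme pairs")
        p = programmes[int(rng.integers(len(programmes)))]
        i, j = rng.choice(len(members[p]), size=2, replace=False)
        pair = (members[p][i], members[p][j])
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
    return PairTable(pairs, role_a="partner_a", role_b="partner_b")


def recovery_ari(truth: SimTruth, clustering, restrict_to_programmes: bool = True):
    """Adjusted Rand index between inferred gene clusters and planted truth.

    Scored over the genes the clustering covers (the HVG-selected genes
    that entered the gene space). By default genes whose truth is
    "background" are excluded — they carry no planted structure, so their
    partition is arbitrary; pass `restrict_to_programmes=False` to score
    them as one truth class.
    """
    from sklearn.metrics import adjusted_rand_score

    genes = [
        g for g in clustering.labels
        if not restrict_to_programmes or truth.gene_programme[g] != BACKGROUND
    ]
    if not genes:
        raise ValueError("no scorable genes in clustering")
    true_labels = [truth.gene_programme[g] for g in genes]
    pred_labels = [clustering.labels[g] for g in genes]
    return float(adjusted_rand_score(true_labels, pred_labels))
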