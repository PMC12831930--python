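"""Per-group expression landscapes over the gene embedding.

A landscape assigns each gene the mean of its z-scored expression over the
cells of one group (a cell cluster or an experimental condition). Painted
onto the gene map, landscapes show which regions of gene space a cell type
or condition switches on; differencing two landscapes localises what
distinguishes them, and summing a landscape's positive part within each
gene programme yields the programme ↔ cell-type relation (Sankey) table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_space import GeneClustering, GeneEmbedding
from .io import CellMetadata, ExpressionMatrix

GROUP_BY_CHOICES = ("cell_cluster", "condition")


@dataclass
class GroupLandscape:
    """Mean per-gene z-score for each cell group; genes × groups."""

    group_by: str
    groups: list
    gene_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.groups)):
            raise ValueError("values must be |genes|×|groups|")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite landscape values")

    def column(self, group) -> np.ndarray:
        try:
            j = self.groups.index(group)
        except ValueError:
            raise ValueError(f"group {group!r} not in landscape") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene"), columns=self.groups
        )


def group_landscape(
    matrix: ExpressionMatrix, meta: CellMetadata, group_by: str = "cell_cluster",
    gene_ids=None,
) -> GroupLandscape:
    """Mean z-score per gene within each cell group.

    `gene_ids` restricts and orders the genes (typically to the embedded
    HVGs); default is every gene in the matrix. Groups are sorted
    lexicographically; empty groups cannot arise since groups are read off
    the cells present.
    """
    if group_by not in GROUP_BY_CHOICES:
        raise ValueError(f"group_by must be one of {GROUP_BY_CHOICES}")
    if matrix.zscores is None:
        raise ValueError("zscores layer required; call zscore_genes() first")
    labels = meta.labels_for(matrix.cell_ids, group_by)
    groups = sorted(set(labels))
    if gene_ids is None:
        gene_ids = list(matrix.gene_ids)
    col = {g: i for i, g in enumerate(matrix.gene_ids)}
    gidx = [col[g] for g in gene_ids]
    z = matrix.zscores[:, gidx]
    values = np.column_stack([z[labels == g].mean(axis=0) for g in groups])
    return GroupLandscape(
        group_by=group_by, groups=groups, gene_ids=list(gene_ids), values=values
    )


def landscape_difference(l: GroupLandscape, group_a, group_b) -> np.ndarray:
    """Per-gene |mean z(group_a) − mean z(group_b)|."""
    return np.abs(l.column(group_a) - l.column(group_b))


def relation_table(
    l: GroupLandscape, clustering: GeneClustering, clip_negative: bool = True
) -> pd.DataFrame:
    """Gene-cluster × cell-group weights for a Sankey diagram.

    weight(G, K) = Σ over genes g in cluster G of max(z̄_{g,K}, 0): only
    above-average expression links a programme to a group. Set
    `clip_negative=False` to sum the raw means instead.
    """
    missing = [g for g in l.gene_ids if g not in clustering.labels]
    if missing:
        raise ValueError(f"{len(missing)} landscape genes lack a cluster label")
    vals = np.maximum(l.values, 0.0) if clip_negative else l.values
    labels = np.asarray([clustering.labels[g] for g in l.gene_ids])
    rows = sorted(set(labels))
    weights = np.vstack([vals[labels == lab].sum(axis=0) for lab in rows])
    return pd.DataFrame(weights, index=pd.Index(rows, name="gene_cluster"),
                        columns=l.groups)


def export_sankey(table: pd.DataFrame, path, threshold: float = 0.0) -> None:
    """Long-format TSV (source, target, weight), weights strictly above threshold."""
    rows = []
    for src in table.index:
        for tgt in table.columns:
            w = float(table.loc[src, tgt])
            if w > threshold:
                rows.append({"source": src, "target": tgt, "weight": w})
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def plot_landscape(
    embedding: GeneEmbedding, values: np.ndarray, path=None, title: str = "",
    ax=None,
):
    """Scatter of the gene map coloured by a per-gene value.

    Diverging palette centred at 0, the natural centre for mean z-scores.
    """
    import matplotlib
    import matplotlib.pyplot as plt

    values = np.asarray(values, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    lim = float(np.max(np.abs(values))) or 1.0
    sc = ax.scatter(
        embedding.coords[:, 0], embedding.coords[:, 1], c=values, s=8,
        cmap="RdBu_r", norm=matplotlib.colors.Normalize(vmin=-lim, vmax=lim),
    )
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.set_title(title)
    ax.figure.colorbar(sc, ax=ax)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
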