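"""Stress-specificity ranking and the gene–treatment interaction network.

Given a panel of treatment-vs-control contrast results over a shared gene
universe, each focal-stress-responsive gene is scored by the minimum
Bonferroni-adjusted p-value it attains in any panel treatment: the higher
the threshold needed to call it anywhere else, the more specific it is to
the focal stress.  Genes significant (p_adj ≤ α) in at least one treatment
form bipartite edges (gene, treatment); a gene's degree counts the
treatments co-regulating it and degree 0 defines the focal-specific set.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .response_recovery import PHASE_OF_CLASS

__all__ = [
    "panel_differential_sets",
    "specificity_rank",
    "build_interaction_network",
    "treatment_similarity_ranking",
]

Panel = dict[str, pd.DataFrame]  # treatment id → contrast result table


def _check_panel(panel: Panel) -> pd.Index:
    if not panel:
        raise ValueError("empty treatment panel")
    universes = [frozenset(df.index) for df in panel.values()]
    if len(set(universes)) != 1:
        raise ValueError("panel treatments do not share one gene universe")
    return next(iter(panel.values())).index


def panel_differential_sets(panel: Panel, alpha: float = 0.001) -> dict[str, set[str]]:
    """Per-treatment set of genes with p_adj ≤ alpha."""
    _check_panel(panel)
    return {
        t: set(df.index[df["p_adj"] <= alpha]) for t, df in panel.items()
    }


def specificity_rank(
    focal: pd.DataFrame,
    panel: Panel,
    alpha: float = 0.001,
    use_raw: bool = False,
) -> pd.DataFrame:
    """Rank focal-responsive genes by specificity to the focal stress.

    ``focal`` is a table indexed by gene with a ``log2_fc`` column (the
    focal contrast; used only to break ties).  Per gene the minimum
    adjusted p over all panel treatments is taken; rank 1 is the most
    specific (largest minimum p — the most relaxed threshold needed to call
    it in any other treatment).  Ties go to the larger focal |log2_fc|,
    then lexicographic gene id.  ``specific`` flags min p > alpha.
    """
    universe = _check_panel(panel)
    missing = set(focal.index) - set(universe)
    if missing:
        raise ValueError(f"focal genes absent from panel universe: {sorted(missing)[:5]}")
    col = "p_raw" if use_raw else "p_adj"
    pmat = pd.DataFrame({t: df[col].reindex(focal.index) for t, df in panel.items()})
    min_p = pmat.min(axis=1)

    out = pd.DataFrame(
        {
            "min_adjusted_p": min_p,
            "focal_abs_fc": focal["log2_fc"].abs(),
            "specific": min_p > alpha,
        },
        index=focal.index.rename("gene_id"),
    )
    order = out.sort_values(
        by=["min_adjusted_p", "focal_abs_fc", "gene_id"],
        ascending=[False, False, True],
        key=lambda s: s if s.name != "gene_id" else s.astype(str),
    )
    out["rank"] = pd.Series(
        np.arange(1, len(order) + 1), index=order.index
    ).reindex(out.index)
    return out.drop(columns="focal_abs_fc")


def build_interaction_network(
    focal_genes,
    panel: Panel,
    alpha: float = 0.001,
) -> tuple[nx.Graph, pd.Series, pd.Series]:
    """Bipartite gene–treatment network over focal-responsive genes.

    Edge (g, t) exists iff gene g is focal-responsive and p_adj(g, t) ≤ α.
    Returns the graph (nodes carry a ``bipartite`` attribute: 0 = gene,
    1 = treatment), the per-gene degree series (0..T, zeros included — the
    degree-0 genes are exactly the focal-specific set at this α), and the
    per-treatment weight series (number of focal genes each co-regulates).
    """
    focal_genes = list(focal_genes)
    sets = panel_differential_sets(panel, alpha=alpha)
    g = nx.Graph()
    g.add_nodes_from(focal_genes, bipartite=0)
    g.add_nodes_from(sets.keys(), bipartite=1)
    for t, genes in sets.items():
        g.add_edges_from((gene, t) for gene in genes if gene in set(focal_genes))
    degrees = pd.Series(
        {gene: g.degree(gene) for gene in focal_genes}, name="degree"
    ).rename_axis("gene_id")
    weights = pd.Series(
        {t: g.degree(t) for t in sets}, name="weight"
    ).rename_axis("treatment")
    return g, degrees, weights


def treatment_similarity_ranking(
    network: nx.Graph,
    gene_classes: pd.Series,
) -> pd.DataFrame:
    """Treatments ordered by how many focal genes they co-regulate.

    ``gene_classes`` maps every focal gene to its 9-class code; each
    treatment's weight is decomposed into the initial/persistent/latent
    (and continuous, normally zero) phases of the genes it touches.
    """
    gene_nodes = {n for n, b in nx.get_node_attributes(network, "bipartite").items() if b == 0}
    treatments = {n for n, b in nx.get_node_attributes(network, "bipartite").items() if b == 1}
    missing = {g for g in gene_nodes if g not in gene_classes.index}
    if missing:
        raise ValueError(f"genes without class labels: {sorted(missing)[:5]}")

    phases = ("initial", "persistent", "latent", "continuous")
    rows = []
    for t in treatments:
        genes = [n for n in network.neighbors(t)]
        counts = {ph: 0 for ph in phases}
        for gnode in genes:
            ph = PHASE_OF_CLASS[gene_classes[gnode]]
            if ph in counts:
                counts[ph] += 1
        rows.append({"treatment": t, "weight": len(genes), **counts})
    out = pd.DataFrame(rows).sort_values(
        ["weight", "treatment"], ascending=[False, True]
    ).reset_index(drop=True)
    return out
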