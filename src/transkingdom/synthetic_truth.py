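"""Ground-truth network and covariance generation.

The generating model is a sparse, small-world signed interaction network:
a random power-law graph (preferential attachment with triad closure) whose
edges carry +/- signs, converted to a positive-definite covariance matrix
that matches the graph's sparsity pattern exactly.  Taxa are split into two
kingdoms ('A' and 'B') to emulate paired 16S/ITS designs, and per-taxon
mean log-abundances are drawn uniformly from (-4, 4).

Structural variants perturb only the cross-kingdom block: the density of
cross-kingdom edges can be scaled up or down, and their sign balance biased
toward negative (``cross_negative_prob`` > 0.5) or positive (< 0.5)
associations.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

from ._rng import child_rng
from .datatypes import GroundTruthModel, InteractionGraph, StructureVariant

__all__ = [
    "generate_powerlaw_graph",
    "assign_kingdoms",
    "graph_to_covariance",
    "apply_structure_variant",
    "draw_mean_log",
    "generate_ground_truth",
    "save_model",
    "load_model",
]

#: Probability of closing a triangle after each preferential-attachment step.
DEFAULT_TRIANGLE_PROB = 0.1
#: Off-diagonal magnitude range for covariance entries.
DEFAULT_MAGNITUDE_RANGE = (0.2, 1.0)
#: Eigenvalue floor enforced by diagonal loading.
DEFAULT_EIGEN_FLOOR = 0.01


def generate_powerlaw_graph(
    n_taxa: int,
    density_param: int = 2,
    seed: int = 0,
    triangle_prob: float = DEFAULT_TRIANGLE_PROB,
    negative_prob: float = 0.5,
) -> InteractionGraph:
    """Random power-law interaction graph with random edge signs.

    Uses preferential attachment with triad closure (Holme–Kim), which
    yields the heavy-tailed degree distribution and small-world clustering
    expected of microbial association networks.  ``density_param`` is the
    number of edges attached per new node.
    """
    if n_taxa < 4:
        raise ValueError("n_taxa must be at least 4 for a non-degenerate network")
    if density_param < 1:
        raise ValueError("density_param must be >= 1")
    rng = child_rng(seed, "powerlaw-graph")
    nx_seed = int(rng.integers(0, 2**31 - 1))
    g = nx.powerlaw_cluster_graph(n_taxa, density_param, triangle_prob, seed=nx_seed)
    edges = sorted(tuple(sorted(e)) for e in g.edges)
    signs = rng.choice([1, -1], size=len(edges), p=[1 - negative_prob, negative_prob])
    return InteractionGraph(n_taxa, dict(zip(edges, (int(s) for s in signs))))


def assign_kingdoms(n_taxa: int, fraction_a: float = 0.5, seed: int = 0) -> np.ndarray:
    """Randomly label taxa 'A' or 'B' with round(fraction_a * n) in A."""
    if not 0.0 < fraction_a < 1.0:
        raise ValueError("fraction_a must lie strictly between 0 and 1")
    n_a = int(round(fraction_a * n_taxa))
    if n_a == 0 or n_a == n_taxa:
        raise ValueError(
            f"fraction_a={fraction_a} leaves an empty kingdom for n_taxa={n_taxa}"
        )
    rng = child_rng(seed, "kingdom-split")
    labels = np.array(["A"] * n_a + ["B"] * (n_taxa - n_a))
    return labels[rng.permutation(n_taxa)]


def graph_to_covariance(
    graph: InteractionGraph,
    magnitude_range: tuple[float, float] = DEFAULT_MAGNITUDE_RANGE,
    seed: int = 0,
    eigen_floor: float = DEFAULT_EIGEN_FLOOR,
) -> np.ndarray:
    """Positive-definite covariance with support and signs from ``graph``.

    Off-diagonal magnitudes are uniform on ``magnitude_range`` with the
    edge's sign; the diagonal starts at 1 and is loaded uniformly by
    (eigen_floor - lambda_min) whenever the smallest eigenvalue falls at or
    below ``eigen_floor``.  Diagonal loading perturbs no off-diagonal entry,
    so support and signs are preserved exactly and the construction always
    succeeds.
    """
    lo, hi = magnitude_range
    if not (0 < lo < hi):
        raise ValueError("magnitude_range must satisfy 0 < low < high")
    rng = child_rng(seed, "covariance-magnitudes")
    n = graph.n_taxa
    cov = np.eye(n)
    for (i, j), sign in sorted(graph.edge_signs.items()):
        v = sign * rng.uniform(lo, hi)
        cov[i, j] = cov[j, i] = v
    lam_min = float(np.linalg.eigvalsh(cov)[0])
    if lam_min <= eigen_floor:
        cov[np.diag_indices(n)] += eigen_floor - lam_min
    return cov


def apply_structure_variant(
    graph: InteractionGraph,
    kingdom: np.ndarray,
    variant: StructureVariant,
    seed: int = 0,
) -> InteractionGraph:
    """Rescale cross-kingdom edge density and resample cross-kingdom signs.

    Intra-kingdom edges are untouched.  The target cross-edge count is
    round(cross_density_factor * current); extra edges are drawn uniformly
    from the absent cross-kingdom pairs, removals uniformly from the present
    ones.  Every cross-kingdom edge then gets a fresh sign, negative with
    probability ``cross_negative_prob``.
    """
    kingdom = np.asarray(kingdom)
    rng = child_rng(seed, "structure-variant")
    cross = sorted(graph.cross_edges(kingdom))
    n_cross = len(cross)
    target = int(round(variant.cross_density_factor * n_cross))

    idx_a = np.flatnonzero(kingdom == "A")
    idx_b = np.flatnonzero(kingdom == "B")
    all_cross = {
        (min(i, j), max(i, j)) for i in idx_a for j in idx_b
    }
    if target > len(all_cross):
        raise ValueError(
            f"cross_density_factor={variant.cross_density_factor} requests "
            f"{target} cross edges but only {len(all_cross)} pairs exist"
        )

    edge_signs = {
        e: s
        for e, s in graph.edge_signs.items()
        if kingdom[e[0]] == kingdom[e[1]]
    }
    kept = list(cross)
    if target < n_cross:
        keep_idx = rng.choice(n_cross, size=target, replace=False)
        kept = [cross[k] for k in sorted(keep_idx)]
    elif target > n_cross:
        absent = sorted(all_cross - set(cross))
        add_idx = rng.choice(len(absent), size=target - n_cross, replace=False)
        kept = cross + [absent[k] for k in sorted(add_idx)]

    p_neg = variant.cross_negative_prob
    for e in sorted(kept):
        edge_signs[e] = -1 if rng.random() < p_neg else 1
    return InteractionGraph(graph.n_taxa, edge_signs)


def draw_mean_log(
    n_taxa: int, low: float = -4.0, high: float = 4.0, seed: int = 0
) -> np.ndarray:
    """Per-taxon mean log-abundances, uniform on the open interval (low, high)."""
    if not low < high:
        raise ValueError("low must be strictly less than high")
    rng = child_rng(seed, "mean-log")
    return rng.uniform(low, high, size=n_taxa)


def generate_ground_truth(
    n_taxa: int = 500,
    density_param: int = 2,
    fraction_a: float = 0.5,
    variant: StructureVariant | None = None,
    magnitude_range: tuple[float, float] = DEFAULT_MAGNITUDE_RANGE,
    mean_log_range: tuple[float, float] = (-4.0, 4.0),
    triangle_prob: float = DEFAULT_TRIANGLE_PROB,
    eigen_floor: float = DEFAULT_EIGEN_FLOOR,
    seed: int = 0,
) -> GroundTruthModel:
    """Full generating model: graph -> kingdoms -> variant -> covariance -> means.

    Taxa are reordered so the kingdom vector is the contiguous block
    ['A' ... 'A', 'B' ... 'B']; every downstream concatenation uses that
    A-then-B order.  Deterministic given ``seed``.
    """
    graph = generate_powerlaw_graph(
        n_taxa, density_param, seed=seed, triangle_prob=triangle_prob
    )
    labels = assign_kingdoms(n_taxa, fraction_a, seed=seed)

    # relabel so kingdom A occupies indices [0, n_a)
    order = np.argsort(labels, kind="stable")
    rank = np.empty(n_taxa, dtype=int)
    rank[order] = np.arange(n_taxa)
    graph = InteractionGraph(
        n_taxa,
        {
            (min(rank[i], rank[j]), max(rank[i], rank[j])): s
            for (i, j), s in graph.edge_signs.items()
        },
    )
    kingdom = labels[order]

    if variant is not None:
        graph = apply_structure_variant(graph, kingdom, variant, seed=seed)
    covariance = graph_to_covariance(
        graph, magnitude_range, seed=seed, eigen_floor=eigen_floor
    )
    mean_log = draw_mean_log(n_taxa, *mean_log_range, seed=seed)
    return GroundTruthModel(graph, covariance, mean_log, kingdom)


# ---------------------------------------------------------------------------
# serialization


def save_model(model: GroundTruthModel, outdir: str | Path) -> None:
    """Write covariance, means, kingdoms and the signed edge list as TSV."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = model.taxon_ids
    pd.DataFrame(model.covariance, index=ids, columns=ids).to_csv(
        outdir / "covariance.tsv", sep="\t"
    )
    pd.DataFrame({"taxon_id": ids, "mean_log": model.mean_log}).to_csv(
        outdir / "mean_log.tsv", sep="\t", index=False
    )
    pd.DataFrame({"taxon_id": ids, "kingdom": model.kingdom}).to_csv(
        outdir / "kingdom.tsv", sep="\t", index=False
    )
    rows = [
        {"taxon_i": ids[i], "taxon_j": ids[j], "sign": s}
        for (i, j), s in sorted(model.graph.edge_signs.items())
    ]
    pd.DataFrame(rows, columns=["taxon_i", "taxon_j", "sign"]).to_csv(
        outdir / "edges.tsv", sep="\t", index=False
    )


def load_model(indir: str | Path) -> GroundTruthModel:
    """Inverse of :func:`save_model`."""
    import pandas as pd

    indir = Path(indir)
    cov = pd.read_csv(indir / "covariance.tsv", sep="\t", index_col=0)
    ids = list(cov.index)
    pos = {t: k for k, t in enumerate(ids)}
    means = pd.read_csv(indir / "mean_log.tsv", sep="\t")
    kingdoms = pd.read_csv(indir / "kingdom.tsv", sep="\t")
    edges = pd.read_csv(indir / "edges.tsv", sep="\t")
    edge_signs = {
        (min(pos[r.taxon_i], pos[r.taxon_j]), max(pos[r.taxon_i], pos[r.taxon_j])): int(
            r.sign
        )
        for r in edges.itertuples()
    }
    graph = InteractionGraph(len(ids), edge_signs)
    return GroundTruthModel(
        graph,
        cov.to_numpy(),
        means.set_index("taxon_id").loc[ids, "mean_log"].to_numpy(),
        kingdoms.set_index("taxon_id").loc[ids, "kingdom"].to_numpy(),
        taxon_ids=ids,
    )
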