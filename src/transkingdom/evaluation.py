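"""Scoring covariance estimates against the generating truth.

Edge-level metrics: the intra/cross-kingdom bias signature (mean edge
strength relative to the strongest edge, with a Mann-Whitney test between
the two groups), R^2 of true on estimated edge values, ROC/AUC treating
|estimate| as an edge classifier (all edges or cross-kingdom only, with an
optional strongest-true-edge restriction), and sign-matched accuracy of the
top-N strongest inferred edges.

Node-level metrics: betweenness / degree / eigenvector centrality on the
thresholded network plus a Lotka-Volterra knockout "keystoneness" score,
each compared to the ground-truth network's scores by R^2.

Community metrics: Louvain partitions of the thresholded networks compared
by best-overlap (Jaccard) and inclusion scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from ._rng import child_seed

__all__ = [
    "edge_partition",
    "mean_relative_edge_strength",
    "bias_test",
    "edge_r2",
    "edge_auc",
    "top_n_accuracy",
    "threshold_network",
    "hub_scores",
    "lv_keystoneness",
    "hub_r2",
    "detect_communities",
    "community_scores",
    "EdgeEvaluation",
    "NodeEvaluation",
    "CommunityEvaluation",
    "evaluate_edges",
    "evaluate_nodes",
    "evaluate_communities",
]

#: Edge fraction kept when turning a covariance estimate into a network.
DEFAULT_TOP_EDGE_FRACTION = 0.10
#: Fraction of true edges treated as positives in the "strongest true
#: edges" AUC variant; the excluded weaker true edges are dropped from the
#: negatives too (neither positives nor clean negatives).
DEFAULT_STRONG_FRACTION = 0.25
DEFAULT_TOP_N = (10, 25, 50, 100)


# ---------------------------------------------------------------------------
# edge metrics


def _upper_masks(kingdom: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Strict-upper-triangle indices and the cross-kingdom mask."""
    kingdom = np.asarray(kingdom)
    n = kingdom.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    cross = kingdom[iu] != kingdom[ju]
    return iu, ju, cross


def _check_square(matrix: np.ndarray, kingdom: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if matrix.shape[0] != len(kingdom):
        raise ValueError("kingdom vector does not match matrix dimension")
    return matrix


def edge_partition(
    matrix: np.ndarray, kingdom: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split strict-upper-triangle entries into intra- and cross-kingdom values."""
    matrix = _check_square(matrix, kingdom)
    iu, ju, cross = _upper_masks(kingdom)
    values = matrix[iu, ju]
    return values[~cross], values[cross]


def mean_relative_edge_strength(
    matrix: np.ndarray, kingdom: np.ndarray
) -> tuple[float, float]:
    """Mean signed edge value per group, relative to the strongest edge.

    This is the bias diagnostic: uncorrected paired-data methods show a
    positive intra-kingdom and negative cross-kingdom shift.
    """
    intra, cross = edge_partition(matrix, kingdom)
    strongest = max(np.max(np.abs(intra), initial=0.0), np.max(np.abs(cross), initial=0.0))
    if strongest == 0:
        raise ValueError("all off-diagonal entries are zero; relative strength undefined")
    return float(intra.mean() / strongest), float(cross.mean() / strongest)


def bias_test(intra: np.ndarray, cross: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value between the two edge groups."""
    intra = np.asarray(intra, dtype=float)
    cross = np.asarray(cross, dtype=float)
    if intra.size == 0 or cross.size == 0:
        raise ValueError("both edge groups must be non-empty")
    return float(
        mannwhitneyu(intra, cross, alternative="two-sided", method="asymptotic").pvalue
    )


def _subset_values(
    truth: np.ndarray, estimate: np.ndarray, kingdom: np.ndarray, subset: str
) -> tuple[np.ndarray, np.ndarray]:
    truth = _check_square(truth, kingdom)
    estimate = _check_square(estimate, kingdom)
    if truth.shape != estimate.shape:
        raise ValueError("truth and estimate dimensions differ")
    iu, ju, cross = _upper_masks(kingdom)
    tv, ev = truth[iu, ju], estimate[iu, ju]
    if subset == "cross":
        return tv[cross], ev[cross]
    if subset == "all":
        return tv, ev
    raise ValueError(f"unknown subset {subset!r}")


def edge_r2(
    truth: np.ndarray,
    estimate: np.ndarray,
    kingdom: np.ndarray,
    subset: str = "all",
) -> float:
    """R^2 of OLS regression of true on estimated edge values (zeros included).

    Degenerate (constant-estimate) fits score 0.
    """
    tv, ev = _subset_values(truth, estimate, kingdom, subset)
    if np.std(ev) == 0 or np.std(tv) == 0:
        return 0.0
    r = np.corrcoef(tv, ev)[0, 1]
    if not np.isfinite(r):
        return 0.0
    return max(float(r**2), 0.0)


def edge_auc(
    truth: np.ndarray,
    estimate: np.ndarray,
    kingdom: np.ndarray,
    subset: str = "all",
    strong_fraction: float | None = None,
) -> float:
    """AUC of |estimate| as a classifier for ground-truth edge presence.

    Sign is ignored.  With ``strong_fraction``, only the strongest true
    edges (by |true value|) count as positives and the remaining true edges
    are excluded entirely.
    """
    tv, ev = _subset_values(truth, estimate, kingdom, subset)
    scores = np.abs(ev)
    labels = tv != 0
    keep = np.ones(tv.size, dtype=bool)
    if strong_fraction is not None:
        if not 0 < strong_fraction <= 1:
            raise ValueError("strong_fraction must lie in (0, 1]")
        true_idx = np.flatnonzero(labels)
        k = max(1, int(round(strong_fraction * true_idx.size)))
        order = true_idx[np.argsort(-np.abs(tv[true_idx]), kind="stable")]
        strong = set(order[:k].tolist())
        labels = np.array([i in strong for i in range(tv.size)])
        keep = ~np.array(
            [i in set(true_idx.tolist()) - strong for i in range(tv.size)]
        )
    labels, scores = labels[keep], scores[keep]
    if labels.all() or not labels.any():
        raise ValueError("AUC needs both positive and negative pairs")
    return float(roc_auc_score(labels, scores))


def top_n_accuracy(
    truth: np.ndarray,
    estimate: np.ndarray,
    kingdom: np.ndarray,
    n_values: tuple[int, ...] = DEFAULT_TOP_N,
    subset: str = "all",
) -> dict[int, float]:
    """Sign-matched accuracy of the N strongest inferred edges.

    An inferred edge is correct iff the true value is nonzero and has the
    same sign.  Ties and order are deterministic (sorted by -|value|, then
    pair index).
    """
    tv, ev = _subset_values(truth, estimate, kingdom, subset)
    order = np.lexsort((np.arange(ev.size), -np.abs(ev)))
    out: dict[int, float] = {}
    for n in n_values:
        if n <= 0:
            raise ValueError("N must be positive")
        if n > ev.size:
            raise ValueError(f"N={n} exceeds the {ev.size} pairs in subset")
        top = order[:n]
        correct = (tv[top] != 0) & (np.sign(tv[top]) == np.sign(ev[top]))
        out[n] = float(correct.mean())
    return out


# ---------------------------------------------------------------------------
# networks, hubs, communities


def threshold_network(
    estimate: np.ndarray, top_fraction: float = DEFAULT_TOP_EDGE_FRACTION
) -> nx.Graph:
    """Keep the strongest fraction of edges by |value| as a signed graph.

    Nodes are 0..n-1 (isolated nodes included); each kept edge stores its
    signed ``weight`` and ``abs_weight``.  The cutoff tie-break is the
    (i, j) pair order, so the edge set is deterministic.
    """
    estimate = np.asarray(estimate, dtype=float)
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    n = estimate.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    values = estimate[iu, ju]
    k = int(np.ceil(top_fraction * values.size))
    order = np.lexsort((ju, iu, -np.abs(values)))[:k]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for idx in order:
        i, j, v = int(iu[idx]), int(ju[idx]), float(values[idx])
        g.add_edge(i, j, weight=v, abs_weight=abs(v))
    return g


def hub_scores(graph: nx.Graph, metric: str) -> np.ndarray:
    """Normalized centrality scores on the (unweighted) thresholded topology.

    Eigenvector centrality is computed per connected component (unit-norm
    within each); isolated nodes score 0 everywhere.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes)
    if metric == "betweenness":
        d = nx.betweenness_centrality(graph, normalized=True)
    elif metric == "degree":
        d = nx.degree_centrality(graph)
    elif metric == "eigenvector":
        d = {v: 0.0 for v in nodes}
        for comp in nx.connected_components(graph):
            if len(comp) < 2:
                continue
            if len(comp) == 2:  # K2: unit-norm eigenvector is uniform
                d.update({v: 1 / np.sqrt(2) for v in comp})
                continue
            sub = graph.subgraph(comp)
            d.update(nx.eigenvector_centrality_numpy(sub))
    else:
        raise ValueError(f"unknown centrality metric {metric!r}")
    return np.abs(np.array([d[v] for v in nodes]))


@dataclass(frozen=True)
class LotkaVolterraConfig:
    """Knockout-simulation settings.

    Interactions are the estimate's off-diagonal scaled so the largest
    magnitude is ``interaction_scale``; self-interaction -1 and growth rate
    +1 for every taxon, giving a carrying capacity of 1 in isolation.
    """

    interaction_scale: float = 0.5
    growth_rate: float = 1.0
    self_interaction: float = -1.0
    t_final: float = 500.0
    derivative_tol: float = 1e-6


def _glv_steady_state(
    a: np.ndarray, r: np.ndarray, x0: np.ndarray, cfg: LotkaVolterraConfig
) -> np.ndarray | None:
    """Integrate dx/dt = x * (r + A x); None if divergent/non-stationary."""

    def rhs(_t, x):
        return x * (r + a @ x)

    with np.errstate(over="ignore", invalid="ignore"):
        sol = solve_ivp(
            rhs, (0.0, cfg.t_final), x0, method="LSODA", rtol=1e-8, atol=1e-10
        )
    if not sol.success:
        return None
    x = sol.y[:, -1]
    if np.any(~np.isfinite(x)) or np.any(np.abs(x) > 1e6):
        return None
    deriv = rhs(0.0, x)
    scale = max(float(np.max(np.abs(x))), 1.0)
    if np.max(np.abs(deriv)) / scale > cfg.derivative_tol * 10:
        return None
    return np.clip(x, 0.0, None)


def lv_keystoneness(
    estimate: np.ndarray,
    config: LotkaVolterraConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Knockout impact score per taxon from generalized Lotka-Volterra dynamics.

    The covariance estimate parameterizes the interaction matrix; the system
    is integrated to a baseline steady state, then re-integrated once per
    taxon with that taxon removed.  Keystoneness is the Bray-Curtis
    dissimilarity between the remaining taxa's baseline and knockout steady
    states (in [0, 1]).  Divergent dynamics flag the taxon with score 1.
    """
    cfg = config or LotkaVolterraConfig()
    est = np.asarray(estimate, dtype=float)
    n = est.shape[0]
    off = est - np.diag(np.diag(est))
    max_off = float(np.max(np.abs(off)))
    a = off * (cfg.interaction_scale / max_off) if max_off > 0 else off
    a = a + cfg.self_interaction * np.eye(n)
    r = np.full(n, cfg.growth_rate)

    baseline = _glv_steady_state(a, r, np.ones(n), cfg)
    if baseline is None:
        warnings.warn("baseline gLV dynamics divergent; all scores set to 1",
                      RuntimeWarning, stacklevel=2)
        return np.ones(n)

    scores = np.zeros(n)
    for k in range(n):
        keep = np.arange(n) != k
        sub = _glv_steady_state(
            a[np.ix_(keep, keep)], r[keep], np.maximum(baseline[keep], 1e-6), cfg
        )
        if sub is None:
            warnings.warn(f"knockout of taxon {k} divergent; score set to 1",
                          RuntimeWarning, stacklevel=2)
            scores[k] = 1.0
            continue
        u, v = baseline[keep], sub
        denom = float(np.sum(u + v))
        scores[k] = float(np.sum(np.abs(u - v)) / denom) if denom > 0 else 0.0
    return np.clip(scores, 0.0, 1.0)


def hub_r2(truth_scores: np.ndarray, estimate_scores: np.ndarray) -> float:
    """R^2 of OLS of ground-truth node scores on reconstructed node scores."""
    t = np.asarray(truth_scores, dtype=float)
    e = np.asarray(estimate_scores, dtype=float)
    if t.shape != e.shape:
        raise ValueError("score vectors must have equal length")
    if np.std(e) == 0 or np.std(t) == 0:
        return 0.0
    r = np.corrcoef(t, e)[0, 1]
    return max(float(r**2), 0.0) if np.isfinite(r) else 0.0


def detect_communities(graph: nx.Graph, seed: int = 0) -> list[set[int]]:
    """Louvain modularity communities on absolute edge weights (seeded)."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    rng_seed = int(child_seed(seed, "louvain").generate_state(1)[0] % (2**31))
    return [
        set(c)
        for c in nx.community.louvain_communities(
            graph, weight="abs_weight", seed=rng_seed
        )
    ]


@dataclass
class CommunityEvaluation:
    """Per-reconstructed-community agreement with the ground-truth partition."""

    method: str
    overlap_scores: np.ndarray
    inclusion_scores: np.ndarray


def community_scores(
    recon_partition: list[set[int]],
    truth_partition: list[set[int]],
    method: str = "",
) -> CommunityEvaluation:
    """Best-overlap (Jaccard) and inclusion score for each reconstructed community."""
    nodes_r = set().union(*recon_partition) if recon_partition else set()
    nodes_t = set().union(*truth_partition) if truth_partition else set()
    if nodes_r != nodes_t:
        raise ValueError("partitions cover different node sets")
    overlap, inclusion = [], []
    for rc in recon_partition:
        best_j, best_i = 0.0, 0.0
        for tc in truth_partition:
            inter = len(rc & tc)
            if inter == 0:
                continue
            best_j = max(best_j, inter / len(rc | tc))
            best_i = max(best_i, inter / len(rc))
        overlap.append(best_j)
        inclusion.append(best_i)
    return CommunityEvaluation(method, np.array(overlap), np.array(inclusion))


# ---------------------------------------------------------------------------
# per-trial evaluation records


@dataclass
class EdgeEvaluation:
    """Edge-level metric record for one (trial, method) pair."""

    method: str
    mean_rel_intra: float
    mean_rel_cross: float
    bias_p_value: float
    r2_all: float
    r2_cross: float
    auc_all: float
    auc_cross: float
    auc_strong: float
    topn_accuracy: dict[int, float] = field(default_factory=dict)

    def to_record(self) -> dict:
        rec = {
            "method": self.method,
            "mean_rel_intra": self.mean_rel_intra,
            "mean_rel_cross": self.mean_rel_cross,
            "bias_p_value": self.bias_p_value,
            "r2_all": self.r2_all,
            "r2_cross": self.r2_cross,
            "auc_all": self.auc_all,
            "auc_cross": self.auc_cross,
            "auc_strong": self.auc_strong,
        }
        rec.update({f"top{n}_accuracy": v for n, v in self.topn_accuracy.items()})
        return rec


@dataclass
class NodeEvaluation:
    """Hub/keystone scores and their agreement with the ground truth."""

    method: str
    scores: dict[str, np.ndarray]
    r2_vs_truth: dict[str, float]

    def to_record(self) -> dict:
        rec = {"method": self.method}
        rec.update({f"r2_{k}": v for k, v in self.r2_vs_truth.items()})
        return rec


def evaluate_edges(
    truth: np.ndarray,
    estimate: np.ndarray,
    kingdom: np.ndarray,
    method: str = "",
    strong_fraction: float = DEFAULT_STRONG_FRACTION,
    top_n: tuple[int, ...] = DEFAULT_TOP_N,
) -> EdgeEvaluation:
    """All edge metrics for one estimate against the ground-truth covariance."""
    intra, cross = edge_partition(estimate, kingdom)
    mri, mrc = mean_relative_edge_strength(estimate, kingdom)
    topn_all = top_n_accuracy(truth, estimate, kingdom, top_n, subset="all")
    return EdgeEvaluation(
        method=method,
        mean_rel_intra=mri,
        mean_rel_cross=mrc,
        bias_p_value=bias_test(intra, cross),
        r2_all=edge_r2(truth, estimate, kingdom, "all"),
        r2_cross=edge_r2(truth, estimate, kingdom, "cross"),
        auc_all=edge_auc(truth, estimate, kingdom, "all"),
        auc_cross=edge_auc(truth, estimate, kingdom, "cross"),
        auc_strong=edge_auc(
            truth, estimate, kingdom, "all", strong_fraction=strong_fraction
        ),
        topn_accuracy=topn_all,
    )


HUB_METRICS = ("betweenness", "degree", "eigenvector", "lv_keystoneness")


def evaluate_nodes(
    truth: np.ndarray,
    estimate: np.ndarray,
    method: str = "",
    top_edge_fraction: float = DEFAULT_TOP_EDGE_FRACTION,
    lv_config: LotkaVolterraConfig | None = None,
    seed: int = 0,
) -> NodeEvaluation:
    """Hub/keystone scores of the estimate's network vs the truth's network."""
    g_truth = threshold_network(truth, top_edge_fraction)
    g_est = threshold_network(estimate, top_edge_fraction)
    scores: dict[str, np.ndarray] = {}
    r2s: dict[str, float] = {}
    for metric in ("betweenness", "degree", "eigenvector"):
        s_t = hub_scores(g_truth, metric)
        s_e = hub_scores(g_est, metric)
        scores[metric] = s_e
        r2s[metric] = hub_r2(s_t, s_e)
    k_t = lv_keystoneness(truth, lv_config, seed=seed)
    k_e = lv_keystoneness(estimate, lv_config, seed=seed)
    scores["lv_keystoneness"] = k_e
    r2s["lv_keystoneness"] = hub_r2(k_t, k_e)
    return NodeEvaluation(method, scores, r2s)


def evaluate_communities(
    truth: np.ndarray,
    estimate: np.ndarray,
    method: str = "",
    top_edge_fraction: float = DEFAULT_TOP_EDGE_FRACTION,
    seed: int = 0,
) -> CommunityEvaluation:
    """Louvain communities of the estimate's network scored against the truth's."""
    part_t = detect_communities(threshold_network(truth, top_edge_fraction), seed)
    part_e = detect_communities(threshold_network(estimate, top_edge_fraction), seed)
    return community_scores(part_e, part_t, method=method)
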