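"""Core containers shared across the package.

The pipeline moves through three stages: a generating model (sparse signed
interaction graph + positive-definite log-abundance covariance), the paired
count tables a sequencing experiment would actually observe, and the
covariance estimates the six reconstruction methods produce from those
tables.  Each stage has one container here; all are plain dataclasses over
numpy arrays so they serialize to TSV/JSON without ceremony.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "InteractionGraph",
    "GroundTruthModel",
    "StructureVariant",
    "AbsoluteAbundanceTable",
    "PairedCountTables",
    "CovarianceEstimate",
    "ErrorDecomposition",
    "METHOD_ORDER",
]

#: Fixed order in which the reconstruction methods are reported everywhere.
METHOD_ORDER = (
    "log_covariance",
    "clr_mixed",
    "clr_split",
    "sparcc",
    "glasso_mixed",
    "glasso_split",
)


def _canon_edge(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass
class InteractionGraph:
    """Signed, undirected interaction graph over ``n_taxa`` nodes.

    Edges are unordered index pairs stored with ``i < j``; each carries a
    sign in {+1, -1} giving the direction of the true association.
    """

    n_taxa: int
    edge_signs: dict[tuple[int, int], int]

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be positive")
        canon: dict[tuple[int, int], int] = {}
        for (i, j), s in self.edge_signs.items():
            if i == j:
                raise ValueError(f"self-loop on taxon {i}")
            if not (0 <= i < self.n_taxa and 0 <= j < self.n_taxa):
                raise ValueError(f"edge ({i},{j}) out of range")
            if s not in (1, -1):
                raise ValueError(f"edge ({i},{j}) sign must be +1 or -1")
            key = _canon_edge(i, j)
            if key in canon and canon[key] != s:
                raise ValueError(f"edge {key} given conflicting signs")
            canon[key] = s
        self.edge_signs = canon

    @property
    def edges(self) -> set[tuple[int, int]]:
        return set(self.edge_signs)

    @property
    def n_edges(self) -> int:
        return len(self.edge_signs)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_taxa, dtype=int)
        for i, j in self.edge_signs:
            deg[i] += 1
            deg[j] += 1
        return deg

    def cross_edges(self, kingdom: np.ndarray) -> set[tuple[int, int]]:
        kingdom = np.asarray(kingdom)
        return {e for e in self.edge_signs if kingdom[e[0]] != kingdom[e[1]]}


@dataclass
class GroundTruthModel:
    """The generating object behind every synthetic data set.

    ``covariance`` (squared log-abundance units) is symmetric positive
    definite with off-diagonal support exactly equal to ``graph.edges`` and
    off-diagonal signs equal to the graph's edge signs.  ``mean_log`` holds
    per-taxon mean log-abundances; ``kingdom`` labels each taxon 'A' or 'B'.
    """

    graph: InteractionGraph
    covariance: np.ndarray
    mean_log: np.ndarray
    kingdom: np.ndarray
    taxon_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.graph.n_taxa
        self.covariance = np.asarray(self.covariance, dtype=float)
        self.mean_log = np.asarray(self.mean_log, dtype=float)
        self.kingdom = np.asarray(self.kingdom, dtype="<U1")
        if self.covariance.shape != (n, n):
            raise ValueError("covariance shape does not match graph")
        if self.mean_log.shape != (n,):
            raise ValueError("mean_log length does not match graph")
        if self.kingdom.shape != (n,):
            raise ValueError("kingdom length does not match graph")
        if not self.taxon_ids:
            self.taxon_ids = [f"T{k + 1:04d}" for k in range(n)]
        for label in ("A", "B"):
            if not np.any(self.kingdom == label):
                raise ValueError(f"kingdom {label} is empty")

    @property
    def n_taxa(self) -> int:
        return self.graph.n_taxa

    def validate(self, eigen_floor: float = 0.0) -> None:
        """Assert the covariance invariants (symmetry, PD, support, signs)."""
        c = self.covariance
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("covariance not symmetric")
        lam_min = float(np.linalg.eigvalsh(c)[0])
        if lam_min <= eigen_floor:
            raise ValueError(f"covariance not PD (lambda_min={lam_min:.3g})")
        n = self.n_taxa
        for i in range(n):
            for j in range(i + 1, n):
                v = c[i, j]
                if (i, j) in self.graph.edge_signs:
                    if v == 0 or np.sign(v) != self.graph.edge_signs[(i, j)]:
                        raise ValueError(f"edge ({i},{j}) sign/support mismatch")
                elif v != 0:
                    raise ValueError(f"nonzero entry off the graph support ({i},{j})")


@dataclass(frozen=True)
class StructureVariant:
    """Perturbation of the cross-kingdom block of the ground-truth graph.

    ``cross_density_factor`` multiplies the number of cross-kingdom edges;
    ``cross_negative_prob`` is the probability a cross-kingdom edge is
    negative.  ``StructureVariant(1.0, 0.5)`` is the unbiased default.
    """

    cross_density_factor: float = 1.0
    cross_negative_prob: float = 0.5

    def __post_init__(self) -> None:
        if not self.cross_density_factor > 0:
            raise ValueError("cross_density_factor must be > 0")
        if not 0.0 <= self.cross_negative_prob <= 1.0:
            raise ValueError("cross_negative_prob must lie in [0, 1]")


@dataclass
class AbsoluteAbundanceTable:
    """Exact absolute abundances (n_samples x n_taxa); unobservable oracle.

    Rows are exp of multivariate-normal draws, hence strictly positive.
    """

    values: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x taxa)")
        if np.any(~np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("abundances must be finite and strictly positive")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length mismatch")
        if len(self.taxon_ids) != self.values.shape[1]:
            raise ValueError("taxon_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class PairedCountTables:
    """The observable data: one count table per kingdom over shared samples.

    ``counts_a``/``counts_b`` are n_samples x n_taxa matrices whose rows sum
    exactly to the per-sample read depths.  Column order matches the
    kingdom-restricted taxon order of the generating model (A block first in
    every concatenation).  Entries are integers for simulated/real reads but
    floats are tolerated so the methods can run on already-relative data.
    """

    counts_a: np.ndarray
    counts_b: np.ndarray
    sample_ids: list[str]
    taxon_ids_a: list[str]
    taxon_ids_b: list[str]
    depths_a: np.ndarray | None = None
    depths_b: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts_a = np.asarray(self.counts_a)
        self.counts_b = np.asarray(self.counts_b)
        if self.counts_a.ndim != 2 or self.counts_b.ndim != 2:
            raise ValueError("count tables must be 2-D (samples x taxa)")
        if self.counts_a.shape[0] != self.counts_b.shape[0]:
            raise ValueError("paired tables must share samples")
        if self.counts_a.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length mismatch")
        if self.counts_a.shape[1] != len(self.taxon_ids_a):
            raise ValueError("taxon_ids_a length mismatch")
        if self.counts_b.shape[1] != len(self.taxon_ids_b):
            raise ValueError("taxon_ids_b length mismatch")
        if self.counts_a.shape[1] == 0 or self.counts_b.shape[1] == 0:
            raise ValueError("both kingdoms must contain at least one taxon")
        if np.any(self.counts_a < 0) or np.any(self.counts_b < 0):
            raise ValueError("counts must be non-negative")
        for depths, counts, name in (
            (self.depths_a, self.counts_a, "A"),
            (self.depths_b, self.counts_b, "B"),
        ):
            if depths is not None:
                depths = np.asarray(depths)
                if not np.array_equal(counts.sum(axis=1), depths):
                    raise ValueError(f"kingdom {name} rows do not sum to depths")

    @property
    def n_samples(self) -> int:
        return self.counts_a.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts_a.shape[1] + self.counts_b.shape[1]

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.taxon_ids_a) + list(self.taxon_ids_b)

    @property
    def kingdom(self) -> np.ndarray:
        return np.array(
            ["A"] * self.counts_a.shape[1] + ["B"] * self.counts_b.shape[1]
        )

    def concatenated(self) -> np.ndarray:
        """A-then-B concatenation of the two tables (samples x all taxa)."""
        return np.hstack([self.counts_a, self.counts_b]).astype(float)


@dataclass
class CovarianceEstimate:
    """A method-labelled covariance matrix over the concatenated taxon set."""

    method: str
    matrix: np.ndarray
    taxon_ids: list[str]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxon_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxon_ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("covariance estimate not symmetric")
        # store the exactly symmetrized form
        self.matrix = 0.5 * (self.matrix + self.matrix.T)


@dataclass(frozen=True)
class ErrorDecomposition:
    """The paired-data error split for one cross-kingdom taxon pair.

    Var[log(X_a/Y_b)] = Var[log(x_a/y_b)] + Var[log(q/r)]
                        + 2 Cov[log(q/r), log(x_a/y_b)],
    where x, y are within-kingdom relative abundances and q, r the unknown
    per-sample kingdom totals.  ``var_scale_term`` (Var[log(q/r)]) is the
    error concatenating the two tables introduces.
    """

    var_lhs: float
    var_ratio_term: float
    var_scale_term: float
    covar_cross_term: float

    @property
    def residual(self) -> float:
        return self.var_lhs - (
            self.var_ratio_term + self.var_scale_term + self.covar_cross_term
        )
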