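"""Covariance reconstruction from paired compositional count tables.

Six methods, all returning a covariance estimate over the concatenated
(A-then-B) taxon set:

- ``log_covariance``: empirical covariance of log counts (no compositional
  correction at all).
- ``clr_mixed``: centered log-ratio transform applied to the concatenated
  tables, then covariance.  The CLR removes a single per-sample scale
  factor, but paired tables have two unrelated ones (q for kingdom A, r for
  kingdom B), so mixing leaves a Var[log(q/r)]-driven artifact: positively
  shifted intra-kingdom and negatively shifted cross-kingdom covariances.
- ``clr_split``: CLR applied to each kingdom's table separately before
  concatenation — the correction that makes the estimate invariant to both
  scale factors.
- ``sparcc``: basis-correlation estimation from log-ratio variances under a
  sparsity assumption, run on the concatenated tables (so it inherits the
  mixed-data artifact).
- ``glasso_mixed`` / ``glasso_split``: l1-penalized Gaussian maximum
  likelihood (graphical lasso) on the mixed / split CLR covariance, with the
  fitted precision matrix inverted so every method reports a covariance.

Counts are shifted by a +1 pseudocount before logs (SparCC instead uses
Dirichlet resampling with a uniform prior, as in its reference
implementation).  Passing ``pseudocount=None`` runs the log-based methods on
already-positive data unchanged, which is how the scale-invariance
properties are stated exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

from ._rng import child_rng
from .read_simulator import true_scale_factors
from .datatypes import (
    METHOD_ORDER,
    AbsoluteAbundanceTable,
    CovarianceEstimate,
    ErrorDecomposition,
    PairedCountTables,
)

__all__ = [
    "pseudocount",
    "clr",
    "log_covariance_method",
    "clr_mixed_method",
    "clr_split_method",
    "variation_matrix",
    "basis_variances",
    "sparcc_correlations",
    "sparcc_method",
    "glasso_fit",
    "GlassoConvergenceError",
    "glasso_mixed_method",
    "glasso_split_method",
    "oracle_log_covariance",
    "error_decomposition",
    "run_all_methods",
]

DEFAULT_PSEUDOCOUNT = 1.0


# ---------------------------------------------------------------------------
# log-ratio machinery


def pseudocount(counts: np.ndarray, value: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Shift every entry by a positive constant so logs are defined."""
    if not value > 0:
        raise ValueError("pseudocount value must be positive")
    return np.asarray(counts, dtype=float) + value


def clr(rows: np.ndarray) -> np.ndarray:
    """Centered log-ratio transform, row-wise.

    clr(x)_i = log(x_i) - mean_j log(x_j).  Invariant to multiplying a row
    by any positive constant; every output row sums to zero.
    """
    rows = np.asarray(rows, dtype=float)
    if np.any(rows <= 0):
        raise ValueError("clr requires strictly positive entries")
    logs = np.log(rows)
    return logs - logs.mean(axis=1, keepdims=True)


def _maybe_pseudocount(x: np.ndarray, value: float | None) -> np.ndarray:
    if value is None:
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise ValueError("pseudocount=None requires strictly positive data")
        return x
    return pseudocount(x, value)


def _cov(rows: np.ndarray) -> np.ndarray:
    if rows.shape[0] < 2:
        raise ValueError("need at least 2 samples to estimate a covariance")
    return np.cov(rows, rowvar=False, ddof=1)


def _split_clr(paired: PairedCountTables, pc: float | None) -> np.ndarray:
    a = clr(_maybe_pseudocount(paired.counts_a, pc))
    b = clr(_maybe_pseudocount(paired.counts_b, pc))
    return np.hstack([a, b])


# ---------------------------------------------------------------------------
# the three direct covariance methods


def log_covariance_method(
    paired: PairedCountTables, pseudocount_value: float | None = DEFAULT_PSEUDOCOUNT
) -> CovarianceEstimate:
    """Empirical covariance of log counts on the concatenated tables."""
    logs = np.log(_maybe_pseudocount(paired.concatenated(), pseudocount_value))
    return CovarianceEstimate("log_covariance", _cov(logs), paired.taxon_ids)


def clr_mixed_method(
    paired: PairedCountTables, pseudocount_value: float | None = DEFAULT_PSEUDOCOUNT
) -> CovarianceEstimate:
    """Covariance of the CLR taken on the concatenated tables (uncorrected)."""
    rows = clr(_maybe_pseudocount(paired.concatenated(), pseudocount_value))
    return CovarianceEstimate("clr_mixed", _cov(rows), paired.taxon_ids)


def clr_split_method(
    paired: PairedCountTables, pseudocount_value: float | None = DEFAULT_PSEUDOCOUNT
) -> CovarianceEstimate:
    """Covariance of per-kingdom CLR rows — the paired-data correction."""
    rows = _split_clr(paired, pseudocount_value)
    return CovarianceEstimate("clr_split", _cov(rows), paired.taxon_ids)


# ---------------------------------------------------------------------------
# SparCC


def variation_matrix(fractions: np.ndarray) -> np.ndarray:
    """T[a, b] = Var[log(x_a / x_b)] across samples.

    Computed from the covariance C of log fractions as
    T = diag(C) 1' + 1 diag(C)' - 2C, which is exact and O(D^2).
    """
    logs = np.log(np.asarray(fractions, dtype=float))
    c = np.cov(logs, rowvar=False, ddof=1)
    d = np.diag(c)
    t = d[:, None] + d[None, :] - 2.0 * c
    np.fill_diagonal(t, 0.0)
    return t


def basis_variances(
    t_matrix: np.ndarray, excluded: set[tuple[int, int]] | None = None
) -> np.ndarray:
    """Solve the sparsity-assumption linear system for basis variances.

    With all basis correlations assumed to sum to ~0, the row sums
    t_a = sum_b T[a, b] satisfy t = M w with M = (D-2) I + 11', i.e.
    M[a, a] = D - 1 and M[a, b] = 1.  Excluded (strongly correlated) pairs
    are dropped from both the row sums and the system.
    """
    t_matrix = np.asarray(t_matrix, dtype=float)
    d = t_matrix.shape[0]
    if d < 4:
        raise ValueError("basis-variance system needs at least 4 components")
    m = np.ones((d, d)) + (d - 2) * np.eye(d)
    t_sums = t_matrix.sum(axis=1).copy()
    if excluded:
        for i, j in excluded:
            m[i, j] = m[j, i] = 0.0
            m[i, i] -= 1.0
            m[j, j] -= 1.0
            t_sums[i] -= t_matrix[i, j]
            t_sums[j] -= t_matrix[i, j]
    omega = np.linalg.solve(m, t_sums)
    if np.any(omega <= 0):
        warnings.warn(
            "non-positive basis variances; falling back to absolute values",
            RuntimeWarning,
            stacklevel=2,
        )
        omega = np.abs(omega)
        omega[omega == 0] = np.finfo(float).tiny
    return omega


def sparcc_correlations(
    t_matrix: np.ndarray,
    exclusion_threshold: float = 0.1,
    max_exclusion_rounds: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """One basis-correlation estimate with iterative strong-pair exclusion.

    Returns (rho, omega): correlations clipped to [-1, 1] and basis
    variances.  Each round drops the most strongly correlated remaining
    pair whose |rho| exceeds the threshold and re-solves the system.
    """
    d = t_matrix.shape[0]
    excluded: set[tuple[int, int]] = set()
    omega = basis_variances(t_matrix)
    rho = _rho_from_omega(t_matrix, omega)
    for _ in range(max_exclusion_rounds):
        masked = np.abs(rho).copy()
        np.fill_diagonal(masked, 0.0)
        for i, j in excluded:
            masked[i, j] = masked[j, i] = 0.0
        flat = int(np.argmax(masked))
        i, j = divmod(flat, d)
        if masked[i, j] <= exclusion_threshold:
            break
        candidate = excluded | {(min(i, j), max(i, j))}
        try:
            omega_new = basis_variances(t_matrix, candidate)
        except np.linalg.LinAlgError:
            # exclusion would make the system singular (tiny D); stop here
            break
        excluded = candidate
        omega = omega_new
        rho = _rho_from_omega(t_matrix, omega)
    return rho, omega


def _rho_from_omega(t_matrix: np.ndarray, omega: np.ndarray) -> np.ndarray:
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    rho = (omega[:, None] + omega[None, :] - t_matrix) / denom
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return 0.5 * (rho + rho.T)


def sparcc_method(
    paired: PairedCountTables,
    exclusion_threshold: float = 0.1,
    max_exclusion_rounds: int = 10,
    n_resamples: int = 20,
    seed: int = 0,
) -> CovarianceEstimate:
    """SparCC basis correlations on the concatenated tables.

    Zeros are handled the reference way: each resample draws per-sample
    fractions from Dirichlet(counts + 1), estimates basis correlations and
    variances, and the per-entry medians over resamples are aggregated into
    a covariance rho_ab * sqrt(omega_a * omega_b) with omega on the
    diagonal.  The median correlation matrix is kept in ``meta``.
    """
    counts = paired.concatenated()
    if counts.shape[1] < 4:
        raise ValueError("SparCC needs at least 4 taxa in total")
    rng = child_rng(seed, "sparcc-resampling")
    rhos, omegas = [], []
    for _ in range(n_resamples):
        gamma = rng.standard_gamma(counts + 1.0)
        fractions = gamma / gamma.sum(axis=1, keepdims=True)
        rho, omega = sparcc_correlations(
            variation_matrix(fractions), exclusion_threshold, max_exclusion_rounds
        )
        rhos.append(rho)
        omegas.append(omega)
    rho_med = np.median(rhos, axis=0)
    np.fill_diagonal(rho_med, 1.0)
    omega_med = np.median(omegas, axis=0)
    cov = rho_med * np.sqrt(np.outer(omega_med, omega_med))
    np.fill_diagonal(cov, omega_med)
    return CovarianceEstimate(
        "sparcc",
        cov,
        paired.taxon_ids,
        meta={"correlation": rho_med, "n_resamples": n_resamples},
    )


# ---------------------------------------------------------------------------
# graphical lasso


class GlassoConvergenceError(RuntimeError):
    """Raised when the graphical-lasso coordinate descent fails to converge."""


def glasso_fit(
    empirical_cov: np.ndarray,
    lam: float,
    max_iter: int = 500,
    tol: float = 1e-2,
) -> np.ndarray:
    """Maximize log det(Theta) - tr(S Theta) - lam * ||Theta||_1,off.

    Returns the fitted precision matrix (symmetric PD).  The diagonal is
    unpenalized; coordinate descent is run to the duality-gap tolerance
    ``tol`` (the default is loose enough for the near-singular CLR
    covariances this package fits) and non-convergence raises
    :class:`GlassoConvergenceError`.
    """
    s = np.asarray(empirical_cov, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("empirical covariance must be square")
    if not np.allclose(s, s.T, atol=1e-8):
        raise ValueError("empirical covariance must be symmetric")
    if not lam > 0:
        raise ValueError("lam must be positive")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        try:
            _, precision, n_iter = _sk_graphical_lasso(
                s, alpha=lam, max_iter=max_iter, tol=tol, return_n_iter=True
            )
        except (FloatingPointError, UserWarning, np.linalg.LinAlgError) as exc:
            raise GlassoConvergenceError(
                f"graphical lasso failed at lam={lam:.4g}: {exc}"
            ) from exc
    if n_iter >= max_iter:
        raise GlassoConvergenceError(
            f"graphical lasso hit max_iter={max_iter} at lam={lam:.4g}"
        )
    return 0.5 * (precision + precision.T)


def default_lambda_grid(empirical_cov: np.ndarray, n_values: int = 20) -> np.ndarray:
    """Log-spaced grid on [1e-3, 1] x max|off-diagonal of S|."""
    s = np.asarray(empirical_cov)
    off = s - np.diag(np.diag(s))
    lam_max = float(np.max(np.abs(off)))
    if lam_max <= 0:
        lam_max = 1.0
    return lam_max * np.logspace(-3, 0, n_values)


#: Target fraction of taxon pairs carrying a precision edge after
#: regularization selection; comparable to the sparsity of the generating
#: power-law networks at benchmark scale.
DEFAULT_TARGET_EDGE_DENSITY = 0.05


@dataclass
class _GlassoSelection:
    lam: float
    precision: np.ndarray
    n_edges: int
    criterion: str
    score: float
    failures: list[float]


def _edge_count(precision: np.ndarray) -> int:
    off = precision - np.diag(np.diag(precision))
    return int(np.count_nonzero(off) // 2)


def _select_glasso(
    empirical_cov: np.ndarray,
    n_samples: int,
    lam_grid: np.ndarray | None,
    selection: str = "density",
    target_edge_density: float = DEFAULT_TARGET_EDGE_DENSITY,
    gamma: float = 0.5,
    max_iter: int = 500,
) -> _GlassoSelection:
    """Choose the regularization strength deterministically.

    ``selection='density'`` (default) walks the grid from the fully
    penalized end toward weaker penalties, stops once the fitted precision
    reaches ``target_edge_density`` of the possible taxon pairs, and keeps
    the fit whose edge density is closest to the target.  This plays the
    role subsampling-based stability selection plays in practice — pinning
    the fit to a realistic sparsity — at a fraction of the cost and with no
    extra randomness.

    ``selection='ebic'`` minimizes the extended BIC
    -2 loglik + k log n + 4 gamma k log p over the whole grid instead.
    Grid points where coordinate descent fails are skipped and recorded.
    """
    s = np.asarray(empirical_cov, dtype=float)
    p = s.shape[0]
    n_pairs = p * (p - 1) / 2
    if lam_grid is None:
        lam_grid = default_lambda_grid(s)
    grid = sorted(np.asarray(lam_grid, dtype=float), reverse=True)
    best: _GlassoSelection | None = None
    failures: list[float] = []
    for lam in grid:
        try:
            precision = glasso_fit(s, lam, max_iter=max_iter)
        except GlassoConvergenceError:
            failures.append(float(lam))
            continue
        k = _edge_count(precision)
        if selection == "density":
            score = abs(k / n_pairs - target_edge_density)
            if best is None or score < best.score:
                best = _GlassoSelection(float(lam), precision, k, selection, score, [])
            if k / n_pairs >= target_edge_density:
                break
        elif selection == "ebic":
            sign, logdet = np.linalg.slogdet(precision)
            if sign <= 0:
                failures.append(float(lam))
                continue
            loglik = 0.5 * n_samples * (logdet - float(np.sum(s * precision)))
            score = -2.0 * loglik + k * np.log(n_samples) + 4.0 * gamma * k * np.log(p)
            if best is None or score < best.score:
                best = _GlassoSelection(float(lam), precision, k, selection, score, [])
        else:
            raise ValueError(f"unknown selection rule {selection!r}")
    if best is None:
        raise GlassoConvergenceError("graphical lasso failed on the entire grid")
    best.failures = failures
    return best


def _glasso_method(
    paired: PairedCountTables,
    split: bool,
    lam_grid: np.ndarray | None,
    pseudocount_value: float | None,
    selection: str,
    target_edge_density: float,
    gamma: float,
    max_iter: int,
) -> CovarianceEstimate:
    if split:
        rows = _split_clr(paired, pseudocount_value)
        name = "glasso_split"
    else:
        rows = clr(_maybe_pseudocount(paired.concatenated(), pseudocount_value))
        name = "glasso_mixed"
    s = _cov(rows)
    sel = _select_glasso(
        s,
        rows.shape[0],
        lam_grid,
        selection=selection,
        target_edge_density=target_edge_density,
        gamma=gamma,
        max_iter=max_iter,
    )
    cov = np.linalg.inv(sel.precision)
    return CovarianceEstimate(
        name,
        0.5 * (cov + cov.T),
        paired.taxon_ids,
        meta={
            "lam": sel.lam,
            "selection": sel.criterion,
            "selection_score": sel.score,
            "n_edges": sel.n_edges,
            "precision": sel.precision,
            "failed_lams": sel.failures,
        },
    )


def glasso_mixed_method(
    paired: PairedCountTables,
    lam_grid: np.ndarray | None = None,
    pseudocount_value: float | None = DEFAULT_PSEUDOCOUNT,
    selection: str = "density",
    target_edge_density: float = DEFAULT_TARGET_EDGE_DENSITY,
    gamma: float = 0.5,
    max_iter: int = 500,
) -> CovarianceEstimate:
    """Graphical lasso on the mixed-CLR covariance; estimate = inv(precision)."""
    return _glasso_method(
        paired, False, lam_grid, pseudocount_value,
        selection, target_edge_density, gamma, max_iter,
    )


def glasso_split_method(
    paired: PairedCountTables,
    lam_grid: np.ndarray | None = None,
    pseudocount_value: float | None = DEFAULT_PSEUDOCOUNT,
    selection: str = "density",
    target_edge_density: float = DEFAULT_TARGET_EDGE_DENSITY,
    gamma: float = 0.5,
    max_iter: int = 500,
) -> CovarianceEstimate:
    """Graphical lasso on the split-CLR covariance (paired-data corrected)."""
    return _glasso_method(
        paired, True, lam_grid, pseudocount_value,
        selection, target_edge_density, gamma, max_iter,
    )


# ---------------------------------------------------------------------------
# oracle and diagnostics


def oracle_log_covariance(abundances: AbsoluteAbundanceTable) -> CovarianceEstimate:
    """Empirical covariance of exact log absolute abundances (simulation only)."""
    return CovarianceEstimate(
        "oracle_log_covariance",
        _cov(np.log(abundances.values)),
        list(abundances.taxon_ids),
    )


def error_decomposition(
    abundances: AbsoluteAbundanceTable,
    kingdom: np.ndarray,
    taxon_a: int,
    taxon_b: int,
) -> ErrorDecomposition:
    """Decompose the cross-kingdom log-ratio variance on exact abundances.

    ``taxon_a`` / ``taxon_b`` index into the kingdom-A / kingdom-B blocks.
    With x, y the within-kingdom relative abundances and q, r the kingdom
    totals, log(X_a/Y_b) = log(x_a/y_b) + log(q/r), so the variance splits
    exactly into the relative-ratio term, the scale term Var[log(q/r)] and
    twice their covariance.  For two taxa of the same kingdom the scale and
    covariance terms vanish identically (the single-table invariance).
    """
    kingdom = np.asarray(kingdom)
    q, r = true_scale_factors(abundances, kingdom)
    idx_a = np.flatnonzero(kingdom == "A")[taxon_a]
    idx_b = np.flatnonzero(kingdom == "B")[taxon_b]
    log_abs = np.log(abundances.values[:, idx_a]) - np.log(
        abundances.values[:, idx_b]
    )
    log_scale = np.log(q) - np.log(r)
    log_rel = log_abs - log_scale

    var = lambda v: float(np.var(v, ddof=1))
    covar = float(np.cov(log_scale, log_rel, ddof=1)[0, 1])
    return ErrorDecomposition(
        var_lhs=var(log_abs),
        var_ratio_term=var(log_rel),
        var_scale_term=var(log_scale),
        covar_cross_term=2.0 * covar,
    )


# ---------------------------------------------------------------------------
# batch runner


def run_all_methods(
    paired: PairedCountTables,
    seed: int = 0,
    abundances: AbsoluteAbundanceTable | None = None,
    pseudocount_value: float | None = DEFAULT_PSEUDOCOUNT,
    sparcc_kwargs: dict | None = None,
    glasso_kwargs: dict | None = None,
) -> tuple[list[CovarianceEstimate], dict[str, str]]:
    """Run the six methods (plus the oracle when abundances are given).

    Returns the estimates in the fixed method order and a map of per-method
    failure messages; a failing method is recorded, not fatal to the batch.
    """
    sparcc_kwargs = dict(sparcc_kwargs or {})
    glasso_kwargs = dict(glasso_kwargs or {})
    runners = {
        "log_covariance": lambda: log_covariance_method(paired, pseudocount_value),
        "clr_mixed": lambda: clr_mixed_method(paired, pseudocount_value),
        "clr_split": lambda: clr_split_method(paired, pseudocount_value),
        "sparcc": lambda: sparcc_method(paired, seed=seed, **sparcc_kwargs),
        "glasso_mixed": lambda: glasso_mixed_method(
            paired, pseudocount_value=pseudocount_value, **glasso_kwargs
        ),
        "glasso_split": lambda: glasso_split_method(
            paired, pseudocount_value=pseudocount_value, **glasso_kwargs
        ),
    }
    estimates: list[CovarianceEstimate] = []
    failures: dict[str, str] = {}
    for name in METHOD_ORDER:
        try:
            estimates.append(runners[name]())
        except Exception as exc:  # failures are data, not crashes
            failures[name] = f"{type(exc).__name__}: {exc}"
    if abundances is not None:
        try:
            estimates.append(oracle_log_covariance(abundances))
        except Exception as exc:
            failures["oracle_log_covariance"] = f"{type(exc).__name__}: {exc}"
    return estimates, failures
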