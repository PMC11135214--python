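"""Log-normal abundance sampling and per-kingdom read simulation.

Exact absolute abundances are exp of multivariate-normal draws with the
ground-truth mean and covariance.  Sequencing is emulated per kingdom and
per sample: a read depth is drawn from Normal(depth_mean, depth_sd)
(rounded, floored), and the counts are one multinomial draw of that size
with probabilities equal to the within-kingdom relative abundances — which
is distributionally identical to drawing the reads one at a time.  The
absolute table is kept aside as the unobservable oracle; only the paired
count tables are ever shown to the inference methods.
"""

from __future__ import annotations

import numpy as np

from ._rng import child_rng
from .datatypes import AbsoluteAbundanceTable, GroundTruthModel, PairedCountTables

__all__ = [
    "sample_absolute_abundances",
    "simulate_reads",
    "true_scale_factors",
    "simulate_paired_tables",
]

DEFAULT_DEPTH_MEAN = 100_000.0
DEFAULT_DEPTH_SD = 10_000.0
#: Depths are floored here; ~10 SD below the default mean, so it essentially
#: never binds but makes the generator total.
MIN_DEPTH = 1_000


def sample_absolute_abundances(
    model: GroundTruthModel, n_samples: int, seed: int = 0
) -> AbsoluteAbundanceTable:
    """Draw exact absolute abundances from the log-normal ground truth."""
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2 (covariance needs 2+ samples)")
    rng = child_rng(seed, "absolute-abundances")
    chol = np.linalg.cholesky(model.covariance)
    z = rng.standard_normal((n_samples, model.n_taxa))
    log_values = model.mean_log + z @ chol.T
    return AbsoluteAbundanceTable(
        np.exp(log_values),
        sample_ids=[f"S{k + 1:04d}" for k in range(n_samples)],
        taxon_ids=list(model.taxon_ids),
    )


def simulate_reads(
    abundances: AbsoluteAbundanceTable,
    kingdom: np.ndarray,
    depth_mean: float = DEFAULT_DEPTH_MEAN,
    depth_sd: float = DEFAULT_DEPTH_SD,
    seed: int = 0,
    depth_multiplier: float = 1.0,
    min_depth: int = MIN_DEPTH,
) -> PairedCountTables:
    """Simulate per-kingdom sequencing of every sample.

    Depths are drawn independently for each (sample, kingdom) pair — real
    16S and ITS libraries have unrelated depths.  ``depth_multiplier``
    scales the depth distribution to explore zero-heavy low-depth regimes
    (1.0 = the study conditions).
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    kingdom = np.asarray(kingdom)
    if kingdom.shape[0] != abundances.values.shape[1]:
        raise ValueError("kingdom vector length does not match abundance table")
    rng = child_rng(seed, "read-simulation")
    n = abundances.n_samples

    counts: dict[str, np.ndarray] = {}
    depths: dict[str, np.ndarray] = {}
    for label in ("A", "B"):
        cols = np.flatnonzero(kingdom == label)
        if cols.size == 0:
            raise ValueError(f"kingdom {label} is empty")
        block = abundances.values[:, cols]
        probs = block / block.sum(axis=1, keepdims=True)
        raw = rng.normal(depth_mean, depth_sd, size=n) * depth_multiplier
        d = np.maximum(np.rint(raw).astype(int), min_depth)
        counts[label] = np.vstack(
            [rng.multinomial(d[i], probs[i]) for i in range(n)]
        )
        depths[label] = d

    ids = np.asarray(abundances.taxon_ids)
    return PairedCountTables(
        counts_a=counts["A"],
        counts_b=counts["B"],
        sample_ids=list(abundances.sample_ids),
        taxon_ids_a=list(ids[kingdom == "A"]),
        taxon_ids_b=list(ids[kingdom == "B"]),
        depths_a=depths["A"],
        depths_b=depths["B"],
    )


def true_scale_factors(
    abundances: AbsoluteAbundanceTable, kingdom: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample total biomass of each kingdom: q (A) and r (B).

    These are the unknown scale factors linking relative to absolute
    abundance.  They are available only in simulation and are used by the
    error diagnostics and tests, never by the inference methods.
    """
    kingdom = np.asarray(kingdom)
    mask_a = kingdom == "A"
    mask_b = kingdom == "B"
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both kingdoms must be non-empty")
    q = abundances.values[:, mask_a].sum(axis=1)
    r = abundances.values[:, mask_b].sum(axis=1)
    return q, r


def simulate_paired_tables(
    model: GroundTruthModel,
    n_samples: int,
    depth_mean: float = DEFAULT_DEPTH_MEAN,
    depth_sd: float = DEFAULT_DEPTH_SD,
    seed: int = 0,
    depth_multiplier: float = 1.0,
) -> tuple[AbsoluteAbundanceTable, PairedCountTables]:
    """Convenience: abundances plus paired reads from one master seed."""
    abundances = sample_absolute_abundances(model, n_samples, seed=seed)
    paired = simulate_reads(
        abundances,
        model.kingdom,
        depth_mean=depth_mean,
        depth_sd=depth_sd,
        seed=seed,
        depth_multiplier=depth_multiplier,
    )
    return abundances, paired
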