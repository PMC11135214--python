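"""Benchmark orchestration and the real-data bias runner.

``run_benchmark`` executes the full experiment grid: for every sample size
and trial it generates a fresh ground-truth model, samples abundances,
simulates paired reads, runs all reconstruction methods and scores them.
All randomness descends from one master seed through documented child-seed
paths, so a report is bit-reproducible from (config, master_seed).

``run_real_data`` applies the same methods and the intra/cross-kingdom
bias diagnostic to user-supplied paired OTU tables (e.g. 16S + ITS),
after top-abundance taxon filtering and sample matching.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .datatypes import METHOD_ORDER, StructureVariant
from .evaluation import (
    DEFAULT_STRONG_FRACTION,
    DEFAULT_TOP_EDGE_FRACTION,
    DEFAULT_TOP_N,
    bias_test,
    edge_partition,
    evaluate_communities,
    evaluate_edges,
    evaluate_nodes,
    threshold_network,
)
from .inference import run_all_methods
from .read_simulator import simulate_paired_tables
from .synthetic_truth import generate_ground_truth
from .tabular_io import filter_top_taxa, match_samples, read_count_table

__all__ = [
    "ExperimentConfig",
    "BenchmarkReport",
    "run_benchmark",
    "compare_methods",
    "run_real_data",
    "write_report",
]


@dataclass
class ExperimentConfig:
    """Settings for one benchmark grid; defaults are the study conditions.

    500 taxa split evenly into two kingdoms, 75/150/300 samples, read depth
    Normal(100 000, 10 000) per (sample, kingdom), 15 trials for edge
    metrics and 20 for hub metrics, networks thresholded at the top 10% of
    edges by absolute strength.
    """

    n_taxa: int = 500
    sample_sizes: tuple[int, ...] = (75, 150, 300)
    n_trials_edges: int = 15
    n_trials_hubs: int = 20
    depth_mean: float = 100_000.0
    depth_sd: float = 10_000.0
    mean_log_range: tuple[float, float] = (-4.0, 4.0)
    density_param: int = 2
    fraction_a: float = 0.5
    variant: StructureVariant = field(default_factory=StructureVariant)
    top_edge_fraction: float = DEFAULT_TOP_EDGE_FRACTION
    strong_fraction: float = DEFAULT_STRONG_FRACTION
    top_n: tuple[int, ...] = DEFAULT_TOP_N
    pseudocount: float = 1.0
    sparcc_kwargs: dict[str, Any] = field(default_factory=dict)
    glasso_kwargs: dict[str, Any] = field(default_factory=dict)
    master_seed: int = 0
    include_oracle: bool = True
    edge_metrics: bool = True
    hub_metrics: bool = False
    community_metrics: bool = False

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if any(s < 2 for s in self.sample_sizes):
            raise ValueError("sample sizes must be >= 2")
        if self.n_trials_edges < 1 or self.n_trials_hubs < 1:
            raise ValueError("trial counts must be positive")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["variant"] = dataclasses.asdict(self.variant)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        d = dict(d)
        if "variant" in d and isinstance(d["variant"], dict):
            d["variant"] = StructureVariant(**d["variant"])
        for key in ("sample_sizes", "mean_log_range", "top_n"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class BenchmarkReport:
    """Per-trial metric records plus aggregates, serializable to disk."""

    config: ExperimentConfig
    edge_records: pd.DataFrame
    node_records: pd.DataFrame
    community_records: pd.DataFrame
    failures: pd.DataFrame

    def aggregate(self, metric: str) -> pd.DataFrame:
        """Mean +/- SD of one edge metric per (method, sample size)."""
        if self.edge_records.empty:
            return pd.DataFrame()
        g = self.edge_records.groupby(["method", "n_samples"])[metric]
        return g.agg(["mean", "std", "count"]).reset_index()


def _run_trial(
    config: ExperimentConfig,
    n_samples: int,
    trial: int,
    collect_nodes: bool,
    collect_communities: bool,
) -> tuple[list[dict], list[dict], list[dict], list[dict]]:
    seed = int(
        np.random.SeedSequence(
            [config.master_seed, n_samples, trial]
        ).generate_state(1)[0]
        % (2**31)
    )
    model = generate_ground_truth(
        n_taxa=config.n_taxa,
        density_param=config.density_param,
        fraction_a=config.fraction_a,
        variant=config.variant,
        mean_log_range=config.mean_log_range,
        seed=seed,
    )
    abundances, paired = simulate_paired_tables(
        model,
        n_samples,
        depth_mean=config.depth_mean,
        depth_sd=config.depth_sd,
        seed=seed,
    )
    estimates, failures = run_all_methods(
        paired,
        seed=seed,
        abundances=abundances if config.include_oracle else None,
        pseudocount_value=config.pseudocount,
        sparcc_kwargs=config.sparcc_kwargs,
        glasso_kwargs=config.glasso_kwargs,
    )
    base = {"n_samples": n_samples, "trial": trial, "seed": seed}
    edge_rows, node_rows, comm_rows, fail_rows = [], [], [], []
    for method, message in failures.items():
        fail_rows.append({**base, "method": method, "error": message})
    for est in estimates:
        if config.edge_metrics:
            ev = evaluate_edges(
                model.covariance,
                est.matrix,
                model.kingdom,
                method=est.method,
                strong_fraction=config.strong_fraction,
                top_n=config.top_n,
            )
            edge_rows.append({**base, **ev.to_record()})
        if collect_nodes:
            nv = evaluate_nodes(
                model.covariance,
                est.matrix,
                method=est.method,
                top_edge_fraction=config.top_edge_fraction,
                seed=seed,
            )
            node_rows.append({**base, **nv.to_record()})
        if collect_communities:
            cv = evaluate_communities(
                model.covariance,
                est.matrix,
                method=est.method,
                top_edge_fraction=config.top_edge_fraction,
                seed=seed,
            )
            comm_rows.append(
                {
                    **base,
                    "method": est.method,
                    "mean_overlap": float(np.mean(cv.overlap_scores)),
                    "mean_inclusion": float(np.mean(cv.inclusion_scores)),
                }
            )
    return edge_rows, node_rows, comm_rows, fail_rows


def run_benchmark(config: ExperimentConfig) -> BenchmarkReport:
    """Execute the full grid of replicates x sample sizes x methods."""
    n_trials = max(
        config.n_trials_edges if config.edge_metrics else 0,
        config.n_trials_hubs if (config.hub_metrics or config.community_metrics) else 0,
    )
    if n_trials == 0:
        raise ValueError("no metric family enabled")
    edge_rows: list[dict] = []
    node_rows: list[dict] = []
    comm_rows: list[dict] = []
    fail_rows: list[dict] = []
    for n_samples in config.sample_sizes:
        for trial in range(n_trials):
            collect_nodes = config.hub_metrics and trial < config.n_trials_hubs
            collect_comms = config.community_metrics and trial < config.n_trials_hubs
            if config.edge_metrics and trial >= config.n_trials_edges:
                if not (collect_nodes or collect_comms):
                    continue
            e, n, c, f = _run_trial(
                config, n_samples, trial, collect_nodes, collect_comms
            )
            if config.edge_metrics and trial < config.n_trials_edges:
                edge_rows.extend(e)
            node_rows.extend(n)
            comm_rows.extend(c)
            fail_rows.extend(f)
    return BenchmarkReport(
        config=config,
        edge_records=pd.DataFrame(edge_rows),
        node_records=pd.DataFrame(node_rows),
        community_records=pd.DataFrame(comm_rows),
        failures=pd.DataFrame(fail_rows),
    )


def compare_methods(
    records: pd.DataFrame,
    metric: str,
    reference_method: str = "clr_split",
) -> pd.DataFrame:
    """Mann-Whitney p-values of each method's metric vs the reference.

    Mirrors the figure-caption convention of testing every method against
    the split-CLR reference across trials; no multiple-testing correction
    (raw significance is reported).
    """
    if metric not in records.columns:
        raise ValueError(f"metric {metric!r} not in records")
    ref = records[records["method"] == reference_method][metric].to_numpy()
    if ref.size < 3:
        raise ValueError("need >= 3 records per method")
    rows = []
    for method, group in records.groupby("method"):
        if method == reference_method:
            continue
        vals = group[metric].to_numpy()
        if vals.size < 3:
            raise ValueError(f"need >= 3 records for method {method!r}")
        p = float(mannwhitneyu(ref, vals, alternative="two-sided").pvalue)
        rows.append(
            {
                "method": method,
                "reference": reference_method,
                "metric": metric,
                "p_value": p,
                "reference_mean": float(ref.mean()),
                "method_mean": float(vals.mean()),
            }
        )
    return pd.DataFrame(rows)


def run_real_data(
    table_a_path: str | Path,
    table_b_path: str | Path,
    fraction_a: float = 0.02,
    fraction_b: float = 0.01,
    dialect: str = "tsv",
    top_edge_fraction: float = DEFAULT_TOP_EDGE_FRACTION,
    pseudocount: float = 1.0,
    seed: int = 0,
    sparcc_kwargs: dict[str, Any] | None = None,
    glasso_kwargs: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Bias-signature analysis of two real paired OTU tables.

    Filters each kingdom to its most abundant taxa, pairs the shared
    samples, runs the six methods and reports per-method mean relative
    intra/cross edge strengths and Mann-Whitney bias p-values (pooled
    intra vs cross, plus each kingdom's intra block vs cross separately),
    along with the thresholded networks.
    """
    table_a = filter_top_taxa(
        read_count_table(table_a_path, dialect, kingdom="A"), fraction_a
    )
    table_b = filter_top_taxa(
        read_count_table(table_b_path, dialect, kingdom="B"), fraction_b
    )
    paired, match_report = match_samples(table_a, table_b)
    estimates, failures = run_all_methods(
        paired,
        seed=seed,
        pseudocount_value=pseudocount,
        sparcc_kwargs=sparcc_kwargs,
        glasso_kwargs=glasso_kwargs,
    )
    kingdom = paired.kingdom
    n_a = len(paired.taxon_ids_a)
    results = []
    networks = {}
    for est in estimates:
        intra, cross = edge_partition(est.matrix, kingdom)
        iu, ju = np.triu_indices(est.matrix.shape[0], k=1)
        vals = est.matrix[iu, ju]
        intra_a = vals[(ju < n_a)]
        intra_b = vals[(iu >= n_a)]
        strongest = float(np.max(np.abs(vals)))
        results.append(
            {
                "method": est.method,
                "mean_rel_intra": float(intra.mean() / strongest),
                "mean_rel_cross": float(cross.mean() / strongest),
                "bias_p_pooled": bias_test(intra, cross),
                "bias_p_intra_a_vs_cross": bias_test(intra_a, cross),
                "bias_p_intra_b_vs_cross": bias_test(intra_b, cross),
            }
        )
        networks[est.method] = threshold_network(est.matrix, top_edge_fraction)
    return {
        "bias": pd.DataFrame(results),
        "estimates": estimates,
        "networks": networks,
        "failures": failures,
        "n_taxa_a": n_a,
        "n_taxa_b": len(paired.taxon_ids_b),
        "n_samples": paired.n_samples,
        "dropped_samples": {
            "a": match_report.dropped_a,
            "b": match_report.dropped_b,
        },
    }


def write_report(report: BenchmarkReport, outdir: str | Path) -> None:
    """Serialize a report: JSON-lines records, TSV aggregates, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, frame in (
        ("edge_records", report.edge_records),
        ("node_records", report.node_records),
        ("community_records", report.community_records),
        ("failures", report.failures),
    ):
        with open(outdir / f"{name}.jsonl", "w") as fh:
            if not frame.empty:
                for rec in frame.to_dict(orient="records"):
                    fh.write(json.dumps(rec) + "\n")
    if not report.edge_records.empty:
        aggs = []
        for metric in ("r2_all", "r2_cross", "mean_rel_intra", "mean_rel_cross",
                       "auc_all", "auc_cross", "auc_strong"):
            a = report.aggregate(metric)
            a.insert(0, "metric", metric)
            aggs.append(a)
        pd.concat(aggs, ignore_index=True).to_csv(
            outdir / "aggregates.tsv", sep="\t", index=False
        )
    import platform

    manifest = {
        "config": report.config.to_dict(),
        "method_order": list(METHOD_ORDER),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
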