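"""Reading, writing and preprocessing paired OTU count tables.

Two dialects: the common OTU-table TSV (taxa x samples, first header cell
``#OTU ID``) and the dense BIOM-JSON flavor.  Preprocessing mirrors what a
real paired 16S/ITS analysis needs before network inference: restricting
both tables to their shared samples and keeping only the most abundant
fraction of taxa per kingdom, ranked by mean within-sample relative
abundance (robust to library-depth differences).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import PairedCountTables

__all__ = [
    "CountTableFile",
    "read_count_table",
    "write_count_table",
    "match_samples",
    "filter_top_taxa",
    "paired_to_tables",
    "write_paired_tables",
]

OTU_HEADER = "#OTU ID"


@dataclass
class CountTableFile:
    """One kingdom's taxa x samples count table."""

    counts: np.ndarray  # taxa x samples, non-negative integers
    taxon_ids: list[str]
    sample_ids: list[str]
    kingdom: str = "A"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (taxa x samples)")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match identifier lists")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxon identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)


def _coerce_counts(frame: pd.DataFrame, path: str) -> np.ndarray:
    values = frame.to_numpy()
    numeric = values.astype(float)
    if np.any(~np.isfinite(numeric)):
        raise ValueError(f"{path}: non-numeric entries in count table")
    ints = np.rint(numeric)
    if np.any(np.abs(numeric - ints) > 1e-9):
        bad = np.argwhere(np.abs(numeric - ints) > 1e-9)[0]
        raise ValueError(
            f"{path}: non-integer count at row {frame.index[bad[0]]!r}, "
            f"column {frame.columns[bad[1]]!r}"
        )
    if np.any(ints < 0):
        bad = np.argwhere(ints < 0)[0]
        raise ValueError(
            f"{path}: negative count at row {frame.index[bad[0]]!r}, "
            f"column {frame.columns[bad[1]]!r}"
        )
    return ints.astype(np.int64)


def _check_unique(ids: list[str], what: str, path: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"{path}: duplicate {what} identifier {x!r}")
        seen.add(x)


def read_count_table(
    path: str | Path, dialect: str = "tsv", kingdom: str = "A"
) -> CountTableFile:
    """Parse a taxa x samples count table (``tsv`` or ``biom-json``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        # pandas silently mangles duplicate column names; check the raw header
        _check_unique(header[1:], "sample", str(path))
        frame = pd.read_csv(path, sep="\t", index_col=0, comment=None)
        taxa = [str(t) for t in frame.index]
        samples = [str(s) for s in frame.columns]
    elif dialect == "biom-json":
        blob = json.loads(path.read_text())
        if blob.get("matrix_type") != "dense":
            raise ValueError(f"{path}: only dense BIOM-JSON is supported")
        taxa = [str(r["id"]) for r in blob["rows"]]
        samples = [str(c["id"]) for c in blob["columns"]]
        frame = pd.DataFrame(blob["data"], index=taxa, columns=samples)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    _check_unique(taxa, "taxon", str(path))
    _check_unique(samples, "sample", str(path))
    return CountTableFile(_coerce_counts(frame, str(path)), taxa, samples, kingdom)


def write_count_table(
    table: CountTableFile, path: str | Path, dialect: str = "tsv"
) -> None:
    """Write a count table; round-trips losslessly with read_count_table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "tsv":
        frame = table.to_frame()
        frame.index.name = OTU_HEADER
        frame.to_csv(path, sep="\t")
    elif dialect == "biom-json":
        blob = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "transkingdom",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": list(table.counts.shape),
            "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.tolist(),
        }
        path.write_text(json.dumps(blob))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


@dataclass
class SampleMatchReport:
    dropped_a: list[str] = field(default_factory=list)
    dropped_b: list[str] = field(default_factory=list)


def match_samples(
    table_a: CountTableFile, table_b: CountTableFile
) -> tuple[PairedCountTables, SampleMatchReport]:
    """Restrict both tables to their shared samples, in a common order.

    Shared samples keep table A's order; unmatched samples are reported.
    """
    shared = [s for s in table_a.sample_ids if s in set(table_b.sample_ids)]
    if len(shared) < 2:
        raise ValueError(
            f"only {len(shared)} shared samples; at least 2 are required"
        )
    report = SampleMatchReport(
        dropped_a=[s for s in table_a.sample_ids if s not in set(shared)],
        dropped_b=[s for s in table_b.sample_ids if s not in set(shared)],
    )
    fa = table_a.to_frame()[shared]
    fb = table_b.to_frame()[shared]
    paired = PairedCountTables(
        counts_a=fa.to_numpy().T,
        counts_b=fb.to_numpy().T,
        sample_ids=shared,
        taxon_ids_a=list(table_a.taxon_ids),
        taxon_ids_b=list(table_b.taxon_ids),
    )
    return paired, report


def filter_top_taxa(table: CountTableFile, top_fraction: float) -> CountTableFile:
    """Keep the most abundant ceil(top_fraction * n_taxa) taxa.

    Abundance is the mean within-sample relative abundance (each sample's
    counts normalized to proportions first), so deep libraries do not
    dominate the ranking.  Ties break by taxon identifier; idempotent at
    the same fraction.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    n_keep = int(np.ceil(top_fraction * table.n_taxa))
    if n_keep == 0:
        raise ValueError("top_fraction keeps zero taxa")
    counts = table.counts.astype(float)
    totals = counts.sum(axis=0)
    totals[totals == 0] = 1.0
    mean_rel = (counts / totals).mean(axis=1)
    order = sorted(
        range(table.n_taxa), key=lambda i: (-mean_rel[i], table.taxon_ids[i])
    )
    keep = sorted(order[:n_keep])
    return CountTableFile(
        table.counts[keep],
        [table.taxon_ids[i] for i in keep],
        list(table.sample_ids),
        table.kingdom,
    )


def paired_to_tables(paired: PairedCountTables) -> tuple[CountTableFile, CountTableFile]:
    """Split a PairedCountTables back into per-kingdom taxa x samples tables."""
    a = CountTableFile(
        np.asarray(paired.counts_a).T.astype(np.int64),
        list(paired.taxon_ids_a),
        list(paired.sample_ids),
        "A",
    )
    b = CountTableFile(
        np.asarray(paired.counts_b).T.astype(np.int64),
        list(paired.taxon_ids_b),
        list(paired.sample_ids),
        "B",
    )
    return a, b


def write_paired_tables(
    paired: PairedCountTables, outdir: str | Path, dialect: str = "tsv"
) -> tuple[Path, Path]:
    """Write one OTU table per kingdom plus the per-sample depths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = "tsv" if dialect == "tsv" else "biom.json"
    a, b = paired_to_tables(paired)
    path_a = outdir / f"counts_A.{ext}"
    path_b = outdir / f"counts_B.{ext}"
    write_count_table(a, path_a, dialect)
    write_count_table(b, path_b, dialect)
    depths = pd.DataFrame(
        {
            "sample_id": paired.sample_ids,
            "depth_A": np.asarray(paired.counts_a).sum(axis=1),
            "depth_B": np.asarray(paired.counts_b).sum(axis=1),
        }
    )
    depths.to_csv(outdir / "depths.tsv", sep="\t", index=False)
    return path_a, path_b
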