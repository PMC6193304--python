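"""Tab-separated and BIOM-style readers/writers.

All tabular artifacts round-trip through these functions: sample x taxon
count matrices (TSV with a sample-id column, or BIOM v1 JSON), sample
metadata, per-sample qPCR totals, square distance matrices, and the
null-model ensemble outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from dustlight.pipeline import CountTable, QpcrTable
from dustlight.sampling_model import EnsembleSummary


def write_count_table(
    table: CountTable, counts_path, metadata_path=None
) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="sample")
    if metadata_path is not None:
        if table.metadata is None:
            raise ValueError("table has no metadata to write")
        table.metadata.to_csv(metadata_path, sep="\t", index_label="sample")


def read_count_table(counts_path, metadata_path=None) -> CountTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col="sample")
    metadata = None
    if metadata_path is not None:
        metadata = pd.read_csv(metadata_path, sep="\t", index_col="sample")
        if "pma_treated" in metadata.columns:
            metadata["pma_treated"] = metadata["pma_treated"].astype(bool)
    return CountTable(counts.astype(np.int64), metadata)


def read_biom_json(path) -> CountTable:
    """Read a BIOM v1 (JSON) table: observations are taxa, columns samples."""
    doc = json.loads(Path(path).read_text())
    taxa = [row["id"] for row in doc["rows"]]
    samples = [col["id"] for col in doc["columns"]]
    n_obs, n_samp = doc["shape"]
    dense = np.zeros((n_obs, n_samp), dtype=np.int64)
    if doc.get("matrix_type") == "dense":
        dense[:] = np.asarray(doc["data"], dtype=np.int64)
    else:
        for i, j, v in doc["data"]:
            dense[int(i), int(j)] = int(v)
    counts = pd.DataFrame(dense.T, index=samples, columns=taxa)
    counts.index.name = "sample"
    return CountTable(counts)


def write_qpcr(qpcr: QpcrTable, path) -> None:
    qpcr.totals.rename("copies_per_mg").to_csv(path, sep="\t", index_label="sample")


def read_qpcr(path) -> QpcrTable:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    return QpcrTable(df["copies_per_mg"])


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="sample"
    )


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    return DistanceMatrix(df.to_numpy(), ids=list(df.index))


def write_ensemble(summary: EnsembleSummary, out_dir) -> None:
    """Write the binned summary (and per-record table when present)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.to_frame().to_csv(out / "ensemble_bins.tsv", sep="\t", index=False)
    per_bin = pd.DataFrame(
        {
            "log10_abundance_low": summary.x_edges[:-1],
            "log10_abundance_high": summary.x_edges[1:],
            "n": summary.counts.sum(axis=1).astype(int),
            "mean_change": summary.mean_change,
        }
    )
    per_bin.to_csv(out / "ensemble_mean_change.tsv", sep="\t", index=False)
    if summary.records is not None:
        summary.records.to_csv(out / "ensemble_records.tsv", sep="\t", index=False)
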