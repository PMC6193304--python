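"""Count-table processing: decontamination, rarefaction, absolute scaling.

The processing chain mirrors standard PMA/qPCR microbiome practice: subtract
reads seen in negative (PCR / extraction-kit) controls, rarefy every sample
to a common depth, convert relative counts to absolute abundances (16S gene
copies per mg dust) using per-sample qPCR totals, and log10(1+x)-transform.
Viable fractions per community are the ratio of the PMA-treated aliquot's
qPCR total to its untreated partner's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREATMENTS = ("dark", "visible", "ultraviolet")


class PairingError(ValueError):
    """Raised when PMA / non-PMA aliquots cannot be matched one-to-one."""


class EmptyResultError(ValueError):
    """Raised when an operation would leave no samples."""


@dataclass
class CountTable:
    """Sample x taxon integer read counts with optional per-sample metadata.

    ``counts`` rows are samples, columns are taxon ids.  ``metadata`` (if
    given) is indexed identically and carries at least ``treatment``,
    ``pma_treated``, ``microcosm`` and ``replicate``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        arr = counts.to_numpy()
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = counts.astype(np.int64)
        if self.metadata is not None and not self.counts.index.equals(
            self.metadata.index
        ):
            raise ValueError("metadata index must match counts index")

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def taxon_ids(self) -> pd.Index:
        return self.counts.columns

    def select_samples(self, ids) -> "CountTable":
        meta = None if self.metadata is None else self.metadata.loc[ids]
        return CountTable(self.counts.loc[ids], meta)


@dataclass
class QpcrTable:
    """Per-sample total 16S gene copies per mg dust (strictly positive)."""

    totals: pd.Series

    def __post_init__(self) -> None:
        totals = pd.Series(self.totals, dtype=float)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0].tolist()
            raise ValueError(f"qPCR totals must be strictly positive; bad: {bad}")
        self.totals = totals

    @property
    def sample_ids(self) -> pd.Index:
        return self.totals.index


@dataclass
class AbsoluteAbundanceTable:
    """Sample x taxon absolute abundances (copies/mg) with provenance."""

    data: pd.DataFrame
    rarefaction_depth: int | None = None
    qpcr_source: str = "qPCR totals"
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("absolute abundances must be non-negative")


@dataclass
class ViableFractions:
    """Per-community viable fraction estimates from paired qPCR totals."""

    fractions: pd.Series
    capped: tuple[str, ...] = ()

    def group_means(self, groups: pd.Series) -> pd.Series:
        """Mean fraction per group label (groups indexed like fractions)."""
        return self.fractions.groupby(groups.loc[self.fractions.index]).mean()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def subtract_controls(
    table: CountTable,
    controls: CountTable,
    aggregation: str = "sum",
) -> tuple[CountTable, list[str]]:
    """Subtract negative-control reads per taxon, flooring at zero.

    Control counts are aggregated across control samples by ``aggregation``
    ("sum", the default, or "max") and subtracted from every experimental
    sample.  Taxa whose counts drop to zero in every sample are removed; the
    returned list names them.  Taxa absent from the control table are
    treated as zero in controls.
    """
    if aggregation not in ("sum", "max"):
        raise ValueError("aggregation must be 'sum' or 'max'")
    ctl = controls.counts.reindex(columns=table.taxon_ids, fill_value=0)
    per_taxon = ctl.sum(axis=0) if aggregation == "sum" else ctl.max(axis=0)
    adjusted = (table.counts - per_taxon).clip(lower=0).astype(np.int64)
    dead = adjusted.columns[(adjusted == 0).all(axis=0)]
    removed = [t for t in dead if (table.counts[t] > 0).any() or per_taxon[t] > 0]
    kept = adjusted.drop(columns=dead)
    logger.info(
        "subtract_controls (%s): removed %d taxa (%s)",
        aggregation, len(removed), ", ".join(map(str, removed)) or "none",
    )
    return CountTable(kept, table.metadata), removed


def rarefy(
    table: CountTable,
    depth: int,
    seed: int | np.random.Generator | None = None,
) -> tuple[CountTable, list[str]]:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Each retained row is a single multivariate-hypergeometric draw (the
    classic rarefaction).  Samples with fewer than ``depth`` total reads are
    excluded and listed in the returned report.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    excluded = totals.index[totals < depth].tolist()
    kept_ids = totals.index[totals >= depth]
    if len(kept_ids) == 0:
        raise EmptyResultError(f"no sample reaches rarefaction depth {depth}")
    rows = {}
    for sid in kept_ids:
        row = table.counts.loc[sid].to_numpy(dtype=np.int64)
        if row.sum() == depth:
            rows[sid] = row
        else:
            rows[sid] = rng.multivariate_hypergeometric(row, depth)
    rarefied = pd.DataFrame.from_dict(rows, orient="index", dtype=np.int64)
    rarefied.columns = table.taxon_ids
    rarefied.index.name = table.counts.index.name
    meta = None if table.metadata is None else table.metadata.loc[kept_ids]
    if excluded:
        logger.info("rarefy: excluded %d samples below depth %d: %s",
                    len(excluded), depth, excluded)
    return CountTable(rarefied, meta), excluded


def to_absolute(table: CountTable, qpcr: QpcrTable) -> AbsoluteAbundanceTable:
    """Scale per-sample relative counts by qPCR totals (copies/mg).

    absolute_ij = (count_ij / row_total_i) * qpcr_i, so every row sums to
    its sample's qPCR total.
    """
    missing = table.sample_ids.difference(qpcr.sample_ids)
    if len(missing):
        raise PairingError(f"samples missing from qPCR table: {missing.tolist()}")
    row_totals = table.counts.sum(axis=1)
    if (row_totals == 0).any():
        bad = row_totals.index[row_totals == 0].tolist()
        raise ValueError(f"samples with zero total reads: {bad}")
    scale = qpcr.totals.loc[table.sample_ids] / row_totals
    data = table.counts.mul(scale, axis=0)
    return AbsoluteAbundanceTable(data=data, qpcr_source="qPCR totals")


def log_transform(table: AbsoluteAbundanceTable) -> AbsoluteAbundanceTable:
    """Element-wise log10(1 + x); zero stays zero."""
    if table.log_transformed:
        raise ValueError("table is already log-transformed")
    return AbsoluteAbundanceTable(
        data=np.log10(1.0 + table.data),
        rarefaction_depth=table.rarefaction_depth,
        qpcr_source=table.qpcr_source,
        log_transformed=True,
    )


def viable_fraction(
    pma_qpcr: QpcrTable, total_qpcr: QpcrTable
) -> ViableFractions:
    """Viable fraction per community: PMA qPCR total / non-PMA qPCR total.

    Both tables must be indexed by the same community ids (see
    :func:`pair_qpcr_by_community`).  Ratios above 1 — possible through
    assay noise — are capped at 1 and flagged.
    """
    pma_ids = set(pma_qpcr.sample_ids)
    tot_ids = set(total_qpcr.sample_ids)
    if pma_ids != tot_ids:
        raise PairingError(
            f"unpaired communities: PMA-only {sorted(pma_ids - tot_ids)}, "
            f"total-only {sorted(tot_ids - pma_ids)}"
        )
    ratio = pma_qpcr.totals / total_qpcr.totals.loc[pma_qpcr.sample_ids]
    capped = tuple(ratio.index[ratio > 1.0])
    if capped:
        logger.warning("viable_fraction: capped %d ratios above 1: %s",
                       len(capped), list(capped))
    return ViableFractions(fractions=ratio.clip(upper=1.0), capped=capped)


def pair_qpcr_by_community(
    qpcr: QpcrTable, metadata: pd.DataFrame
) -> tuple[QpcrTable, QpcrTable]:
    """Split a qPCR table into paired PMA / non-PMA tables keyed by community.

    Communities are identified by the metadata ``community`` column if
    present, otherwise by "{microcosm}:{replicate}".  Every community must
    contribute exactly one PMA-treated and one untreated aliquot.
    """
    meta = metadata.loc[qpcr.sample_ids]
    if "community" in meta.columns:
        comm = meta["community"].astype(str)
    else:
        comm = meta["microcosm"].astype(str) + ":" + meta["replicate"].astype(str)
    pma_flag = meta["pma_treated"].astype(bool)
    halves = []
    for flag in (True, False):
        sub = qpcr.totals[pma_flag.eq(flag).to_numpy()]
        keys = comm[pma_flag.eq(flag).to_numpy()]
        if keys.duplicated().any():
            raise PairingError(
                f"duplicate aliquots (pma_treated={flag}): "
                f"{keys[keys.duplicated()].tolist()}"
            )
        halves.append(QpcrTable(pd.Series(sub.to_numpy(), index=keys.to_numpy())))
    pma_tab, tot_tab = halves
    if set(pma_tab.sample_ids) != set(tot_tab.sample_ids):
        raise PairingError("PMA and non-PMA aliquots do not pair one-to-one")
    return pma_tab, tot_tab


@dataclass
class PipelineResult:
    """Everything the fixed processing chain produces."""

    decontaminated: CountTable
    removed_taxa: list[str]
    rarefied: CountTable
    excluded_samples: list[str]
    absolute: AbsoluteAbundanceTable
    transformed: AbsoluteAbundanceTable
    depth: int


def run_pipeline(
    counts: CountTable,
    qpcr: QpcrTable,
    controls: CountTable | None = None,
    depth: int = 50_000,
    seed: int | np.random.Generator | None = None,
) -> PipelineResult:
    """Fixed chain: subtract controls -> rarefy -> absolute -> log10(1+x)."""
    logger.info("pipeline order: subtract_controls -> rarefy(depth=%d) -> "
                "to_absolute -> log_transform", depth)
    removed: list[str] = []
    table = counts
    if controls is not None:
        table, removed = subtract_controls(table, controls)
    decontaminated = table
    rarefied, excluded = rarefy(table, depth, seed)
    absolute = to_absolute(rarefied, qpcr)
    absolute.rarefaction_depth = depth
    transformed = log_transform(absolute)
    return PipelineResult(
        decontaminated=decontaminated,
        removed_taxa=removed,
        rarefied=rarefied,
        excluded_samples=excluded,
        absolute=absolute,
        transformed=transformed,
        depth=depth,
    )
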