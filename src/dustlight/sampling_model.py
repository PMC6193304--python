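"""Ecological sampling-theory null model for apparent abundance artefacts.

The model asks what a fixed-depth sequencing experiment *appears* to show
when a community loses a handful of its most abundant taxa but is otherwise
unchanged.  A community is a sequence abundance distribution (SAD): per-taxon
16S gene-copy abundances ``chi_i`` (copies per mg dust) drawn from a
lognormal.  The fraction of each taxon's gene copies that originate from
living cells is a logistic function of its abundance,

    alpha(chi) = (lam - phi) / (1 + exp(-k (chi - chi0))) + phi,

with minimum viability ``phi``, maximum viability ``lam``, steepness ``k``
and half-saturation abundance ``chi0``.  Sequencing is modelled as
size-biased sampling: a multinomial draw of a fixed number of reads with
probabilities proportional to living abundance (libraries pooled at equal
amplicon concentration).  Each model iteration samples an intact community
and its truncated twin (the top-n most abundant taxa removed) at the same
depth and records, per surviving taxon, the apparent log10-fold change in
read counts.  Aggregated over many random parameter sets, this yields the
null expectation that very rare taxa *appear* to increase after dominant
taxa are lost, purely through relaxed detection limits.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit


class DegenerateCommunityError(ValueError):
    """Raised when reads are requested from a community with no living mass."""


class OracleCapacityError(ValueError):
    """Raised when an instance is too large for exhaustive enumeration."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SadParams:
    """Lognormal SAD parameters: ``n_taxa`` draws from Lognormal(mu, sigma).

    ``mu`` and ``sigma`` are the mean and standard deviation of the natural
    log of abundance (the standard lognormal parameterization).
    """

    n_taxa: int
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.n_taxa < 0:
            raise ValueError(f"n_taxa must be >= 0, got {self.n_taxa}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class ViabilityParams:
    """Parameters of the logistic abundance-viability relationship.

    phi and lam are the minimum and maximum viable fractions, k the
    steepness (per copies/mg) and chi0 the half-saturation abundance
    (copies/mg) at which viability is midway between phi and lam.
    """

    phi: float
    lam: float
    k: float
    chi0: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi <= self.lam <= 1.0):
            raise ValueError(
                f"need 0 <= phi <= lam <= 1, got phi={self.phi}, lam={self.lam}"
            )
        if self.chi0 < 0:
            raise ValueError(f"chi0 must be >= 0, got {self.chi0}")


@dataclass(frozen=True)
class AbundanceDistribution:
    """Per-taxon gene-copy abundances (copies/mg) for one community."""

    abundances: np.ndarray
    taxon_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "abundances", ab)
        if ab.ndim != 1:
            raise ValueError("abundances must be a 1-D vector")
        if len(self.taxon_ids) != ab.size:
            raise ValueError("taxon_ids length must match abundances")
        if np.any(ab < 0):
            raise ValueError("abundances must be non-negative")

    def __len__(self) -> int:
        return self.abundances.size


@dataclass(frozen=True)
class ParamRanges:
    """Uniform sampling ranges for one null-model iteration.

    Each ``*_range`` is an inclusive (low, high) pair.  ``chi0`` is drawn
    indirectly: a quantile level from ``chi0_quantile_range`` is applied to
    the realized SAD, so the half-saturation abundance tracks the scale of
    the community.  ``k`` is drawn from ``k_range`` in units of inverse SAD
    interquartile range, so steepness tracks the spread.  ``removal_range``
    bounds the integer number of dominant taxa removed; ``depth`` is the
    fixed number of reads per simulated library.
    """

    s_range: tuple[int, int] = (500, 5000)
    mu_range: tuple[float, float] = (0.0, 3.0)
    sigma_range: tuple[float, float] = (1.0, 4.0)
    phi_range: tuple[float, float] = (0.0, 0.2)
    lam_range: tuple[float, float] = (0.2, 1.0)
    k_range: tuple[float, float] = (0.1, 10.0)
    chi0_quantile_range: tuple[float, float] = (0.05, 0.99)
    removal_range: tuple[int, int] = (10, 65)
    depth: int = 50_000
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "s_range",
            "mu_range",
            "sigma_range",
            "phi_range",
            "lam_range",
            "k_range",
            "chi0_quantile_range",
            "removal_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound {lo} exceeds upper {hi}")
        if self.removal_range[0] < 0:
            raise ValueError("removal_range must be non-negative")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass(frozen=True)
class PairedSimulation:
    """One intact/truncated community pair resampled at fixed depth."""

    true_abundances: AbundanceDistribution
    living: np.ndarray
    removed_ids: frozenset[str]
    counts_before: np.ndarray
    counts_after: np.ndarray
    seed: int | None

    def __post_init__(self) -> None:
        removed_idx = [
            i for i, t in enumerate(self.true_abundances.taxon_ids)
            if t in self.removed_ids
        ]
        if np.any(self.counts_after[removed_idx] != 0):
            raise ValueError("removed taxa must have zero counts after truncation")


@dataclass(frozen=True)
class EnsembleSummary:
    """Binned (log10 true abundance, apparent log10-fold change) surface.

    ``counts[i, j]`` is the number of (taxon, iteration) records falling in
    abundance bin i and change bin j; ``mean_change[i]`` is the mean apparent
    change of the records in abundance bin i (NaN where empty).
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    mean_change: np.ndarray
    n_iterations: int
    n_records: int
    records: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.x_edges) <= 0) or np.any(np.diff(self.y_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if int(self.counts.sum()) != self.n_records:
            raise ValueError("total bin occupancy must equal number of records")

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per occupied 2-D bin."""
        xi, yi = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "log10_abundance_low": self.x_edges[xi],
                "log10_abundance_high": self.x_edges[xi + 1],
                "change_low": self.y_edges[yi],
                "change_high": self.y_edges[yi + 1],
                "n": self.counts[xi, yi].astype(int),
            }
        )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def _taxon_ids(n: int) -> tuple[str, ...]:
    width = max(4, len(str(max(n - 1, 0))))
    return tuple(f"t{i:0{width}d}" for i in range(n))


def draw_sad(
    params: SadParams, seed: int | np.random.Generator | None = None
) -> AbundanceDistribution:
    """Draw a sequence abundance distribution from Lognormal(mu, sigma)."""
    rng = np.random.default_rng(seed)
    ab = rng.lognormal(params.mu, params.sigma, params.n_taxa)
    return AbundanceDistribution(ab, _taxon_ids(params.n_taxa))


def viability(chi, v: ViabilityParams):
    """Viable fraction alpha(chi) of a taxon at abundance chi (copies/mg).

    Bounded by [phi, lam]; monotone non-decreasing in chi when k > 0.
    Accepts scalars or arrays.
    """
    chi = np.asarray(chi, dtype=float)
    if np.any(chi < 0):
        raise ValueError("abundance chi must be non-negative")
    out = (v.lam - v.phi) * expit(v.k * (chi - v.chi0)) + v.phi
    return out if out.ndim else float(out)


def living_abundances(dist: AbundanceDistribution, v: ViabilityParams) -> np.ndarray:
    """Element-wise living population sizes alpha(chi_i) * chi_i."""
    return viability(dist.abundances, v) * dist.abundances


def truncate_top(
    dist: AbundanceDistribution, n_remove: int
) -> tuple[AbundanceDistribution, frozenset[str]]:
    """Remove exactly the ``n_remove`` most abundant taxa.

    Ties are broken by taxon index: among equal abundances the
    lowest-indexed taxon is removed first.
    """
    if not 0 <= n_remove <= len(dist):
        raise ValueError(
            f"n_remove must be in [0, {len(dist)}], got {n_remove}"
        )
    # stable argsort on -abundance removes ties lowest-index-first
    order = np.argsort(-dist.abundances, kind="stable")
    removed = order[:n_remove]
    keep_mask = np.ones(len(dist), dtype=bool)
    keep_mask[removed] = False
    kept = AbundanceDistribution(
        dist.abundances[keep_mask],
        tuple(t for t, k in zip(dist.taxon_ids, keep_mask) if k),
    )
    return kept, frozenset(dist.taxon_ids[i] for i in removed)


def sample_reads(
    living: np.ndarray,
    depth: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Size-biased sampling: multinomial reads proportional to living mass."""
    living = np.asarray(living, dtype=float)
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if np.any(living < 0):
        raise ValueError("living abundances must be non-negative")
    total = living.sum()
    if total == 0:
        if depth > 0:
            raise DegenerateCommunityError(
                "cannot sample reads from a community with zero living abundance"
            )
        return np.zeros(living.size, dtype=np.int64)
    rng = np.random.default_rng(seed)
    return rng.multinomial(depth, living / total)


def apparent_change(count_before, count_after, pseudocount: float = 1.0):
    """Apparent log10-fold change log10((after + pc) / (before + pc))."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    before = np.asarray(count_before, dtype=float)
    after = np.asarray(count_after, dtype=float)
    if np.any(before < 0) or np.any(after < 0):
        raise ValueError("counts must be non-negative")
    out = np.log10((after + pseudocount) / (before + pseudocount))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# iteration and ensemble
# ---------------------------------------------------------------------------


def _draw_parameters(ranges: ParamRanges, rng: np.random.Generator) -> dict:
    s = int(rng.integers(ranges.s_range[0], ranges.s_range[1] + 1))
    mu = rng.uniform(*ranges.mu_range)
    sigma = rng.uniform(*ranges.sigma_range)
    phi, lam = sorted(
        (rng.uniform(*ranges.phi_range), rng.uniform(*ranges.lam_range))
    )
    k_raw = rng.uniform(*ranges.k_range)
    chi0_q = rng.uniform(*ranges.chi0_quantile_range)
    lo, hi = ranges.removal_range
    n_remove = int(rng.integers(lo, hi + 1))
    return dict(
        s=s, mu=mu, sigma=sigma, phi=phi, lam=lam,
        k_raw=k_raw, chi0_q=chi0_q, n_remove=min(n_remove, s),
    )


def run_iteration(
    ranges: ParamRanges,
    seed: int | np.random.Generator | None = None,
    abundance_axis: str = "living",
) -> tuple[PairedSimulation, pd.DataFrame]:
    """One draw of the null model: parameters, SAD, paired resampling.

    Returns the paired simulation and a per-taxon record frame for taxa
    surviving truncation, with columns ``taxon``, ``abundance`` (on the
    requested axis: "living" alpha(chi)*chi or "total" chi),
    ``count_before``, ``count_after`` and ``change``.
    """
    if abundance_axis not in ("living", "total"):
        raise ValueError("abundance_axis must be 'living' or 'total'")
    rng = np.random.default_rng(seed)
    p = _draw_parameters(ranges, rng)
    sad = draw_sad(SadParams(p["s"], p["mu"], p["sigma"]), rng)

    chi0 = float(np.quantile(sad.abundances, p["chi0_q"])) if len(sad) else 0.0
    iqr = float(np.subtract(*np.percentile(sad.abundances, [75, 25]))) if len(sad) else 0.0
    k = p["k_raw"] / iqr if iqr > 0 else p["k_raw"]
    v = ViabilityParams(p["phi"], p["lam"], k, chi0)

    living = living_abundances(sad, v)
    counts_before = sample_reads(living, ranges.depth, rng)

    kept, removed_ids = truncate_top(sad, p["n_remove"])
    keep_mask = np.array([t not in removed_ids for t in sad.taxon_ids])
    living_kept = living[keep_mask]
    counts_after_kept = sample_reads(living_kept, ranges.depth, rng)
    counts_after = np.zeros(len(sad), dtype=np.int64)
    counts_after[keep_mask] = counts_after_kept

    sim = PairedSimulation(
        true_abundances=sad,
        living=living,
        removed_ids=removed_ids,
        counts_before=counts_before,
        counts_after=counts_after,
        seed=None,
    )
    axis_ab = (living if abundance_axis == "living" else sad.abundances)[keep_mask]
    change = apparent_change(
        counts_before[keep_mask], counts_after_kept, ranges.pseudocount
    )
    records = pd.DataFrame(
        {
            "taxon": [t for t, m in zip(sad.taxon_ids, keep_mask) if m],
            "abundance": axis_ab,
            "count_before": counts_before[keep_mask],
            "count_after": counts_after_kept,
            "change": change,
        }
    )
    return sim, records


def run_ensemble(
    n_iter: int,
    ranges: ParamRanges | None = None,
    seed: int | None = None,
    abundance_axis: str = "living",
    n_bins: tuple[int, int] = (60, 40),
    keep_records: bool = False,
) -> EnsembleSummary:
    """Aggregate ``n_iter`` null-model iterations into a binned summary.

    Records with zero abundance on the chosen axis are dropped (they are
    below any detection limit and have no defined log10 abundance).
    Reproducible: the ensemble is a pure function of (n_iter, ranges, seed).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    ranges = ranges or ParamRanges()
    children = np.random.SeedSequence(seed).spawn(n_iter)
    frames = []
    for i, child in enumerate(children):
        _, rec = run_iteration(ranges, np.random.default_rng(child), abundance_axis)
        rec.insert(0, "iteration", i)
        frames.append(rec)
    records = pd.concat(frames, ignore_index=True)
    records = records[records["abundance"] > 0].reset_index(drop=True)

    log_ab = np.log10(records["abundance"].to_numpy())
    change = records["change"].to_numpy()
    counts, x_edges, y_edges = np.histogram2d(log_ab, change, bins=n_bins)
    which = np.clip(np.digitize(log_ab, x_edges) - 1, 0, n_bins[0] - 1)
    sums = np.bincount(which, weights=change, minlength=n_bins[0])
    ns = np.bincount(which, minlength=n_bins[0])
    with np.errstate(invalid="ignore"):
        mean_change = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    return EnsembleSummary(
        x_edges=x_edges,
        y_edges=y_edges,
        counts=counts,
        mean_change=mean_change,
        n_iterations=n_iter,
        n_records=len(records),
        records=records if keep_records else None,
    )


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------


def _compositions(total: int, parts: int):
    """All weak compositions of ``total`` into ``parts`` non-negative ints."""
    for cuts in itertools.combinations(range(total + parts - 1), parts - 1):
        prev, out = -1, []
        for c in cuts:
            out.append(c - prev - 1)
            prev = c
        out.append(total + parts - 2 - prev)
        yield out


def _exact_expectations(living: np.ndarray, depth: int, pseudocount: float):
    """E[count_i] and E[log10(count_i + pc)] by full multinomial enumeration."""
    s = living.size
    total = living.sum()
    if total == 0:
        if depth > 0:
            raise DegenerateCommunityError("zero living abundance")
        return np.zeros(s), np.full(s, math.log10(pseudocount))
    if depth == 0:
        return np.zeros(s), np.full(s, math.log10(pseudocount))
    # enumerate only over the support; zero-abundance taxa never get reads
    support = np.nonzero(living > 0)[0]
    p = living[support] / total
    if support.size == 1:
        e_count_s = np.array([[float(depth)]])
        e_log_s = np.array([math.log10(depth + pseudocount)])
        outcomes = None
    else:
        outcomes = np.array(list(_compositions(depth, support.size)))
        probs = sps.multinomial(depth, p).pmf(outcomes)
        e_count_s = probs @ outcomes
        e_log_s = probs @ np.log10(outcomes + pseudocount)
    e_count = np.zeros(s)
    e_log = np.full(s, math.log10(pseudocount))
    e_count[support] = np.ravel(e_count_s)
    e_log[support] = np.ravel(e_log_s)
    return e_count, e_log


def enumerate_exact(
    living: Sequence[float],
    depth: int,
    pseudocount: float = 1.0,
    living_after: Sequence[float] | None = None,
    max_outcomes: int = 200_000,
) -> pd.DataFrame:
    """Exact expectations over all multinomial outcomes (brute force).

    Enumerates every read-count outcome of sampling ``depth`` reads from
    ``living`` (and independently from ``living_after``, defaulting to the
    same vector) and returns per-taxon exact ``expected_count_before``,
    ``expected_count_after`` and ``expected_change``, the expectation of the
    apparent log10-fold change with the given pseudocount.  Intended as an
    independent test oracle for the Monte-Carlo machinery; instances beyond
    ``max_outcomes`` enumerated outcomes raise :class:`OracleCapacityError`.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    living = np.asarray(living, dtype=float)
    after = living if living_after is None else np.asarray(living_after, dtype=float)
    if after.size != living.size:
        raise ValueError("living_after must match living in length")
    if np.any(living < 0) or np.any(after < 0):
        raise ValueError("abundances must be non-negative")
    n_out = math.comb(depth + living.size - 1, living.size - 1)
    if n_out > max_outcomes:
        raise OracleCapacityError(
            f"{n_out} outcomes exceeds enumeration capacity {max_outcomes}"
        )
    e_count_b, e_log_b = _exact_expectations(living, depth, pseudocount)
    e_count_a, e_log_a = _exact_expectations(after, depth, pseudocount)
    # before/after draws are independent, so E[log ratio] separates
    return pd.DataFrame(
        {
            "expected_count_before": e_count_b,
            "expected_count_after": e_count_a,
            "expected_change": e_log_a - e_log_b,
        }
    )
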