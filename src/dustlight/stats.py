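"""Distance-based community statistics.

Canberra beta-diversity, PERMANOVA (one-way and pairwise with
Benjamini-Hochberg adjustment), permdisp-style multivariate dispersion
analysis, and one-way ANOVA with Tukey-Kramer contrasts.

The PERMANOVA implementation uses the distance-based sum-of-squares
partition of McArdle & Anderson: with N samples in a groups,

    SS_total  = sum_{i<j} d_ij^2 / N
    SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g
    F = (SS_between / (a - 1)) / (SS_within / (N - a)),  R^2 = SS_between / SS_total

and a permutation null obtained by shuffling sample labels.  p-values use
the +1 convention (the observed statistic counts as one permutation), so p
is never 0 and never below 1 / (n_perm + 1).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd


class DesignError(ValueError):
    """Raised when a grouping is unusable (fewer than 2 groups or singletons)."""


@dataclass(frozen=True)
class PermanovaResult:
    label: str
    f_stat: float
    r2: float
    p_value: float
    n_permutations: int
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError(f"R^2 out of [0, 1]: {self.r2}")


@dataclass
class DispersionResult:
    """Per-sample distances to group centroids plus the ANOVA on them."""

    distances: pd.Series
    group_means: pd.Series
    f_stat: float
    p_value: float
    tukey: pd.DataFrame | None


@dataclass
class AnovaResult:
    f_stat: float
    p_value: float
    tukey: pd.DataFrame | None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def canberra_matrix(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Canberra distances between sample rows.

    d(x, y) = sum_j |x_j - y_j| / (|x_j| + |y_j|) over coordinates where the
    denominator is positive; coordinates zero in both samples contribute 0.
    """
    values = table.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("abundance table must be non-negative")
    condensed = pdist(values, metric="canberra")
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in table.index])


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _align_groups(dm: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, pd.Series):
        return groups.loc[list(dm.ids)].to_numpy()
    groups = np.asarray(groups)
    if groups.size != len(dm.ids):
        raise ValueError("groups length must match distance matrix")
    return groups


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ss = 0.0
    for g in range(n_groups):
        idx = np.nonzero(codes == g)[0]
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def _f_from_ssw(ssw, ss_total: float, n: int, a: int):
    # ssw = 0 (perfect separation) legitimately yields F = inf
    ssb = ss_total - ssw
    with np.errstate(divide="ignore"):
        return (ssb / (a - 1)) / (np.asarray(ssw) / (n - a))


def permanova(
    dm: DistanceMatrix,
    groups,
    n_perm: int | str = 999,
    seed: int | np.random.Generator | None = None,
    label: str = "one-way",
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``n_perm`` is the number of random label permutations, or ``"exact"``
    to enumerate every permutation (only for small N): in exact mode the
    p-value is the fraction of all permutations (identity included) whose
    pseudo-F reaches the observed one — the minimal achievable p for the
    design is then the frequency of the observed arrangement class.
    """
    codes, uniques = pd.factorize(_align_groups(dm, groups))
    a = len(uniques)
    if a < 2:
        raise DesignError("need at least two groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        raise DesignError(f"every group needs >= 2 samples, sizes={sizes.tolist()}")
    n = len(codes)
    d2 = np.asarray(dm.data, dtype=float) ** 2
    ss_total = d2.sum() / (2.0 * n)
    ssw_obs = _ss_within(d2, codes, a)
    f_obs = _f_from_ssw(ssw_obs, ss_total, n, a)
    r2 = (ss_total - ssw_obs) / ss_total if ss_total > 0 else 0.0

    if n_perm == "exact":
        if n > 9:
            raise ValueError("exact enumeration limited to N <= 9")
        f_perm = np.array(
            [
                _f_from_ssw(_ss_within(d2, codes[list(perm)], a), ss_total, n, a)
                for perm in itertools.permutations(range(n))
            ]
        )
        p = float(np.mean(f_perm >= f_obs - 1e-12))
        n_done = math.factorial(n)
    else:
        rng = np.random.default_rng(seed)
        n_perm = int(n_perm)
        # one-hot group membership for each permuted labelling; SS_within for
        # permutation b is sum_g h_bg' D2 h_bg / (2 n_g), done in one einsum
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        labels_perm = codes[perms]  # (B, n)
        onehot = (labels_perm[:, :, None] == np.arange(a)[None, None, :]).astype(float)
        quad = np.einsum("big,ij,bjg->bg", onehot, d2, onehot, optimize=True)
        ssw_perm = (quad / (2.0 * sizes)).sum(axis=1)
        f_perm = _f_from_ssw(ssw_perm, ss_total, n, a)
        p = (1.0 + np.sum(f_perm >= f_obs - 1e-12)) / (1.0 + n_perm)
        n_done = n_perm
    return PermanovaResult(
        label=label, f_stat=float(f_obs), r2=float(r2),
        p_value=float(p), n_permutations=n_done,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def pairwise_permanova(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> list[PermanovaResult]:
    """PERMANOVA on every unordered pair of group levels, BH-adjusted.

    Each contrast runs on the sub-matrix of the two levels' samples with its
    own ``n_perm`` label permutations; adjusted p-values control FDR across
    the set of contrasts.
    """
    aligned = _align_groups(dm, groups)
    levels = list(pd.unique(aligned))
    if len(levels) < 2:
        raise DesignError("need at least two groups")
    pairs = list(itertools.combinations(levels, 2))
    children = np.random.SeedSequence(seed).spawn(len(pairs))
    raw = []
    for (g1, g2), child in zip(pairs, children):
        mask = np.isin(aligned, [g1, g2])
        ids = [sid for sid, m in zip(dm.ids, mask) if m]
        sub = dm.filter(ids)
        raw.append(
            permanova(sub, aligned[mask], n_perm=n_perm,
                      seed=np.random.default_rng(child), label=f"{g1}-{g2}")
        )
    adjusted = bh_adjust([r.p_value for r in raw])
    return [
        PermanovaResult(
            label=r.label, f_stat=r.f_stat, r2=r.r2, p_value=r.p_value,
            n_permutations=r.n_permutations, p_adjusted=float(p_adj),
        )
        for r, p_adj in zip(raw, adjusted)
    ]


def permanova_table(results: list[PermanovaResult]) -> pd.DataFrame:
    """Tidy one-row-per-contrast frame (contrast, R2, p, adjusted p)."""
    return pd.DataFrame(
        {
            "contrast": [r.label for r in results],
            "R2": [r.r2 for r in results],
            "p": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "n_permutations": [r.n_permutations for r in results],
        }
    )


# ---------------------------------------------------------------------------
# dispersion (permdisp-style)
# ---------------------------------------------------------------------------


def _pcoa_coordinates(dm: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding keeping negative-eigenvalue axes.

    Returns (real, imaginary) coordinate blocks.  Negative eigenvalues of
    the Gower-centered matrix are kept as "imaginary" axes whose squared
    distances are later subtracted — the standard correction used when
    computing distances to centroids from semi-metric dissimilarities.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    tol = 1e-9 * max(abs(eigvals).max(), 1.0)
    pos = eigvals > tol
    neg = eigvals < -tol
    real = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    imag = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    return real, imag


def dispersion_analysis(
    dm: DistanceMatrix,
    groups,
    seed: int | np.random.Generator | None = None,
) -> DispersionResult:
    """Multivariate homogeneity of group dispersions.

    Embeds samples by principal coordinates (negative eigenvalues retained
    as imaginary axes), measures each sample's distance to its group
    centroid (squared real distance minus squared imaginary distance,
    floored at zero), then runs one-way ANOVA with Tukey contrasts on those
    distances.  ``seed`` is accepted for interface symmetry; the analysis
    itself is deterministic.
    """
    aligned = _align_groups(dm, groups)
    codes, uniques = pd.factorize(aligned)
    if len(uniques) < 2:
        raise DesignError("need at least two groups")
    if np.bincount(codes).min() < 2:
        raise DesignError("every group needs >= 2 samples")
    real, imag = _pcoa_coordinates(dm)
    n = len(codes)
    if real.shape[1] == 0 and imag.shape[1] == 0:
        warnings.warn("degenerate embedding: all samples identical; "
                      "dispersions are zero", UserWarning, stacklevel=2)
        z = np.zeros(n)
    else:
        z2 = np.zeros(n)
        for g in range(len(uniques)):
            idx = codes == g
            for block, sign in ((real, 1.0), (imag, -1.0)):
                if block.shape[1]:
                    delta = block[idx] - block[idx].mean(axis=0)
                    z2[idx] += sign * (delta**2).sum(axis=1)
        z = np.sqrt(np.clip(z2, 0.0, None))
    distances = pd.Series(z, index=list(dm.ids), name="distance_to_centroid")
    group_series = pd.Series(aligned, index=list(dm.ids))
    group_means = distances.groupby(group_series).mean()
    anova = anova_tukey(distances, group_series)
    return DispersionResult(
        distances=distances,
        group_means=group_means,
        f_stat=anova.f_stat,
        p_value=anova.p_value,
        tukey=anova.tukey,
    )


# ---------------------------------------------------------------------------
# ANOVA + Tukey
# ---------------------------------------------------------------------------


def anova_tukey(values, groups) -> AnovaResult:
    """One-way ANOVA with Tukey-Kramer (unbalanced-safe) pairwise contrasts.

    If every group has zero internal variance the F statistic is undefined:
    reported as ``inf`` (p=0) when group means differ, or 0 (p=1) when all
    values are identical, with ``degenerate=True`` and no Tukey table.
    """
    values = np.asarray(pd.Series(values), dtype=float)
    groups = np.asarray(pd.Series(groups).astype(str))
    codes, uniques = pd.factorize(groups)
    if len(uniques) < 2:
        raise DesignError("need at least two groups")
    if np.bincount(codes).min() < 2:
        raise DesignError("every group needs >= 2 samples")
    samples = [values[codes == g] for g in range(len(uniques))]
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if ssw == 0.0:
        means = [s.mean() for s in samples]
        if np.allclose(means, means[0]):
            return AnovaResult(0.0, 1.0, None, degenerate=True)
        return AnovaResult(float("inf"), 0.0, None, degenerate=True)
    f_stat, p = sps.f_oneway(*samples)
    tukey = pairwise_tukeyhsd(values, groups)
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return AnovaResult(float(f_stat), float(p), tukey_df)
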