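"""Mechanistic generator of synthetic daylight-microcosm experiments.

Emulates a microcosm study in which replicate dust communities from one
homogenized inoculum pool are exposed to dark, visible-light or
ultraviolet-light conditions, then assayed by paired PMA-treated (living)
and untreated (total) 16S amplicon sequencing plus qPCR totals.

The default design is 3 treatments x 3 microcosms x 6 replicate communities
= 54 communities, each with two sequencing aliquots (108 count rows).  All
communities share one lognormal base abundance distribution (the
homogenized pool) perturbed by small multiplicative replicate noise.  Light
treatments suppress a set of numerically dominant "sensitive" clades both
in total gene-copy abundance and, much more strongly, in viability; dark
microcosms instead carry a compositional dominance gradient of those same
clades.  Per-community viable fractions are drawn around treatment-level
targets; the packaged defaults put those targets at 12%, 6.8% and 6.1% for
dark, visible and UV groups.  qPCR totals are the true totals with
lognormal measurement noise; read counts are multinomial draws (total
abundances for untreated aliquots, living abundances for PMA aliquots)
with a small Poisson spike of contaminant reads that also populate the
negative-control samples.

Every stochastic quantity needed to regenerate the read counts is kept in
the returned truth record, so generated data can be traced back to ground
truth in recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dustlight.pipeline import CountTable, QpcrTable

TREATMENTS = ("dark", "visible", "ultraviolet")


@dataclass(frozen=True)
class ExperimentDesign:
    """Shape of the microcosm experiment."""

    treatments: tuple[str, ...] = TREATMENTS
    microcosms_per_treatment: int = 3
    replicates_per_microcosm: int = 6
    sequencing_depth: int = 65_000
    depth_jitter: int = 8_000
    n_controls: int = 2

    def __post_init__(self) -> None:
        if len(self.treatments) < 1:
            raise ValueError("need at least one treatment")
        if min(self.microcosms_per_treatment, self.replicates_per_microcosm) < 1:
            raise ValueError("microcosms and replicates must be >= 1")
        if self.sequencing_depth <= self.depth_jitter:
            raise ValueError("sequencing_depth must exceed depth_jitter")
        if self.n_controls < 0:
            raise ValueError("n_controls must be >= 0")

    @property
    def n_communities(self) -> int:
        return (
            len(self.treatments)
            * self.microcosms_per_treatment
            * self.replicates_per_microcosm
        )


@dataclass(frozen=True)
class EffectConfig:
    """Treatment effects and noise structure of the generator.

    ``viability_targets`` are treatment-level mean viable fractions; each
    community's fraction is the target times a mean-one lognormal multiplier
    with log-sd ``viability_spread_sigma``, clipped to ``fraction_bounds``.
    ``viability_suppression`` multiplies the community fraction to give the
    (much lower) viability of sensitive-clade taxa; ``total_suppression``
    scales sensitive-clade total abundances.  ``dark_gradient`` scales the
    sensitive clades across dark microcosms, creating a compositional
    dominance gradient (community totals are renormalized afterwards, so
    the gradient moves composition, not total biomass).
    """

    n_taxa: int = 1200
    sad_sigma: float = 2.0
    total_copies: float = 1.0e7
    sensitive_clades: dict = field(
        default_factory=lambda: {
            "Saccharopolyspora-like": 23,
            "Staphylococcus-like": 12,
        }
    )
    minor_clades: dict = field(
        default_factory=lambda: {
            "Acidimicrobiales-like": ("visible", 3),
            "Cytophagales-like": ("ultraviolet", 3),
        }
    )
    dominance_share: float = 0.30
    dark_gradient: tuple[float, ...] = (0.2, 1.0, 8.0)
    total_suppression: dict = field(
        default_factory=lambda: {"dark": 1.0, "visible": 0.06, "ultraviolet": 0.05}
    )
    minor_boost: float = 8.0
    viability_suppression: dict = field(
        default_factory=lambda: {"dark": 1.0, "visible": 0.05, "ultraviolet": 0.04}
    )
    viability_targets: dict = field(
        default_factory=lambda: {"dark": 0.12, "visible": 0.068, "ultraviolet": 0.061}
    )
    viability_spread_sigma: float = 0.45
    fraction_bounds: tuple[float, float] = (0.004, 0.73)
    replicate_noise_sigma: float = 0.3
    community_scale_sigma: float = 0.15
    qpcr_noise_sigma: float = 0.1
    n_contaminants: int = 4
    contaminant_control_mean: float = 40.0
    contaminant_sample_mean: float = 8.0

    def __post_init__(self) -> None:
        for t, target in self.viability_targets.items():
            if not 0.0 < target <= 1.0:
                raise ValueError(f"viability target for {t} must be in (0, 1]")
        for name, d in (
            ("total_suppression", self.total_suppression),
            ("viability_suppression", self.viability_suppression),
        ):
            for t, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}[{t}] must be in [0, 1]")
        if not 0.0 < self.dominance_share < 1.0:
            raise ValueError("dominance_share must be in (0, 1)")
        if self.fraction_bounds[0] >= self.fraction_bounds[1]:
            raise ValueError("fraction_bounds must be increasing")


def default_effects() -> EffectConfig:
    """The packaged default effect configuration.

    Treatment-level viable-fraction targets are 12% (dark), 6.8% (visible)
    and 6.1% (ultraviolet); per-community fractions are clipped to the
    0.4-73% range.
    """
    return EffectConfig()


def null_effects(viability: float = 0.08) -> EffectConfig:
    """A zero-effect configuration: treatments are exchangeable.

    No clade suppression, no dominance gradient, one common viability
    target; useful for null-calibration of downstream tests.
    """
    flat = {t: 1.0 for t in TREATMENTS}
    return EffectConfig(
        dark_gradient=(1.0, 1.0, 1.0),
        total_suppression=dict(flat),
        viability_suppression=dict(flat),
        viability_targets={t: viability for t in TREATMENTS},
        minor_boost=1.0,
    )


@dataclass
class TruthRecord:
    """Ground truth behind one generated experiment."""

    abundances: pd.DataFrame          # community x taxon total copies/mg
    living: pd.DataFrame              # community x taxon living copies/mg
    viabilities: pd.DataFrame         # community x taxon viable fraction
    target_fraction: pd.Series        # drawn community-level targets
    realized_fraction: pd.Series      # sum(living)/sum(total) per community
    clades: dict                      # clade name -> list of taxon ids
    sensitive_taxa: list
    aliquot_depths: dict              # sample id -> reads drawn
    aliquot_seeds: dict               # sample id -> SeedSequence for counts
    design: ExperimentDesign
    effects: EffectConfig


@dataclass
class SyntheticExperiment:
    counts: CountTable
    qpcr: QpcrTable
    controls: CountTable
    truth: TruthRecord


def _taxon_ids(n: int) -> list[str]:
    return [f"t{i:04d}" for i in range(n)]


def _assign_clades(effects: EffectConfig) -> tuple[dict, list[str]]:
    """Fixed, reproducible clade membership at the head of the taxon list."""
    ids = _taxon_ids(effects.n_taxa)
    clades: dict[str, list[str]] = {}
    cursor = 0
    for name, size in effects.sensitive_clades.items():
        clades[name] = ids[cursor : cursor + size]
        cursor += size
    for name, (_, size) in effects.minor_clades.items():
        clades[name] = ids[cursor : cursor + size]
        cursor += size
    if cursor > effects.n_taxa:
        raise ValueError("clades exceed n_taxa")
    sensitive = [t for n_ in effects.sensitive_clades for t in clades[n_]]
    return clades, sensitive


def _sample_aliquot_counts(
    p_source: np.ndarray,
    depth: int,
    n_contaminants: int,
    contaminant_mean: float,
    seed_seq: np.random.SeedSequence,
) -> np.ndarray:
    """Multinomial community reads plus Poisson contaminant reads."""
    rng = np.random.default_rng(seed_seq)
    reads = rng.multinomial(depth, p_source / p_source.sum())
    spikes = rng.poisson(contaminant_mean, n_contaminants)
    return np.concatenate([reads, spikes])


def generate_experiment(
    design: ExperimentDesign | None = None,
    effects: EffectConfig | None = None,
    seed: int | None = None,
) -> SyntheticExperiment:
    """Generate a complete synthetic experiment with its ground truth."""
    design = design or ExperimentDesign()
    effects = effects or default_effects()
    if len(effects.dark_gradient) != design.microcosms_per_treatment:
        raise ValueError(
            "dark_gradient must have one multiplier per microcosm "
            f"({design.microcosms_per_treatment})"
        )
    for t in design.treatments:
        for d in (
            effects.viability_targets,
            effects.total_suppression,
            effects.viability_suppression,
        ):
            if t not in d:
                raise ValueError(f"effect configuration missing treatment {t!r}")

    ss = np.random.SeedSequence(seed)
    ss_base, ss_comm, ss_counts, ss_qpcr, ss_ctl = ss.spawn(5)

    taxa = _taxon_ids(effects.n_taxa)
    clades, sensitive = _assign_clades(effects)
    sens_idx = np.array([taxa.index(t) for t in sensitive])
    minor_idx = {
        treat: np.array([taxa.index(t) for t in clades[name]])
        for name, (treat, _) in effects.minor_clades.items()
    }

    # homogenized inoculum pool: one lognormal SAD, sensitive clades boosted
    # to a fixed dominance share of total gene copies
    rng_base = np.random.default_rng(ss_base)
    base = rng_base.lognormal(0.0, effects.sad_sigma, effects.n_taxa)
    target_share = effects.dominance_share
    boost = (target_share / (1 - target_share)) * (
        (base.sum() - base[sens_idx].sum()) / base[sens_idx].sum()
    )
    base[sens_idx] *= boost
    base *= effects.total_copies / base.sum()

    rng_comm = np.random.default_rng(ss_comm)
    rng_qpcr = np.random.default_rng(ss_qpcr)

    communities, sample_rows = [], []
    abund_rows, living_rows, viab_rows = {}, {}, {}
    target_frac, realized_frac = {}, {}
    qpcr_totals: dict[str, float] = {}
    aliquot_specs: list[tuple[str, str, bool]] = []  # sample id, community, pma

    for treatment in design.treatments:
        for m in range(design.microcosms_per_treatment):
            microcosm = f"{treatment[0].upper()}{m + 1}"
            for r in range(design.replicates_per_microcosm):
                community = f"{microcosm}.r{r + 1}"
                chi = base * rng_comm.lognormal(
                    0.0, effects.replicate_noise_sigma, effects.n_taxa
                )
                if treatment == "dark":
                    chi[sens_idx] *= effects.dark_gradient[m]
                else:
                    chi[sens_idx] *= effects.total_suppression[treatment]
                    if treatment in minor_idx:
                        chi[minor_idx[treatment]] *= effects.minor_boost
                # gradient/suppression shift composition only; totals are
                # set by an independent community-scale draw
                total = effects.total_copies * rng_comm.lognormal(
                    0.0, effects.community_scale_sigma
                )
                chi *= total / chi.sum()

                sigma = effects.viability_spread_sigma
                f_c = float(
                    np.clip(
                        effects.viability_targets[treatment]
                        * rng_comm.lognormal(-0.5 * sigma**2, sigma),
                        *effects.fraction_bounds,
                    )
                )
                v = np.empty(effects.n_taxa)
                v_sens = f_c * effects.viability_suppression[treatment]
                t_sens = chi[sens_idx].sum()
                t_rest = total - t_sens
                v_rest = np.clip((f_c * total - v_sens * t_sens) / t_rest, 0.0, 1.0)
                v[:] = v_rest
                v[sens_idx] = v_sens
                living = chi * v

                communities.append(community)
                abund_rows[community] = chi
                living_rows[community] = living
                viab_rows[community] = v
                target_frac[community] = f_c
                realized_frac[community] = living.sum() / total
                noise = rng_qpcr.lognormal(0.0, effects.qpcr_noise_sigma, 2)
                for pma, source_total, nz in (
                    (False, total, noise[0]),
                    (True, living.sum(), noise[1]),
                ):
                    sid = f"{community}|{'pma' if pma else 'tot'}"
                    qpcr_totals[sid] = source_total * nz
                    aliquot_specs.append((sid, community, pma))
                    sample_rows.append(
                        dict(
                            sample=sid,
                            treatment=treatment,
                            pma_treated=pma,
                            microcosm=microcosm,
                            replicate=f"r{r + 1}",
                            community=community,
                        )
                    )

    # read counts: one child seed per aliquot so counts are reproducible
    # from the truth record alone
    count_children = ss_counts.spawn(len(aliquot_specs))
    rng_depth = np.random.default_rng(ss_counts)
    contam_ids = [f"contam{i + 1}" for i in range(effects.n_contaminants)]
    depths, seeds, count_rows = {}, {}, {}
    for (sid, community, pma), child in zip(aliquot_specs, count_children):
        depth = int(
            rng_depth.integers(
                design.sequencing_depth - design.depth_jitter,
                design.sequencing_depth + design.depth_jitter + 1,
            )
        )
        depths[sid], seeds[sid] = depth, child
        source = living_rows[community] if pma else abund_rows[community]
        count_rows[sid] = _sample_aliquot_counts(
            source, depth, effects.n_contaminants,
            effects.contaminant_sample_mean, child,
        )

    all_columns = taxa + contam_ids
    counts_df = pd.DataFrame.from_dict(count_rows, orient="index", dtype=np.int64)
    counts_df.columns = all_columns
    counts_df.index.name = "sample"
    metadata = pd.DataFrame(sample_rows).set_index("sample")

    rng_ctl = np.random.default_rng(ss_ctl)
    ctl_rows = {
        f"control{i + 1}": np.concatenate(
            [
                np.zeros(effects.n_taxa, dtype=np.int64),
                rng_ctl.poisson(
                    effects.contaminant_control_mean, effects.n_contaminants
                ),
            ]
        )
        for i in range(design.n_controls)
    }
    controls_df = pd.DataFrame.from_dict(ctl_rows, orient="index", dtype=np.int64)
    controls_df.columns = all_columns
    controls_df.index.name = "sample"

    truth = TruthRecord(
        abundances=pd.DataFrame.from_dict(abund_rows, orient="index", columns=taxa),
        living=pd.DataFrame.from_dict(living_rows, orient="index", columns=taxa),
        viabilities=pd.DataFrame.from_dict(viab_rows, orient="index", columns=taxa),
        target_fraction=pd.Series(target_frac, name="target_fraction"),
        realized_fraction=pd.Series(realized_frac, name="realized_fraction"),
        clades=clades,
        sensitive_taxa=sensitive,
        aliquot_depths=depths,
        aliquot_seeds=seeds,
        design=design,
        effects=effects,
    )
    return SyntheticExperiment(
        counts=CountTable(counts_df, metadata),
        qpcr=QpcrTable(pd.Series(qpcr_totals, name="copies_per_mg")),
        controls=CountTable(controls_df),
        truth=truth,
    )


def counts_from_truth(truth: TruthRecord) -> pd.DataFrame:
    """Regenerate the experiment's count table from its truth record.

    Uses the stored per-aliquot depths and seeds; the result is
    bit-identical to the originally generated counts.
    """
    effects = truth.effects
    rows = {}
    for sid, seed_seq in truth.aliquot_seeds.items():
        community, kind = sid.split("|")
        source = (
            truth.living.loc[community] if kind == "pma"
            else truth.abundances.loc[community]
        ).to_numpy()
        rows[sid] = _sample_aliquot_counts(
            source,
            truth.aliquot_depths[sid],
            effects.n_contaminants,
            effects.contaminant_sample_mean,
            seed_seq,
        )
    taxa = list(truth.abundances.columns) + [
        f"contam{i + 1}" for i in range(effects.n_contaminants)
    ]
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=np.int64)
    df.columns = taxa
    df.index.name = "sample"
    return df
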