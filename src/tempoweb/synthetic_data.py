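"""Synthetic temporal plant-frugivore communities.

The generator emulates the statistical structure the analysis assumes:
roughly ten sampling periods over one year, a few dozen plant and bird
species, a nested interaction backbone, a migrant influx concentrated in
some periods, and a seasonal trade-off between the number of fruiting
species and their crop sizes (many species with small crops in migration
peaks, few species with huge crops in the wet season).

Links arise from a latent-trait model: plant "attractiveness" ``a_p`` and
bird "generality" ``g_b`` are lognormal, and a fruiting plant and a
present bird connect with probability ``1 - exp(-c (a_p g_b)^s)`` where
``s`` is the nestedness strength. At ``s = 0`` every pair connects with
the same probability (the Bernoulli-independent baseline used for null
calibration); increasing ``s`` concentrates links on high-trait species
and produces nested matrices. Intensities are negative-binomial given a
link; FAI categories derive from simulated crop sizes through the ordinal
breakpoints 1-10 / 11-100 / 101-1,000 / 1,001-10,000 / >10,000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .io_model import InteractionMatrix, SpeciesRecord, TemporalNetworkSeries, TraitTable

FAI_BREAKPOINTS = np.array([10.0, 100.0, 1000.0, 10000.0])

SUPPORTED_EFFECTS = ("intercept", "prop_migratory", "fruit_richness")


def fai_category_from_crop(crop_size) -> np.ndarray:
    """Ordinal FAI category (1..5) of a fruit crop size (number of fruits)."""
    crop = np.atleast_1d(np.asarray(crop_size, dtype=float))
    return (np.searchsorted(FAI_BREAKPOINTS, crop, side="left") + 1).astype(int)


@dataclass
class SimulationConfig:
    """Knobs of the community simulator; defaults give a small fast system."""

    n_periods: int = 10
    n_plants: int = 20
    n_resident_birds: int = 12
    n_migrant_birds: int = 8
    migration_schedule: np.ndarray | None = None  # per-period migrant presence prob
    phenology: np.ndarray | None = None           # per-period plant fruiting prob
    crop_size_mu: np.ndarray | None = None        # per-period lognormal log-median
    crop_size_sigma: float = 1.2
    nestedness_strength: np.ndarray | float = 1.0
    intensity_dispersion: float = 1.0             # negative-binomial size parameter
    link_density: float = 0.35                    # c in 1 - exp(-c (a g)^s)
    base_link_prob: float = 0.0                   # floor for opportunistic links
    trait_sigma: float = 0.7                      # lognormal sd of latent traits
    n_core_residents: int = 4                     # residents with boosted generality
    n_core_migrants: int = 1                      # migrants with boosted generality
    core_boost: float = 5.0
    core_migrant_boost: float | None = None       # defaults to core_boost
    resident_presence: float = 0.8
    core_resident_presence: float = 0.95          # core-prone residents are common
    individuals_per_plant: float = 3.0            # Poisson mean of FAI records
    effect_sizes: dict = field(default_factory=dict)
    seed: int = 0
    period_labels: list[str] | None = None

    def __post_init__(self):
        problems = []
        for name in ("n_periods", "n_plants", "n_resident_birds", "n_migrant_birds"):
            if getattr(self, name) <= 0:
                problems.append(name)
        if self.migration_schedule is None:
            self.migration_schedule = np.full(self.n_periods, 0.3)
        self.migration_schedule = np.asarray(self.migration_schedule, dtype=float)
        if self.migration_schedule.shape != (self.n_periods,) or np.any(
            (self.migration_schedule < 0) | (self.migration_schedule > 1)
        ):
            problems.append("migration_schedule")
        if self.phenology is None:
            self.phenology = np.full(self.n_periods, 0.5)
        self.phenology = np.asarray(self.phenology, dtype=float)
        if self.phenology.shape != (self.n_periods,) or np.any(
            (self.phenology < 0) | (self.phenology > 1)
        ):
            problems.append("phenology")
        if self.crop_size_mu is None:
            self.crop_size_mu = np.full(self.n_periods, np.log(200.0))
        self.crop_size_mu = np.asarray(self.crop_size_mu, dtype=float)
        if self.crop_size_mu.shape != (self.n_periods,):
            problems.append("crop_size_mu")
        self.nestedness_strength = np.broadcast_to(
            np.asarray(self.nestedness_strength, dtype=float), (self.n_periods,)
        ).copy()
        if np.any(self.nestedness_strength < 0):
            problems.append("nestedness_strength")
        if self.intensity_dispersion <= 0:
            problems.append("intensity_dispersion")
        if self.link_density <= 0:
            problems.append("link_density")
        unknown = [k for k in self.effect_sizes if k not in SUPPORTED_EFFECTS]
        if unknown:
            problems.append(f"effect_sizes ({unknown})")
        if problems:
            raise InvalidParameterError(f"invalid SimulationConfig fields: {problems}")
        if self.period_labels is None:
            self.period_labels = [f"P{t:02d}" for t in range(self.n_periods)]
        if len(self.period_labels) != self.n_periods:
            raise InvalidParameterError("period_labels length must equal n_periods")


# Study-period labels in sampling order (Nov 2013 .. Nov 2014).
STUDY_PERIODS = ["Nov13", "Jan14", "Mar14", "May14", "Jun14", "Jul14",
                 "Aug14", "Sep14", "Oct14", "Nov14"]


def paper_like(seed: int = 0) -> SimulationConfig:
    """Preset at the study's scale: 10 periods, 42 plants, 27 resident +
    17 migrant birds, ~320 distinct links, migrant peaks in Jan and Oct and
    no migrants in June, fruit richness high when migrants are in and crop
    sizes largest in the wet mid-year months, and a nested backbone strong
    in half the periods."""
    #           Nov13 Jan14 Mar14 May14 Jun14 Jul14 Aug14 Sep14 Oct14 Nov14
    schedule = [0.18, 0.90, 0.70, 0.12, 0.00, 0.08, 0.12, 0.70, 0.90, 0.18]
    phenology = [0.42, 0.60, 0.55, 0.33, 0.26, 0.28, 0.33, 0.60, 0.55, 0.42]
    crop_mu = np.log([150, 40, 60, 600, 2500, 2000, 800, 40, 30, 150])
    strength = [2.0, 2.0, 2.0, 0.5, 0.5, 0.5, 0.5, 2.0, 2.0, 0.5]
    return SimulationConfig(
        n_periods=10,
        n_plants=42,
        n_resident_birds=27,
        n_migrant_birds=17,
        migration_schedule=schedule,
        phenology=np.asarray(phenology),
        crop_size_mu=crop_mu,
        nestedness_strength=strength,
        intensity_dispersion=0.8,
        link_density=0.14,
        base_link_prob=0.02,
        trait_sigma=0.6,
        n_core_residents=7,
        n_core_migrants=3,
        core_boost=6.0,
        core_migrant_boost=3.0,
        resident_presence=0.62,
        seed=seed,
        period_labels=list(STUDY_PERIODS),
    )


@dataclass
class GroundTruth:
    """Latent parameters and realized covariates of one simulated series."""

    plant_attractiveness: np.ndarray
    bird_generality: np.ndarray
    migrant_ids: list[str]
    resident_ids: list[str]
    core_prone_ids: list[str]
    realized: pd.DataFrame  # per-period realized covariates

    def to_frame(self) -> pd.DataFrame:
        return self.realized


def _traits(config: SimulationConfig, rng: np.random.Generator):
    plants = [f"pl{i:02d}" for i in range(config.n_plants)]
    residents = [f"rb{i:02d}" for i in range(config.n_resident_birds)]
    migrants = [f"mb{i:02d}" for i in range(config.n_migrant_birds)]
    records = [
        SpeciesRecord(p, f"Plant {p}", "plant", "not_applicable",
                      seeds_per_fruit=float(rng.integers(1, 30)))
        for p in plants
    ]
    records += [SpeciesRecord(b, f"Resident {b}", "bird", "resident") for b in residents]
    records += [SpeciesRecord(b, f"Migrant {b}", "bird", "migratory") for b in migrants]
    return plants, residents, migrants, TraitTable(records)


def simulate_series(
    config: SimulationConfig,
) -> tuple[TemporalNetworkSeries, pd.DataFrame, GroundTruth]:
    """Draw one temporal series, its FAI records and the ground truth.

    Same config (including seed) gives identical outputs; all randomness
    flows through one seeded generator.
    """
    rng = np.random.default_rng(config.seed)
    plants, residents, migrants, traits = _traits(config, rng)
    birds = residents + migrants

    a = rng.lognormal(0.0, config.trait_sigma, config.n_plants)
    g = rng.lognormal(0.0, config.trait_sigma, len(birds))
    core_residents = residents[: config.n_core_residents]
    core_migrants = migrants[: config.n_core_migrants]
    core_prone = core_residents + core_migrants
    mig_boost = config.core_migrant_boost if config.core_migrant_boost is not None else config.core_boost
    for b in core_residents:
        g[birds.index(b)] *= config.core_boost
    for b in core_migrants:
        g[birds.index(b)] *= mig_boost

    matrices = []
    fai_rows = []
    realized_rows = []
    for t in range(config.n_periods):
        label = config.period_labels[t]
        fruiting = rng.random(config.n_plants) < config.phenology[t]
        res_presence = np.where(
            np.arange(len(residents)) < config.n_core_residents,
            config.core_resident_presence,
            config.resident_presence,
        )
        present_res = rng.random(len(residents)) < res_presence
        present_mig = rng.random(len(migrants)) < config.migration_schedule[t]
        present = np.concatenate([present_res, present_mig])
        # keep the system connected enough to form a network every period
        if fruiting.sum() < 2:
            fruiting[np.argsort(-a)[:2]] = True
        if present.sum() < 2:
            present[np.argsort(-g)[:2]] = True

        s = config.nestedness_strength[t]
        ag = np.outer(a[fruiting], g[present])
        # normalize so the mean link probability is governed by link_density
        agn = ag**s
        agn = agn / agn.mean()
        p_link = 1.0 - np.exp(-config.link_density * agn)
        p_link = np.maximum(p_link, config.base_link_prob)
        links = rng.random(p_link.shape) < p_link

        mean_w = 1.0 + 2.0 * ag / ag.mean()
        size = config.intensity_dispersion
        w = np.where(
            links,
            1.0 + rng.negative_binomial(size, size / (size + mean_w)),
            0.0,
        ).astype(float)
        keep_p = w.sum(axis=1) > 0
        keep_b = w.sum(axis=0) > 0
        if keep_p.sum() == 0 or keep_b.sum() == 0:  # pathological tiny configs
            i, j = np.unravel_index(np.argmax(p_link), p_link.shape)
            w[i, j] = 1.0
            keep_p = w.sum(axis=1) > 0
            keep_b = w.sum(axis=0) > 0
        plant_ids = [p for p, f in zip(plants, fruiting) if f]
        bird_ids = [b for b, pr in zip(birds, present) if pr]
        m = InteractionMatrix(
            period_label=label,
            plants=[p for p, k in zip(plant_ids, keep_p) if k],
            birds=[b for b, k in zip(bird_ids, keep_b) if k],
            weights=w[np.ix_(keep_p, keep_b)],
        )
        matrices.append(m)

        # FAI records for fruiting plants (independent of realized links)
        for p_idx in np.where(fruiting)[0]:
            n_ind = 1 + rng.poisson(config.individuals_per_plant)
            crops = rng.lognormal(
                config.crop_size_mu[t] + np.log(a[p_idx]), config.crop_size_sigma, n_ind
            )
            crops = np.maximum(crops, 1.0)
            for k, cat in enumerate(fai_category_from_crop(crops)):
                fai_rows.append((label, plants[p_idx], f"{plants[p_idx]}-{k}", int(cat)))

        n_mig_in_net = sum(1 for b in m.birds if b in set(migrants))
        realized_rows.append(
            {
                "period": label,
                "n_plants": m.n_plants,
                "n_birds": m.n_birds,
                "n_links": m.n_links(),
                "prop_migratory": n_mig_in_net / m.n_birds,
                "nestedness_strength": s,
            }
        )

    series = TemporalNetworkSeries(matrices=matrices, traits=traits)
    fai = pd.DataFrame(fai_rows, columns=["period", "plant_id", "individual_id", "fai_category"])
    truth = GroundTruth(
        plant_attractiveness=a,
        bird_generality=g,
        migrant_ids=migrants,
        resident_ids=residents,
        core_prone_ids=core_prone,
        realized=pd.DataFrame(realized_rows),
    )
    return series, fai, truth


@dataclass
class RecoveryBundle:
    """Covariates, Poisson response and ground-truth coefficients."""

    covariates: pd.DataFrame   # period, prop_migratory, fruit_richness, fruit_abundance
    response_table: pd.DataFrame  # period + 'response' column (metrics-table shaped)
    true_beta: dict


def simulate_for_recovery(config: SimulationConfig) -> RecoveryBundle:
    """Per-period dataset with a known log-linear covariate -> response law.

    The expected response follows
    ``exp(b0 + b1 * prop_migratory + b2 * fruit_richness)`` with the betas
    taken from ``config.effect_sizes`` (missing names default to 0, the
    intercept to log 20), and the realized response is Poisson. This gives
    the regression module a recoverable ground truth.
    """
    beta = {
        "intercept": float(config.effect_sizes.get("intercept", np.log(20.0))),
        "prop_migratory": float(config.effect_sizes.get("prop_migratory", 0.0)),
        "fruit_richness": float(config.effect_sizes.get("fruit_richness", 0.0)),
    }
    rng = np.random.default_rng(config.seed)
    n = config.n_periods
    mig = rng.beta(1.5, 3.0, n)
    rich = rng.poisson(10.0, n).astype(float)
    eta = beta["intercept"] + beta["prop_migratory"] * mig + beta["fruit_richness"] * rich
    y = rng.poisson(np.exp(np.clip(eta, -20, 20))).astype(float)
    periods = [f"P{t:02d}" for t in range(n)]
    cov = pd.DataFrame(
        {
            "period": periods,
            "prop_migratory": mig,
            "fruit_richness": rich,
            "fruit_abundance": rng.uniform(1.0, 5.0, n),
        }
    )
    resp = pd.DataFrame({"period": periods, "response": y})
    return RecoveryBundle(covariates=cov, response_table=resp, true_beta=beta)
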