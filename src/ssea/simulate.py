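"""Seeded generators emulating factorial multiple-driver experiments.

Three scenario families are covered, all fully reproducible from a seed:

* a marine-heatwave larval survival experiment — two crab species, larvae
  from three females each, four temperature treatments (constant low T1,
  gradual increase T2, constant high T3, sharp-step heatwave T4) crossed
  with three environmental contexts (optimal, food limitation, low
  salinity), five replicate groups of 10-11 larvae per cell, binomial
  survival with logit-linear treatment effects, and per-death day records;
* a genotype growth panel — continuous responses of a set of genotypes
  (default 13, as in a bryozoan warming x acidification panel) with
  configurable per-genotype (f1, f2, g) truths;
* a time-evolving synergy — a 2x2 temperature x habitat-quality surface
  whose interactive effect grows sigmoidally through time while the
  good-habitat temperature effect stays constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .dataset import FactorialDataset, SSEAError

__all__ = [
    "HeatwaveDesign",
    "EffectConfig",
    "TemperatureProfile",
    "TimeEvolutionConfig",
    "default_heatwave_effects",
    "gen_heatwave_experiment",
    "gen_temperature_profiles",
    "gen_genotype_panel",
    "gen_time_evolution",
    "DEFAULT_GENOTYPE_TRUTHS",
]

#: treatment -> (temperature regime, temperature level); T4 is the heatwave
TREATMENT_FACTORS: dict[str, tuple[str, str]] = {
    "T1": ("steady", "low"),
    "T2": ("changing", "low"),
    "T3": ("steady", "high"),
    "T4": ("changing", "high"),
}

DEFAULT_CONTEXTS = ("optimal", "food_limited", "low_salinity")
DEFAULT_SPECIES = ("cold_adapted", "warm_adapted")


@dataclass(frozen=True)
class HeatwaveDesign:
    """Structure of the simulated heatwave survival experiment.

    Defaults give 180 replicate units per species: 3 females x 4 temperature
    treatments x (3 contexts x 5 replicates).
    """

    n_species: int = 2
    n_females: int = 3
    n_temperature_treatments: int = 4
    n_contexts: int = 3
    n_replicates_per_cell: int = 5
    group_size_range: tuple[int, int] = (10, 11)
    window_days: int = 6
    increase_day: int = 2  # day the T4 temperature step is applied

    def __post_init__(self) -> None:
        if self.n_temperature_treatments != 4:
            raise SSEAError("the design uses the four treatments T1-T4")
        lo, hi = self.group_size_range
        if not (1 <= lo <= hi):
            raise SSEAError("invalid group_size_range")

    @property
    def replicate_units_per_species(self) -> int:
        return (
            self.n_females
            * self.n_temperature_treatments
            * self.n_replicates_per_cell
            * self.n_contexts
        )

    def species_labels(self) -> list[str]:
        base = list(DEFAULT_SPECIES)
        return [
            base[i] if i < len(base) else f"species{i + 1}"
            for i in range(self.n_species)
        ]

    def context_labels(self) -> list[str]:
        base = list(DEFAULT_CONTEXTS)
        return [
            base[i] if i < len(base) else f"context{i + 1}"
            for i in range(self.n_contexts)
        ]


@dataclass(frozen=True)
class EffectConfig:
    """Generative truth for one species x context, on the logit scale."""

    baseline_survival: float = 0.9
    regime_effect: float = 0.0
    level_effect: float = 0.0
    heatwave_interaction: float = 0.0
    fraction_deaths_after_increase: float = 0.5

    def cell_probability(self, regime: str, level: str) -> float:
        changing = 1.0 if regime == "changing" else 0.0
        high = 1.0 if level == "high" else 0.0
        if self.baseline_survival in (0.0, 1.0):
            if self.regime_effect or self.level_effect or self.heatwave_interaction:
                raise SSEAError(
                    "degenerate baseline survival with nonzero effects gives "
                    "an undefined logit-linear probability"
                )
            return self.baseline_survival
        eta = (
            logit(self.baseline_survival)
            + self.regime_effect * changing
            + self.level_effect * high
            + self.heatwave_interaction * changing * high
        )
        p = float(expit(eta))
        if not 0.0 < p < 1.0:
            raise SSEAError(
                f"implied survival probability {p} outside (0,1) for cell "
                f"(regime={regime}, level={level})"
            )
        return p


def default_heatwave_effects() -> dict[tuple[str, str], EffectConfig]:
    """Generative truths emulating the study system.

    The cold-adapted species suffers a heatwave-specific survival drop under
    food limitation (negative regime x level interaction on the logit scale,
    deaths concentrated after the temperature step); the warm-adapted
    competitor survives uniformly well (> 80%) with no treatment effects.
    """
    cold = {
        "optimal": EffectConfig(0.92, -0.1, -0.2, 0.0, 0.5),
        "food_limited": EffectConfig(0.80, -0.2, -0.3, -1.8, 0.85),
        "low_salinity": EffectConfig(0.85, -0.1, -0.2, 0.0, 0.5),
    }
    warm = {c: EffectConfig(0.93, 0.0, 0.0, 0.0, 0.5) for c in DEFAULT_CONTEXTS}
    out: dict[tuple[str, str], EffectConfig] = {}
    for c, e in cold.items():
        out[("cold_adapted", c)] = e
    for c, e in warm.items():
        out[("warm_adapted", c)] = e
    return out


def _effects_for(
    effects, species: str, context: str
) -> EffectConfig:
    if isinstance(effects, EffectConfig):
        return effects
    if isinstance(effects, Mapping):
        for key in ((species, context), species, context):
            if key in effects:
                return effects[key]
        raise SSEAError(f"no effect config for species={species}, context={context}")
    raise SSEAError("effects must be an EffectConfig or a mapping")


def gen_heatwave_experiment(
    design: HeatwaveDesign = HeatwaveDesign(),
    effects: EffectConfig | Mapping = None,
    seed: int = 0,
) -> tuple[FactorialDataset, pd.DataFrame]:
    """Simulate the heatwave survival experiment.

    Returns the replicate-level dataset (response = proportion surviving,
    with ``n_trials`` group sizes) and a long death-timing table with one
    row per dead larva (columns species, female, context, treatment,
    replicate, death_day).  For the heatwave treatment the configured
    fraction of deaths falls on or after the day the step is applied; deaths
    in other treatments are spread uniformly over the development window.
    """
    if effects is None:
        effects = default_heatwave_effects()
    rng = np.random.default_rng(seed)
    lo, hi = design.group_size_range
    rows = []
    deaths = []
    for species in design.species_labels():
        for female_i in range(design.n_females):
            female = f"F{female_i + 1}"
            for context in design.context_labels():
                cfg = _effects_for(effects, species, context)
                for treatment in ("T1", "T2", "T3", "T4"):
                    regime, level = TREATMENT_FACTORS[treatment]
                    p = cfg.cell_probability(regime, level)
                    for rep in range(design.n_replicates_per_cell):
                        size = int(rng.integers(lo, hi + 1))
                        survivors = int(rng.binomial(size, p))
                        n_dead = size - survivors
                        rows.append(
                            {
                                "unit": f"{species}/{female}",
                                "context": context,
                                "driver1": regime,
                                "driver2": level,
                                "replicate": f"R{rep + 1}",
                                "response": survivors / size,
                                "n_trials": size,
                                "species": species,
                                "female": female,
                                "treatment": treatment,
                                "regime": regime,
                                "level": level,
                                "n_survivors": survivors,
                            }
                        )
                        if n_dead == 0:
                            continue
                        if treatment == "T4":
                            n_after = int(
                                rng.binomial(n_dead, cfg.fraction_deaths_after_increase)
                            )
                            days = np.concatenate(
                                [
                                    np.full(n_dead - n_after, 1, dtype=int),
                                    rng.integers(
                                        design.increase_day,
                                        design.window_days + 1,
                                        size=n_after,
                                    ),
                                ]
                            )
                        else:
                            days = rng.integers(1, design.window_days + 1, size=n_dead)
                        for d in days:
                            deaths.append(
                                {
                                    "species": species,
                                    "female": female,
                                    "context": context,
                                    "treatment": treatment,
                                    "replicate": f"R{rep + 1}",
                                    "death_day": int(d),
                                }
                            )
    death_df = pd.DataFrame(
        deaths,
        columns=["species", "female", "context", "treatment", "replicate", "death_day"],
    )
    return FactorialDataset(pd.DataFrame(rows), copy=False), death_df


@dataclass(frozen=True)
class TemperatureProfile:
    """Daily temperatures (deg C) of one treatment over the larval window."""

    treatment: str
    daily_values: tuple[float, ...]

    @property
    def mean(self) -> float:
        return float(np.mean(self.daily_values))


def gen_temperature_profiles(
    window_days: int = 6,
    t_low: float = 15.0,
    t_high: float = 18.0,
) -> list[TemperatureProfile]:
    """Construct the four temperature-treatment profiles.

    T2 is a continuous linear ramp from ``t_low`` to ``t_high`` across the
    window (0.5 deg C/day for the default 15->18 over 6 days), recorded as
    day-midpoint values so its daily mean equals the ramp average
    ``(t_low + t_high) / 2``.  T4 is the heatwave step: day 1 at ``t_low``,
    every later day at ``t_high``.  T1 and T3 are constant controls at the
    T2 and T4 means respectively (16.5 and 17.5 deg C by default).
    """
    if window_days < 2:
        raise SSEAError("window_days must be >= 2")
    step = (t_high - t_low) / window_days
    t2 = tuple(t_low + step * (i + 0.5) for i in range(window_days))
    t4 = (t_low,) + (t_high,) * (window_days - 1)
    t1 = (float(np.mean(t2)),) * window_days
    t3 = (float(np.mean(t4)),) * window_days
    return [
        TemperatureProfile("T1", t1),
        TemperatureProfile("T2", t2),
        TemperatureProfile("T3", t3),
        TemperatureProfile("T4", t4),
    ]


# per-genotype (f1, f2, g) truths spanning double-negative, double-positive
# and opposite-direction single effects with synergistic and antagonistic
# deviations, in arbitrary growth units
DEFAULT_GENOTYPE_TRUTHS: tuple[tuple[float, float, float], ...] = (
    (-0.60, -0.30, -0.40),
    (-0.52, -0.10, -0.15),
    (-0.45, 0.15, 0.20),
    (-0.40, -0.25, 0.35),
    (-0.33, 0.20, -0.25),
    (-0.27, -0.05, 0.10),
    (-0.20, 0.10, -0.05),
    (-0.15, -0.20, 0.30),
    (-0.08, 0.25, -0.20),
    (-0.02, -0.15, 0.15),
    (0.05, 0.05, 0.25),
    (0.10, -0.35, -0.30),
    (0.18, 0.30, 0.05),
)


def gen_genotype_panel(
    n_genotypes: int = 13,
    truths: Sequence[tuple[float, float, float]] | None = None,
    baseline: float = 1.0,
    noise_sd: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
    driver1_levels: tuple[str, str] = ("ambient", "warm"),
    driver2_levels: tuple[str, str] = ("pH8.1", "pH7.8"),
) -> FactorialDataset:
    """Simulate a genotype panel of continuous 2x2 responses.

    Each genotype's response in cell (x1, x2) is
    ``baseline + f1*x1 + f2*x2 + g*x1*x2 + Gaussian noise`` with indicator
    coding, so a noiseless panel decomposes back to the configured truths
    exactly.
    """
    if n_genotypes < 1:
        raise SSEAError("n_genotypes must be >= 1")
    if noise_sd < 0:
        raise SSEAError("noise_sd must be nonnegative")
    if truths is None:
        base = DEFAULT_GENOTYPE_TRUTHS
        truths = tuple(base[i % len(base)] for i in range(n_genotypes))
    if len(truths) != n_genotypes:
        raise SSEAError("need one (f1, f2, g) triple per genotype")
    rng = np.random.default_rng(seed)
    labels = [
        chr(ord("A") + i) if i < 26 else f"G{i + 1}" for i in range(n_genotypes)
    ]
    rows = []
    for geno, (f1, f2, g) in zip(labels, truths):
        for x1, lv1 in enumerate(driver1_levels):
            for x2, lv2 in enumerate(driver2_levels):
                mu = baseline + f1 * x1 + f2 * x2 + g * x1 * x2
                for rep in range(n_replicates):
                    y = mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    rows.append(
                        {
                            "unit": geno,
                            "context": "",
                            "driver1": lv1,
                            "driver2": lv2,
                            "replicate": f"R{rep + 1}",
                            "response": y,
                        }
                    )
    return FactorialDataset(pd.DataFrame(rows), copy=False)


@dataclass(frozen=True)
class TimeEvolutionConfig:
    """A 2x2 temperature x habitat surface evolving through time.

    The reference is the best condition (control temperature, good habitat).
    The good-habitat temperature effect is a small constant; in the poor
    habitat the interactive deviation follows a logistic curve
    ``asymptote / (1 + exp(-slope * (t - midpoint)))``, nondecreasing in
    time for a nonnegative slope.  Units are arbitrary.
    """

    n_timepoints: int = 10
    baseline: float = 10.0
    good_habitat_temperature_effect: float = 0.5
    habitat_effect: float = -1.0
    asymptote: float = 4.0
    midpoint: float = 5.0
    slope: float = 1.2
    noise_sd: float = 0.0
    n_replicates: int = 1
    seed: int = 0
    temperature_levels: tuple[str, str] = ("10C", "elevated")
    habitat_levels: tuple[str, str] = ("good", "poor")

    def g_true(self, t: float) -> float:
        return float(self.asymptote / (1.0 + np.exp(-self.slope * (t - self.midpoint))))


def gen_time_evolution(
    config: TimeEvolutionConfig = TimeEvolutionConfig(),
) -> tuple[list[FactorialDataset], pd.DataFrame]:
    """Simulate the time evolution of a synergistic 2x2 response.

    Returns one dataset per time point plus the underlying true surface
    (columns t, f1, f2, g, and the four cell means).
    """
    if config.slope < 0:
        raise SSEAError("slope must be nonnegative (g must not decrease in time)")
    rng = np.random.default_rng(config.seed)
    datasets = []
    truth_rows = []
    f1 = config.good_habitat_temperature_effect
    f2 = config.habitat_effect
    for t in range(1, config.n_timepoints + 1):
        g = config.g_true(t)
        cells = {
            (0, 0): config.baseline,
            (1, 0): config.baseline + f1,
            (0, 1): config.baseline + f2,
            (1, 1): config.baseline + f1 + f2 + g,
        }
        rows = []
        for (x1, x2), mu in cells.items():
            for rep in range(config.n_replicates):
                y = mu + (
                    rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
                )
                rows.append(
                    {
                        "unit": "system",
                        "context": f"t{t:02d}",
                        "driver1": config.temperature_levels[x1],
                        "driver2": config.habitat_levels[x2],
                        "replicate": f"R{rep + 1}",
                        "response": y,
                    }
                )
        datasets.append(FactorialDataset(pd.DataFrame(rows), copy=False))
        truth_rows.append(
            {
                "t": t,
                "f1": f1,
                "f2": f2,
                "g": g,
                "r00": cells[(0, 0)],
                "r10": cells[(1, 0)],
                "r01": cells[(0, 1)],
                "r11": cells[(1, 1)],
            }
        )
    return datasets, pd.DataFrame(truth_rows)
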