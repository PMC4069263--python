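"""Synthetic data with known ground truth for the diet-switch design.

Two generators emulate the statistical structure of the study:

* :func:`generate_expression` draws a genes x samples log2 expression matrix
  for the CF / RF / SF cohorts over the 12 post-switch sampling hours, with
  each gene following one of seven temporal archetypes (null, fast switching
  up/down, refractory, responsive, deviating, slow/partial switching).
* :func:`generate_cohorts` draws per-fly survival records under Gompertz
  mortality, with the SF cohort's hazard moving from the CF to the RF level
  over a configurable lag after the diet switch, plus scheduled censoring for
  the flies removed at sampling times.

Both are fully deterministic given their seed, and both return a truth table
so downstream stages can be scored against the generating model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import COHORTS, ExpressionMatrix

#: the study's post-switch sampling grid, in hours
DEFAULT_TIMEPOINTS: tuple[float, ...] = (2, 4, 6, 8, 12, 18, 24, 32, 40, 48, 56, 72)

ARCHETYPES = ("null", "switch_up", "switch_down", "refractory",
              "responsive", "deviating", "slow_switch")

#: default archetype proportions, loosely mirroring the study: most genes are
#: diet-independent, fast switchers skew 2:1 down vs up, refractory genes are
#: the largest diet-dependent class after the slow/partial tail.
DEFAULT_MIX: dict[str, float] = {
    "null": 0.88,
    "switch_up": 0.01,
    "switch_down": 0.02,
    "refractory": 0.03,
    "responsive": 0.01,
    "deviating": 0.01,
    "slow_switch": 0.04,
}

#: category each archetype should land in under the three-comparison logic
#: when effects are well resolved (a slow logistic is significantly different
#: from both CF and RF over the 72 h window, hence Category III)
EXPECTED_CATEGORY = {
    "null": "V",
    "switch_up": "I",
    "switch_down": "I",
    "refractory": "II",
    "responsive": "III",
    "deviating": "IV",
    "slow_switch": "III",
}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class SimulationError(RuntimeError):
    """Simulation cannot honor the configuration (e.g. censoring overdraw)."""


@dataclass
class ExprSimConfig:
    """Settings for the expression-matrix generator.

    delta is the log2 RF-minus-CF offset of an affected gene, tau the fast
    logistic time constant in hours, sigma the residual noise SD in log2
    units. t0_fast places the fast logistic midpoint so that fast switchers
    complete within 4-6 h; t0_slow/tau_slow shape the slow/partial archetype
    that has not completed by 72 h.
    """

    n_genes: int = 2000
    archetype_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    delta: float = 1.0
    tau: float = 1.0
    sigma: float = 0.25
    t0_fast: float = 2.0
    t0_slow: float = 36.0
    tau_slow: float = 24.0
    responsive_level: float = 0.5
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS
    replicates_per_point: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")
        unknown = set(self.archetype_mix) - set(ARCHETYPES)
        if unknown:
            raise ConfigurationError(f"unknown archetypes: {sorted(unknown)}")
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"archetype proportions sum to {total}, not 1")
        if any(v < 0 for v in self.archetype_mix.values()):
            raise ConfigurationError("archetype proportions must be >= 0")
        tp = np.asarray(self.timepoints, dtype=float)
        if len(tp) < 2 or np.any(np.diff(tp) <= 0):
            raise ConfigurationError("timepoints must be strictly increasing, >= 2")
        if self.replicates_per_point < 1:
            raise ConfigurationError("replicates_per_point must be >= 1")


def logistic_fraction(t: np.ndarray | float, t0: float, tau: float) -> np.ndarray:
    """Completion fraction 1 / (1 + exp(-(t - t0)/tau)) of a switching gene."""
    t = np.asarray(t, dtype=float)
    return 1.0 / (1.0 + np.exp(-(t - t0) / tau))


def archetype_fraction(archetype: str, t: np.ndarray, config: ExprSimConfig) -> np.ndarray:
    """SF completion fraction f(t) toward the RF offset for one archetype."""
    t = np.asarray(t, dtype=float)
    if archetype in ("switch_up", "switch_down"):
        return logistic_fraction(t, config.t0_fast, config.tau)
    if archetype == "slow_switch":
        return logistic_fraction(t, config.t0_slow, config.tau_slow)
    if archetype == "refractory":
        return np.zeros_like(t)
    if archetype == "responsive":
        return np.full_like(t, config.responsive_level)
    if archetype in ("null", "deviating"):
        # deviating genes carry a separate SF-only offset; the RF offset is 0
        return np.zeros_like(t)
    raise ConfigurationError(f"unknown archetype {archetype!r}")


def generate_expression(config: ExprSimConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate the three-cohort time course; returns (matrix, truth table).

    Per gene g with baseline mu_g ~ U(4, 12): CF samples ~ N(mu_g, sigma^2);
    RF samples ~ N(mu_g + delta_g, sigma^2); SF samples at hour t ~
    N(mu_g + delta_g * f(t) + offset_g * [deviating], sigma^2), where f is the
    archetype's completion fraction. Signs: switch_up has delta_g = +delta,
    switch_down -delta; refractory / responsive / slow_switch draw the sign at
    random; deviating genes have delta_g = 0 but a signed SF-only offset.
    """
    rng = np.random.default_rng(config.seed)
    names = list(config.archetype_mix)
    probs = np.array([config.archetype_mix[a] for a in names], dtype=float)
    archetypes = rng.choice(names, size=config.n_genes, p=probs / probs.sum())
    mu = rng.uniform(4.0, 12.0, size=config.n_genes)
    signs = rng.choice([-1.0, 1.0], size=config.n_genes)

    delta_rf = np.zeros(config.n_genes)
    sf_offset = np.zeros(config.n_genes)
    for i, a in enumerate(archetypes):
        if a == "switch_up":
            delta_rf[i] = config.delta
        elif a == "switch_down":
            delta_rf[i] = -config.delta
        elif a in ("refractory", "responsive", "slow_switch"):
            delta_rf[i] = signs[i] * config.delta
        elif a == "deviating":
            sf_offset[i] = signs[i] * config.delta

    times = np.asarray(config.timepoints, dtype=float)
    reps = config.replicates_per_point
    frac = np.stack([archetype_fraction(a, times, config) for a in archetypes])

    columns, blocks = [], []
    for cohort in COHORTS:
        if cohort == "CF":
            level = np.repeat(mu[:, None], len(times), axis=1)
        elif cohort == "RF":
            level = np.repeat((mu + delta_rf)[:, None], len(times), axis=1)
        else:  # SF
            level = mu[:, None] + delta_rf[:, None] * frac + sf_offset[:, None]
        for j, t in enumerate(times):
            for r in range(1, reps + 1):
                columns.append(f"{cohort}_t{int(t):02d}_r{r}")
                blocks.append(level[:, j])
    values = np.column_stack(blocks)
    if config.sigma > 0:
        values = values + rng.normal(0.0, config.sigma, size=values.shape)

    gene_ids = [f"g{i:05d}" for i in range(1, config.n_genes + 1)]
    frame = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                         columns=columns)
    metadata = pd.DataFrame(
        {
            "cohort": [c.split("_")[0] for c in columns],
            "time_h": [float(c.split("_t")[1].split("_r")[0]) for c in columns],
            "replicate": [int(c.rsplit("_r", 1)[1]) for c in columns],
        },
        index=pd.Index(columns, name="sample_id"),
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "archetype": archetypes,
            "expected_category": [EXPECTED_CATEGORY[a] for a in archetypes],
            "mu": mu,
            "delta_rf": delta_rf,
            "sf_offset": sf_offset,
        }
    )
    return ExpressionMatrix(frame, metadata), truth


# ---------------------------------------------------------------------------
# survival cohorts


@dataclass
class CohortSimConfig:
    """Settings for the Gompertz survival-cohort generator.

    The CF hazard is a * exp(b * day) per day; RF multiplies it by
    dr_hazard_fold (< 1 for protective dietary restriction); SF follows the CF
    hazard before switch_day and then interpolates linearly in hazard to the
    RF level over convergence_lag days. censor_schedule maps a cohort to
    (day, count) pairs: that many live flies are censored after the day's
    deaths are recorded, emulating removal for sampling.
    """

    n_flies: int = 3000
    gompertz_a: float = 0.002
    gompertz_b: float = 0.06
    dr_hazard_fold: float = 0.5
    switch_day: int = 40
    convergence_lag: int = 3
    censor_schedule: Mapping[str, Sequence[tuple[int, int]]] | None = None
    max_day: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise ConfigurationError("n_flies must be >= 1")
        if self.gompertz_a <= 0:
            raise ConfigurationError("gompertz_a must be > 0")
        if not (0 < self.dr_hazard_fold <= 1):
            raise ConfigurationError("dr_hazard_fold must be in (0, 1]")
        if self.switch_day < 1:
            raise ConfigurationError("switch_day must be >= 1")
        if self.convergence_lag < 0:
            raise ConfigurationError("convergence_lag must be >= 0")
        if self.censor_schedule:
            for cohort, pairs in self.censor_schedule.items():
                if cohort not in COHORTS:
                    raise ConfigurationError(f"unknown cohort {cohort!r} in censor_schedule")
                for day, count in pairs:
                    if day < 1 or count < 0:
                        raise ConfigurationError("censor days >= 1, counts >= 0")


def cohort_hazards(config: CohortSimConfig) -> dict[str, Callable[[float], float]]:
    """True per-day hazard functions for the three cohorts."""
    a, b, fold = config.gompertz_a, config.gompertz_b, config.dr_hazard_fold
    s, lag = config.switch_day, config.convergence_lag

    def h_cf(day: float) -> float:
        return a * math.exp(b * day)

    def h_rf(day: float) -> float:
        return fold * a * math.exp(b * day)

    def h_sf(day: float) -> float:
        if day < s:
            return h_cf(day)
        # one interpolation step per day on the new diet: w = 1 on the day the
        # trajectory reaches RF (switch_day + lag; immediately when lag = 0)
        w = min(1.0, (day - s + 1) / (lag + 1))
        return (1 - w) * h_cf(day) + w * h_rf(day)

    return {"CF": h_cf, "RF": h_rf, "SF": h_sf}


def generate_cohorts(config: CohortSimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate per-fly survival for CF, RF and SF; returns (events, truth).

    Each day, every live fly dies with probability 1 - exp(-h(day)); scheduled
    censoring then removes live flies. Flies still alive at max_day are
    censored there, so deaths + censored = n_flies per cohort. The events
    frame has one row per fly: (fly_id, cohort, day, status).
    """
    rng = np.random.default_rng(config.seed)
    hazards = cohort_hazards(config)
    schedule = {c: dict() for c in COHORTS}
    if config.censor_schedule:
        for cohort, pairs in config.censor_schedule.items():
            for day, count in pairs:
                schedule[cohort][int(day)] = schedule[cohort].get(int(day), 0) + int(count)

    records: list[tuple[str, str, int, str]] = []
    for cohort in COHORTS:
        h = hazards[cohort]
        event_day = np.full(config.n_flies, config.max_day, dtype=int)
        status = np.full(config.n_flies, "censored", dtype=object)
        alive = np.ones(config.n_flies, dtype=bool)
        for day in range(1, config.max_day + 1):
            idx = np.flatnonzero(alive)
            if idx.size == 0:
                break
            p = 1.0 - math.exp(-h(day))
            dies = rng.random(idx.size) < p
            died = idx[dies]
            event_day[died] = day
            status[died] = "death"
            alive[died] = False
            n_censor = schedule[cohort].get(day, 0)
            if n_censor:
                survivors = np.flatnonzero(alive)
                if n_censor > survivors.size:
                    raise SimulationError(
                        f"cannot censor {n_censor} flies from cohort {cohort} on day "
                        f"{day}: only {survivors.size} alive")
                chosen = survivors[:n_censor]
                event_day[chosen] = day
                status[chosen] = "censored"
                alive[chosen] = False
        for i in range(config.n_flies):
            records.append((f"{cohort}_{i + 1:05d}", cohort, int(event_day[i]), status[i]))

    events = pd.DataFrame(records, columns=["fly_id", "cohort", "day", "status"])
    truth = {
        "hazards": hazards,
        "params": {
            "gompertz_a": config.gompertz_a,
            "gompertz_b": config.gompertz_b,
            "dr_hazard_fold": config.dr_hazard_fold,
            "switch_day": config.switch_day,
            "convergence_lag": config.convergence_lag,
        },
    }
    return events, truth


# ---------------------------------------------------------------------------
# TSV writers matching the package's external file contracts


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
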