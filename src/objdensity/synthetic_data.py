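"""Seeded generators for object populations and observer cohorts.

Object populations: volumes log-uniform over a configured range, with
density following a power law of volume, d = c * V**gamma, with
multiplicative lognormal scatter; weight = density * volume, so the
ratio identity DR = WR - VR holds by construction on derived pairs.

Observer cohorts: each simulated subject reports pair ratios relative to
a reference of 10.  Perceived-volume (PV) reports compress the true log
volume ratio by a factor beta; expected-weight (EW) reports add a
density-prior term (a :class:`~objdensity.pair_ratios.RatioLine`)
evaluated, by default, at the perceived (compressed) log volume ratio.
Everything is bit-reproducible given a config and its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .density_stats import fit_power_law
from .objects_io import DATASET_CLASSES, ObjectRecord, ObjectTable
from .pair_ratios import (
    STIMULUS_PAIRS,
    STIMULUS_VOLUMES,
    RatioLine,
    build_pairs,
    fit_ratio_line,
    stimulus_pair_table,
)
from .perception_stats import (
    GROUPS,
    OBJECT_SETS,
    ORDERS,
    REFERENCE_UNITS,
    TRIAL_COLUMNS,
    mixed_anova,
    subject_pair_means,
)


@dataclass(frozen=True)
class EnvGenConfig:
    """Configuration of a synthetic environmental object population."""

    n_objects: int = 195
    volume_log_range: tuple[float, float] = (0.0, 9.0)  # ln cm^3
    density_coefficient: float = 2.0  # g/cm^3 at V = 1 cm^3
    density_exponent: float = -0.387
    log_noise_sd: float = 0.5
    seed: int = 0
    dataset: str = "D1"

    def __post_init__(self) -> None:
        if self.n_objects < 3:
            raise ValueError("n_objects must be >= 3")
        if self.log_noise_sd < 0:
            raise ValueError("log_noise_sd must be >= 0")
        lo, hi = self.volume_log_range
        if not lo < hi:
            raise ValueError("volume_log_range must be nondegenerate")
        if self.density_coefficient <= 0:
            raise ValueError("density_coefficient must be > 0")
        if self.dataset not in DATASET_CLASSES:
            raise ValueError(f"unknown dataset {self.dataset!r}")


def gen_env_objects(config: EnvGenConfig) -> ObjectTable:
    """Generate an :class:`ObjectTable` from a power-law density model."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.volume_log_range
    volumes = np.exp(rng.uniform(lo, hi, config.n_objects))
    noise = (
        rng.normal(0.0, config.log_noise_sd, config.n_objects)
        if config.log_noise_sd > 0
        else np.zeros(config.n_objects)
    )
    densities = (
        config.density_coefficient
        * volumes ** config.density_exponent
        * np.exp(noise)
    )
    weights = densities * volumes
    category, liftable = DATASET_CLASSES[config.dataset]
    records = [
        ObjectRecord(
            id=f"syn-{config.seed}-{i:04d}",
            name=f"synthetic object {i}",
            dataset=config.dataset,
            category=category,
            liftable=liftable,
            volume=float(volumes[i]),
            weight=float(weights[i]),
            volume_method="mesh_scan",
        )
        for i in range(config.n_objects)
    ]
    return ObjectTable(records, provenance=f"synthetic seed={config.seed}")


@dataclass(frozen=True)
class ObserverGenConfig:
    """Configuration of a simulated EW/PV observer cohort."""

    n_per_group: int = 10
    compression_beta: float = 0.85
    prior_line: RatioLine = field(
        default_factory=lambda: RatioLine(-0.387, 0.114, "density")
    )
    report_log_noise_sd: float = 0.25
    trials_per_cell: int = 10
    seed: int = 0
    prior_on_perceived: bool = True  # evaluate the prior at the compressed VR
    quantize_reports: bool = False  # round reports to whole units

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not 0.0 < self.compression_beta <= 1.0:
            raise ValueError("compression_beta must be in (0, 1]")
        if self.report_log_noise_sd < 0:
            raise ValueError("report_log_noise_sd must be >= 0")
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")
        if self.prior_line.kind != "density":
            raise ValueError("prior_line must be a density line")


def gen_observer_trials(
    config: ObserverGenConfig,
    stimulus_volumes: dict[str, tuple[float, float, float, float]] | None = None,
) -> pd.DataFrame:
    """Simulate a complete factorial cohort of ratio-report trials.

    Every (subject, object set, pair, order) cell receives
    ``trials_per_cell`` trials.  The canonical log small/large ratio of a
    trial is

        PV:  beta * VR + noise
        EW:  beta * VR + prior(beta * VR) + noise

    with prior(v) = slope_d * v + intercept_d, evaluated at the true VR
    instead when ``prior_on_perceived`` is False.  The log ratio is then
    re-expressed as a report in reference-10 units honoring the
    presentation order.
    """
    volumes = STIMULUS_VOLUMES if stimulus_volumes is None else stimulus_volumes
    for name in OBJECT_SETS:
        if name not in volumes:
            raise ValueError(f"missing stimulus volumes for {name!r}")
    vr = {
        name: {p: math.log(r) for p, r in stimulus_pair_table(volumes[name]).items()}
        for name in OBJECT_SETS
    }
    rng = np.random.default_rng(config.seed)
    slope_d, icpt_d = config.prior_line.slope, config.prior_line.intercept
    rows = []
    for group in GROUPS:
        for si in range(config.n_per_group):
            subject = f"{group}{si + 1:02d}"
            for oset in OBJECT_SETS:
                for pair in STIMULUS_PAIRS:
                    v = vr[oset][pair]
                    perceived = config.compression_beta * v
                    mean_log = perceived
                    if group == "EW":
                        at = perceived if config.prior_on_perceived else v
                        mean_log += slope_d * at + icpt_d
                    for order in ORDERS:
                        noise = (
                            rng.normal(0.0, config.report_log_noise_sd,
                                       config.trials_per_cell)
                            if config.report_log_noise_sd > 0
                            else np.zeros(config.trials_per_cell)
                        )
                        log_ratio = mean_log + noise
                        if order == "S-L":
                            report = REFERENCE_UNITS * np.exp(-log_ratio)
                        else:
                            report = REFERENCE_UNITS * np.exp(log_ratio)
                        if config.quantize_reports:
                            report = np.maximum(np.rint(report), 1.0)
                        rows.extend(
                            {
                                "subject": subject,
                                "group": group,
                                "object_set": oset,
                                "pair": pair,
                                "order": order,
                                "report": float(r),
                            }
                            for r in report
                        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def recovery_experiment(
    env_config: EnvGenConfig | None = None,
    observer_config: ObserverGenConfig | None = None,
    n_replicates: int = 100,
    seed: int = 0,
) -> dict:
    """Replicate generation + analysis and summarize parameter recovery.

    For each replicate (seeded independently from ``seed``):

    * environmental part — generate a population, fit the density power
      law and the pair weight-ratio line; collect recovered gamma and
      line slope;
    * observer part — simulate a cohort, run the split-plot ANOVA and
      collect the condition-effect p-value.

    Returns a dict with per-replicate arrays and bias/RMSE/rejection-rate
    summaries for whichever parts were configured.
    """
    if env_config is None and observer_config is None:
        raise ValueError("configure at least one of env/observer parts")
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_replicates)
    report: dict = {"n_replicates": n_replicates, "seed": seed}

    if env_config is not None:
        gammas = np.empty(n_replicates)
        slopes = np.empty(n_replicates)
        for i in range(n_replicates):
            cfg = EnvGenConfig(
                n_objects=env_config.n_objects,
                volume_log_range=env_config.volume_log_range,
                density_coefficient=env_config.density_coefficient,
                density_exponent=env_config.density_exponent,
                log_noise_sd=env_config.log_noise_sd,
                seed=int(seeds[i]),
                dataset=env_config.dataset,
            )
            table = gen_env_objects(cfg)
            gammas[i] = fit_power_law(table).gamma
            slopes[i] = fit_ratio_line(build_pairs(table), "weight").slope
        truth = env_config.density_exponent
        report["env"] = {
            "gamma_true": truth,
            "gamma_recovered": gammas,
            "gamma_bias": float(gammas.mean() - truth),
            "gamma_rmse": float(np.sqrt(np.mean((gammas - truth) ** 2))),
            "weight_slope_recovered": slopes,
            "weight_slope_true": 1.0 + truth,
        }

    if observer_config is not None:
        pvals = np.empty(n_replicates)
        for i in range(n_replicates):
            cfg = ObserverGenConfig(
                n_per_group=observer_config.n_per_group,
                compression_beta=observer_config.compression_beta,
                prior_line=observer_config.prior_line,
                report_log_noise_sd=observer_config.report_log_noise_sd,
                trials_per_cell=observer_config.trials_per_cell,
                seed=int(seeds[n_replicates + i]),
                prior_on_perceived=observer_config.prior_on_perceived,
                quantize_reports=observer_config.quantize_reports,
            )
            trials = gen_observer_trials(cfg)
            table = mixed_anova(subject_pair_means(trials))
            pvals[i] = table["condition"].p
        report["observer"] = {
            "condition_p": pvals,
            "rejection_rate_05": float(np.mean(pvals < 0.05)),
        }
    return report
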