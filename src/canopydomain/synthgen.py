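"""Synthetic behavioral-observation and survival data for the cage design.

Emulates the field experiment's structure: blocks of cages nested in years
(2015/2017/2018-style), a woodlouse presence treatment in every year, a
warming treatment only in the 2018-style year, half-hourly position records
between 07:00 and 19:00 (25 checks per animal per day), and end-of-season
binomial survival of the 2-3 grasshoppers stocked per cage.

Cage-level mean heights follow the same linear model the inference module
fits — species intercepts, year and block-in-year random deviations,
woodlouse/warming/interaction effects, and a correlated cage-level residual
— so generator/estimator round trips exercise the full pipeline with known
truth.  Default true effects use the spider woodlouse shift (+16.5 cm) and
warming x woodlouse interaction (-19.3 cm) as the study conditions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "generate_observations", "generate_survival",
           "OBSERVATION_TIMES"]

#: Observation schedule: every 30 minutes from 07:00 to 19:00 inclusive.
OBSERVATION_TIMES = tuple(range(7 * 60, 19 * 60 + 1, 30))  # 25 checks


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the generator.

    Baseline heights and within-cage spreads are the grasshopper 69 +/- 10 cm
    and spider 60 +/- 28 cm canopy distributions; woodlice draw from a
    ground-skewed gamma and are detected only rarely during the day.
    """

    years: tuple[int, ...] = (2015, 2017, 2018)
    blocks_per_year: int = 4
    cages_per_block: int = 5
    baseline_mefe: float = 69.0     # cm
    baseline_pimi: float = 60.0     # cm
    within_sd_mefe: float = 10.0    # cm, within-cage spread
    within_sd_pimi: float = 28.0    # cm
    beta_pimi_w: float = 16.5       # cm, woodlouse effect on spider height
    beta_pimi_t: float = 0.0
    beta_pimi_tw: float = -19.3     # cm, warming x woodlouse interaction
    beta_mefe_w: float = 0.0
    beta_mefe_t: float = 0.0
    beta_mefe_tw: float = 0.0
    year_sd_mefe: float = 3.0       # cm, year random-intercept sd
    year_sd_pimi: float = 6.0
    block_sd_mefe: float = 3.0      # cm, block-in-year random-intercept sd
    block_sd_pimi: float = 6.0
    resid_sd_mefe: float = 5.0      # cm, cage-level residual sd
    resid_sd_pimi: float = 12.0
    resid_corr: float = 0.2         # within-cage spider/grasshopper correlation
    woodlouse_shape: float = 1.0
    woodlouse_rate: float = 0.2     # per cm (mean 5 cm)
    woodlice_per_cage: int = 6
    woodlouse_detection_p: float = 0.02  # per half-hourly check
    n_spiders: int = 1
    survival_intercept: float = 1.5       # logit scale
    survival_slope: float = -10.0         # per cm^-1 of attack rate
    height_resolution: float = 0.5        # cm, field recording resolution

    def stocked_for_year(self, year: int) -> int:
        """Grasshoppers stocked per cage: 3 in the warmed-design year, else 2."""
        return 3 if year == max(self.years) else 2

    def config_digest(self) -> int:
        """Stable digest of the configuration, mixed into the random seed."""
        return zlib.crc32(repr(self).encode())


def _rng_for(config: SyntheticConfig, seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, config.config_digest(),
                                zlib.crc32(label.encode())])
    )


def _cage_design(config: SyntheticConfig) -> pd.DataFrame:
    """Deterministic treatment layout: W alternates within block; T only in
    the last year, assigned to the second half of each block."""
    rows = []
    for year in config.years:
        warmed_year = year == max(config.years)
        for b in range(config.blocks_per_year):
            block = f"{year}-B{b + 1}"
            for c in range(config.cages_per_block):
                rows.append({
                    "cage_id": f"{block}-C{c + 1}",
                    "block": block,
                    "year": year,
                    "woodlice": c % 2,
                    "warmed": int(warmed_year and c >= config.cages_per_block // 2),
                    "stocked": config.stocked_for_year(year),
                })
    return pd.DataFrame(rows)


def _round_to(x: np.ndarray, resolution: float) -> np.ndarray:
    return np.round(x / resolution) * resolution


def _truncated_normal(rng, mean, sd, size):
    """Normal draws redrawn until non-negative (heights cannot be below ground)."""
    out = rng.normal(mean, sd, size)
    bad = out < 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = out < 0
    return out


def generate_observations(config: SyntheticConfig, seed: int) -> pd.DataFrame:
    """Generate a half-hourly observation table for the full cage design.

    Per cage, draws the (spider, grasshopper) mean-height pair from the
    linear model with correlated residuals, then draws per-animal,
    per-time-point heights from the within-cage distributions (normal
    truncated at ground level, recorded at 0.5 cm resolution).  Woodlice in
    woodlouse cages appear sparsely (low daytime detection probability) with
    gamma-distributed heights.  Deterministic given ``seed`` and the config.
    """
    rng = _rng_for(config, seed, "observations")
    design = _cage_design(config)

    # random deviations shared across cages of a year / block
    year_dev = {
        y: (rng.normal(0.0, config.year_sd_mefe),
            rng.normal(0.0, config.year_sd_pimi))
        for y in config.years
    }
    block_dev = {
        blk: (rng.normal(0.0, config.block_sd_mefe),
              rng.normal(0.0, config.block_sd_pimi))
        for blk in design["block"].unique()
    }
    cov = np.array([
        [config.resid_sd_mefe**2,
         config.resid_corr * config.resid_sd_mefe * config.resid_sd_pimi],
        [config.resid_corr * config.resid_sd_mefe * config.resid_sd_pimi,
         config.resid_sd_pimi**2],
    ])

    records = []
    for row in design.itertuples():
        w, t = row.woodlice, row.warmed
        resid = rng.multivariate_normal([0.0, 0.0], cov)
        mean_mefe = (config.baseline_mefe + year_dev[row.year][0]
                     + block_dev[row.block][0]
                     + config.beta_mefe_t * t + config.beta_mefe_w * w
                     + config.beta_mefe_tw * t * w + resid[0])
        mean_pimi = (config.baseline_pimi + year_dev[row.year][1]
                     + block_dev[row.block][1]
                     + config.beta_pimi_t * t + config.beta_pimi_w * w
                     + config.beta_pimi_tw * t * w + resid[1])

        def emit(species, animal_heights):
            for heights in animal_heights:
                for time_min, z in zip(OBSERVATION_TIMES, heights):
                    records.append({
                        "cage_id": row.cage_id, "block": row.block,
                        "year": row.year, "woodlice": w, "warmed": t,
                        "species": species, "time_min": time_min,
                        "x_cm": np.nan, "y_cm": np.nan,
                        "z_cm": max(float(z), 0.0),
                        "behavior": "perch", "substrate": "vegetation",
                    })

        n_checks = len(OBSERVATION_TIMES)
        emit("PIMI", [
            _round_to(_truncated_normal(rng, max(mean_pimi, 0.0),
                                        config.within_sd_pimi, n_checks),
                      config.height_resolution)
            for _ in range(config.n_spiders)
        ])
        emit("MEFE", [
            _round_to(_truncated_normal(rng, max(mean_mefe, 0.0),
                                        config.within_sd_mefe, n_checks),
                      config.height_resolution)
            for _ in range(row.stocked)
        ])
        if w:
            detected = rng.random((config.woodlice_per_cage, n_checks)) \
                < config.woodlouse_detection_p
            n_det = int(detected.sum())
            if n_det:
                z_w = _round_to(
                    rng.gamma(config.woodlouse_shape,
                              1.0 / config.woodlouse_rate, n_det),
                    config.height_resolution)
                times = np.array(OBSERVATION_TIMES * config.woodlice_per_cage
                                 ).reshape(config.woodlice_per_cage, -1)[detected]
                for time_min, z in zip(times, z_w):
                    records.append({
                        "cage_id": row.cage_id, "block": row.block,
                        "year": row.year, "woodlice": w, "warmed": t,
                        "species": "ONAS", "time_min": int(time_min),
                        "x_cm": np.nan, "y_cm": np.nan, "z_cm": float(z),
                        "behavior": "forage", "substrate": "litter",
                    })
    return pd.DataFrame.from_records(records)


def generate_survival(cage_summaries: pd.DataFrame, config: SyntheticConfig,
                      seed: int) -> pd.DataFrame:
    """Binomial end-of-season survival per cage.

    survivors ~ Binomial(stocked, inverse-logit(alpha + beta_A * A)) with the
    cage's overlap-based attack rate A (per cm).  Requires a summary table
    with ``cage_id``, ``year`` and ``A`` columns.
    """
    rng = _rng_for(config, seed, "survival")
    rows = []
    for row in cage_summaries.itertuples():
        stocked = config.stocked_for_year(int(row.year))
        logit_p = config.survival_intercept + config.survival_slope * row.A
        p = 1.0 / (1.0 + np.exp(-logit_p))
        rows.append({
            "cage_id": row.cage_id,
            "year": int(row.year),
            "stocked": stocked,
            "survivors": int(rng.binomial(stocked, p)),
        })
    return pd.DataFrame(rows)
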