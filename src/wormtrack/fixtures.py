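"""Named phenotype fixtures for development and validation.

Profiles encode the qualitative contrasts seen in Go-alpha-pathway
locomotion screens: hyperactive mutants crawl faster with more frequent
reversals and spend time coiled, wild-type animals do neither, and a
rescue panel pairs solvent-matched wild-type, untreated-mutant and
drug-treated-mutant cohorts whose reversal rates bracket a partial rescue.
Everything is synthetic, generated from a seed at call time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as wio
from .simulate import (GroundTruth, ImageStack, SimulationConfig,
                       simulate_cohort, simulate_ground_truth)

# small arena keeps fixture stacks light while leaving room for steering
_FIXTURE_BASE = dict(
    arena_size=(384, 384),
    n_worms=2,
    duration=60.0,
    steer_margin=1500.0,
)

# mutant_like reversal rate is >= 2x wt_like and carries a nonzero coil share
PROFILES: dict[str, dict] = {
    "wt_like": dict(speed_mean=30.0, speed_sd=5.0, reversal_rate=1.5,
                    coil_rate=0.0),
    "mutant_like": dict(speed_mean=75.0, speed_sd=10.0, reversal_rate=4.5,
                        coil_rate=0.6, coil_duration_mean=15.0),
    "coiler": dict(speed_mean=40.0, speed_sd=8.0, reversal_rate=3.0,
                   coil_rate=2.0, coil_duration_mean=20.0),
}

# reversal rates (events/min) for the three solvent-matched rescue cohorts;
# the drug-treated mutant sits between the untreated mutant and wild type,
# so the percent rescue is strictly between 0 and 100.
RESCUE_RATES = {"wt_solvent": 1.5, "mutant_solvent": 4.5, "mutant_drug": 2.5}

PROFILE_NAMES = sorted(PROFILES) + ["rescue_panel"]


def profile_config(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Simulation config for a named phenotype profile."""
    if name not in PROFILES:
        raise ValueError(
            f"unknown profile {name!r}; valid profiles: {PROFILE_NAMES}")
    params = {**_FIXTURE_BASE, **PROFILES[name], **overrides, "seed": seed}
    return SimulationConfig(**params)


@dataclass
class FixtureBundle:
    name: str
    stacks: dict[str, ImageStack]
    ground_truths: dict[str, GroundTruth]
    assay_tables: dict[str, pd.DataFrame]


def _paralysis_table(rng: np.random.Generator, group: str, n: int,
                     median_min: float, assay_end: float = 120.0
                     ) -> pd.DataFrame:
    scale = median_min / np.log(2.0)
    times = rng.exponential(scale, size=n)
    observed = times < assay_end
    times = np.minimum(times, assay_end)
    return pd.DataFrame({
        "animal_id": [f"{group}_{i}" for i in range(n)],
        "group": group,
        "event_time": np.round(times, 2),
        "event_observed": observed,
    })


def make_fixtures(profile: str, seed: int = 0,
                  out_dir: str | Path | None = None) -> FixtureBundle:
    """Generate the named fixture bundle (image stacks + ground truth +
    assay CSVs); ``rescue_panel`` yields three behavior-level cohorts whose
    reversal rates embody a partial drug rescue."""
    rng = np.random.default_rng(seed)
    stacks: dict[str, ImageStack] = {}
    gts: dict[str, GroundTruth] = {}
    tables: dict[str, pd.DataFrame] = {}

    if profile in PROFILES:
        cfg = profile_config(profile, seed=seed)
        stack, gt = simulate_cohort(cfg)
        stacks[profile] = stack
        gts[profile] = gt
        tables["paralysis"] = pd.concat([
            _paralysis_table(rng, "control", 20, median_min=60.0),
            _paralysis_table(rng, profile, 20,
                             median_min=25.0 if profile != "wt_like" else 60.0),
        ], ignore_index=True)
    elif profile == "rescue_panel":
        for cohort, rate in RESCUE_RATES.items():
            cfg = SimulationConfig(**{
                **_FIXTURE_BASE,
                "speed_mean": 40.0,
                "reversal_rate": rate,
                "coil_rate": 0.0,
                "duration": 300.0,
                "n_worms": 5,
                "seed": int(rng.integers(0, 2**31 - 1)),
            })
            gts[cohort] = simulate_ground_truth(cfg)
        rows = []
        for cohort, gt in gts.items():
            per_worm = gt.per_worm()["cum_reversals"].max()
            minutes = gt.config.duration / 60.0
            for worm_id, count in per_worm.items():
                rows.append({"group": cohort, "animal_id": worm_id,
                             "reversals_per_min": count / minutes})
        tables["reversal_rates"] = pd.DataFrame(rows)
    else:
        raise ValueError(
            f"unknown profile {profile!r}; valid profiles: {PROFILE_NAMES}")

    bundle = FixtureBundle(name=profile, stacks=stacks, ground_truths=gts,
                           assay_tables=tables)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, stack in stacks.items():
            wio.write_stack_tiff(stack, out / f"{name}.tif")
        for name, gt in gts.items():
            gt.to_csv(out / f"{name}_ground_truth.csv")
        for name, table in tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
    return bundle
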