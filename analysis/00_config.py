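"""Shared configuration for the numbered analysis drivers.

One study configuration is used across scripts 01-06 so each stage can be
re-derived deterministically from the seed alone: 10 territories holding 24
wolf data sets (mixed breeders/nonbreeders, mixed half-hourly and hourly
schedules, 21-day study periods) on 30 x 30 km landscapes calibrated to the
study-area summaries (gravel 0.88 and main 0.19 km/km2 on average, houses
3.0 per km2, 81.7% forest). Run any script with --seed to change the
realization; all stages stay mutually consistent.
"""

from wolfroads.pipeline import RunConfig
from wolfroads.synthetic_data import LandscapeConfig, WolfConfig

RESULTS = "results"


def study_config(seed: int = 1) -> RunConfig:
    return RunConfig(
        n_territories=10,
        n_datasets=24,
        landscape=LandscapeConfig(extent_km=(30.0, 30.0)),
        wolf=WolfConfig(study_days=21),
        cv_reps=3,
        seed=seed,
    )
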