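"""Canonical feature registry.

Every feature the pipeline emits or consumes is named
``<sensor>.<axis|pair>.<feature>`` and the full, ordered list of 234 names
is fixed here so feature tables are column-stable across runs and machines.

Layout per sensor (78 names): 39 time-domain values (12 per axis plus the
three inter-axis correlations) followed by 39 frequency-domain values
(13 per axis).  Three sensors give 3 x 78 = 234.
"""

from __future__ import annotations

SENSORS = ("non_dominant_wrist", "dominant_wrist", "chest")
AXES = ("x", "y", "z")

#: per-axis time-domain features (12)
TIME_AXIS_FEATURES = (
    "mean",
    "sd",
    "rr",
    "det",
    "l_mean",
    "l_max",
    "entr",
    "lam",
    "tt",
    "le",
    "sampen",
    "permen",
)

#: per-sensor pairwise features (3)
TIME_PAIR_FEATURES = ("corr_xy", "corr_xz", "corr_yz")

#: per-axis frequency-domain features (13)
FREQ_AXIS_FEATURES = (
    "spectral_energy",
    "component_entropy",
    "stft_c1",
    "stft_c2",
    "stft_c3",
    "stft_c4",
    "stft_c5",
    "wpd_l1",
    "wpd_l2",
    "wpd_l3",
    "wpd_l4",
    "wpd_l5",
    "wpd_l6",
)


def sensor_time_feature_names(sensor: str) -> list[str]:
    names = [f"{sensor}.{ax}.{feat}" for ax in AXES for feat in TIME_AXIS_FEATURES]
    names += [f"{sensor}.{pair[5:]}.{pair}" for pair in TIME_PAIR_FEATURES]
    return names


def sensor_freq_feature_names(sensor: str) -> list[str]:
    return [f"{sensor}.{ax}.{feat}" for ax in AXES for feat in FREQ_AXIS_FEATURES]


def _build_registry() -> tuple[str, ...]:
    names: list[str] = []
    for sensor in SENSORS:
        names += sensor_time_feature_names(sensor)
        names += sensor_freq_feature_names(sensor)
    return tuple(names)


#: the canonical ordered 234 feature names
FEATURE_NAMES: tuple[str, ...] = _build_registry()

#: names belonging to the chest sensor (used by the ablation flag)
CHEST_FEATURE_NAMES: tuple[str, ...] = tuple(
    n for n in FEATURE_NAMES if n.startswith("chest.")
)

N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 234
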