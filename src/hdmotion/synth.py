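"""Seeded generator of synthetic accelerometer cohorts.

The original clinical recordings (token-transfer task performed by people
with Huntington's disease and healthy controls while wearing three
tri-axial accelerometers) are not publicly deposited, so this module
generates cohorts with the statistical structure the analysis pipeline
assumes:

* healthy sessions are quasi-periodic — eight smooth transfer cycles of
  roughly 1.7 s each over a ~13.6 s session, with small cycle-duration
  jitter and additive sensor noise;
* HD sessions are slower (duration grows with severity), their cycle
  timing is more irregular, and they are contaminated with short choreic
  bursts (damped 6-12 Hz oscillations in a random 3-D direction) whose
  rate and amplitude grow with a latent severity parameter;
* the same severity parameter drives the synthetic clinician score
  (mULMS): each of the five 0-4 sub-items is drawn Binomial(4,
  severity/20) so the target is integer, bounded and noisy like the real
  scale;
* severe cases fail the harder tasks, in order: mULMS >= 14 leaves only
  the baseline simple recording, 14 > mULMS >= 10 drops the dual task.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import (
    CohortDataset,
    Group,
    Participant,
    Placement,
    Task,
    TaskRecording,
    TriaxialSignal,
    ValidationError,
)

SAMPLING_HZ = 100.0

#: healthy session statistics: mean/sd of total duration in seconds
HEALTHY_DURATION_MEAN_S = 13.6
HEALTHY_DURATION_SD_S = 1.5
#: additional seconds of duration per severity unit for HD sessions
HD_DURATION_SLOPE_S = 0.85
N_CYCLES = 8

#: amplitude of the non-dominant-wrist movement pattern, in g
WRIST_AMPLITUDE_G = 0.8
#: relative amplitudes of y and z axes, and of the other sensors
AXIS_SCALES = {"x": 1.0, "y": 0.6, "z": 0.4}
SENSOR_SCALES = {
    Placement.NON_DOMINANT_WRIST: 1.0,
    Placement.DOMINANT_WRIST: 0.5,
    Placement.CHEST: 0.1,
}
AXIS_PHASES = {"x": 0.0, "y": 0.5 * np.pi, "z": np.pi}

#: task difficulty multipliers on duration; the dual task also raises the
#: burst rate (dual-task interference)
TASK_DURATION_FACTOR = {
    Task.BASELINE_SIMPLE: 1.0,
    Task.BASELINE_COMPLEX: 1.15,
    Task.DUAL: 1.3,
}
DUAL_BURST_RATE_FACTOR = 1.2

#: mULMS thresholds for ordered task failure
MISSING_BOTH_THRESHOLD = 14
MISSING_DUAL_THRESHOLD = 10


@dataclass
class SimulationConfig:
    """Cohort-level generator settings.

    The slopes express how the HD signal degrades per unit of the latent
    severity (0-20 scale): extra choreic bursts per second
    (``burst_rate_slope``), their mean peak amplitude in g
    (``burst_amp_slope``) and the growth of the cycle-duration
    coefficient of variation (``cycle_cv_slope``).
    """

    n_control: int = 48
    n_hd: int = 44
    seed: int = 7
    severity_range: tuple[float, float] = (1.0, 18.0)
    noise_sd: float = 0.02
    burst_rate_slope: float = 0.05
    burst_amp_slope: float = 0.04
    cycle_cv_slope: float = 0.03
    base_cycle_cv: float = 0.05
    base_burst_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_hd < 1:
            raise ValidationError("participant counts must be >= 1")
        for name in ("burst_rate_slope", "burst_amp_slope", "cycle_cv_slope"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        lo, hi = self.severity_range
        if not (0 <= lo <= hi <= 20):
            raise ValidationError("severity_range must lie within [0, 20]")


def severity_to_items(severity: float, rng: np.random.Generator) -> tuple[int, ...]:
    """Draw the five 0-4 mULMS sub-items from a latent severity in [0, 20].

    Each item is Binomial(4, severity/20), independently, so the expected
    item sum equals the severity.
    """
    if not 0 <= severity <= 20:
        raise ValidationError(f"severity out of [0, 20]: {severity}")
    return tuple(int(v) for v in rng.binomial(4, severity / 20.0, size=5))


def _cycle_durations(
    duration_s: float, cycle_cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Jittered per-cycle durations summing to roughly the session length."""
    base = duration_s / N_CYCLES
    return base * np.clip(rng.normal(1.0, cycle_cv, size=N_CYCLES), 0.3, None)


def _cycle_pattern(durations: np.ndarray, phase: float) -> np.ndarray:
    """Quasi-periodic transfer pattern: one Hann-windowed sinusoid bump per
    cycle; the carrier completes one oscillation per cycle (fundamental
    ~ 8/duration Hz)."""
    parts = []
    for d in durations:
        n = max(int(round(d * SAMPLING_HZ)), 4)
        t_rel = np.arange(n) / n  # fraction of the cycle
        window = 0.5 * (1.0 - np.cos(2.0 * np.pi * t_rel))  # Hann bump
        parts.append(window * np.sin(2.0 * np.pi * t_rel + phase))
    return np.concatenate(parts)


def _choreic_bursts(
    n: int,
    rate_per_s: float,
    amp_mean_g: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Superimposed burst train, shape (n, 3): damped 6-12 Hz oscillations
    of 0.2-0.5 s with exponential peak amplitudes, each along a random 3-D
    orientation."""
    out = np.zeros((n, 3))
    duration_s = n / SAMPLING_HZ
    n_events = rng.poisson(rate_per_s * duration_s)
    for _ in range(n_events):
        start = int(rng.uniform(0, n))
        dur = rng.uniform(0.2, 0.5)
        freq = rng.uniform(6.0, 12.0)
        amp = rng.exponential(amp_mean_g) if amp_mean_g > 0 else 0.0
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        n_b = min(int(dur * SAMPLING_HZ), n - start)
        if n_b <= 0:
            continue
        t = np.arange(n_b) / SAMPLING_HZ
        wave = amp * np.exp(-3.0 * t / dur) * np.sin(2.0 * np.pi * freq * t)
        out[start : start + n_b] += np.outer(wave, direction)
    return out


def simulate_session(
    group: Group | str,
    severity: float,
    task: Task | str,
    rng: np.random.Generator,
    config: SimulationConfig | None = None,
    participant_id: str = "sim",
    trunk_chorea: float | None = None,
) -> TaskRecording:
    """Generate one three-sensor recording for a participant-task.

    ``trunk_chorea`` (0-4) scales the chest-sensor burst amplitude; when
    not given it defaults to its expected value ``severity / 5``.
    """
    group = Group(group)
    task = Task(task)
    cfg = config or SimulationConfig()
    if group is Group.CONTROL and severity != 0:
        raise ValidationError("control sessions must have severity 0")
    if trunk_chorea is None:
        trunk_chorea = severity / 5.0

    duration = rng.normal(
        HEALTHY_DURATION_MEAN_S + HD_DURATION_SLOPE_S * severity,
        HEALTHY_DURATION_SD_S,
    )
    lo, hi = (10.0, 20.0) if group is Group.CONTROL else (10.0, 45.0)
    duration = float(np.clip(duration, lo, hi)) * TASK_DURATION_FACTOR[task]

    cycle_cv = cfg.base_cycle_cv + cfg.cycle_cv_slope * severity
    # one jittered cycle-timing realisation shared by every axis and sensor
    # (hands and trunk move with the same task rhythm); axes differ only in
    # carrier phase and amplitude
    durations = _cycle_durations(duration, cycle_cv, rng)
    axis_patterns = {
        ax: AXIS_SCALES[ax] * _cycle_pattern(durations, AXIS_PHASES[ax])
        for ax in ("x", "y", "z")
    }
    n = min(len(p) for p in axis_patterns.values())

    burst_rate = 0.0
    if group is Group.HD:
        burst_rate = cfg.base_burst_rate + cfg.burst_rate_slope * severity
        if task is Task.DUAL:
            burst_rate *= DUAL_BURST_RATE_FACTOR
    amp_mean = cfg.burst_amp_slope * severity

    sensors = {}
    for placement, scale in SENSOR_SCALES.items():
        axes = {
            ax: WRIST_AMPLITUDE_G * scale * axis_patterns[ax][:n].copy()
            for ax in ("x", "y", "z")
        }
        if group is Group.HD:
            chest_scale = trunk_chorea / 4.0 if placement is Placement.CHEST else 1.0
            bursts = _choreic_bursts(n, burst_rate, amp_mean * chest_scale, rng)
            for i, ax in enumerate(("x", "y", "z")):
                axes[ax] += bursts[:, i]
        for ax in ("x", "y", "z"):
            axes[ax] += rng.normal(0.0, cfg.noise_sd, size=n)
            np.clip(axes[ax], -8.0, 8.0, out=axes[ax])
        sensors[placement] = TriaxialSignal(
            placement=placement, fs=SAMPLING_HZ, x=axes["x"], y=axes["y"], z=axes["z"]
        )
    return TaskRecording(participant_id=participant_id, task=task, sensors=sensors)


def missing_tasks(mulms: int) -> list[Task]:
    """Ordered task failure for severe impairment."""
    if mulms >= MISSING_BOTH_THRESHOLD:
        return [Task.BASELINE_COMPLEX, Task.DUAL]
    if mulms >= MISSING_DUAL_THRESHOLD:
        return [Task.DUAL]
    return []


def simulate_cohort(config: SimulationConfig | None = None) -> CohortDataset:
    """Generate a full cohort: participants, scores and recordings."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    participants: list[Participant] = []
    recordings: dict[tuple[str, Task], TaskRecording] = {}

    for i in range(cfg.n_control):
        pid = f"C{i + 1:03d}"
        participants.append(Participant(id=pid, group=Group.CONTROL, mulms=0))
        for task in Task:
            recordings[(pid, task)] = simulate_session(
                Group.CONTROL, 0.0, task, rng, cfg, participant_id=pid
            )

    lo, hi = cfg.severity_range
    for i in range(cfg.n_hd):
        pid = f"H{i + 1:03d}"
        severity = float(rng.uniform(lo, hi))
        items = severity_to_items(severity, rng)
        p = Participant(id=pid, group=Group.HD, mulms_items=items)
        participants.append(p)
        absent = missing_tasks(p.mulms)
        for task in Task:
            if task in absent:
                continue
            recordings[(pid, task)] = simulate_session(
                Group.HD,
                severity,
                task,
                rng,
                cfg,
                participant_id=pid,
                trunk_chorea=items[2],
            )
    return CohortDataset(participants=participants, recordings=recordings)
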