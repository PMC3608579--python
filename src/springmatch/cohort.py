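"""Synthetic cohorts for the virtual-spring force-matching experiment.

Generates per-trial records with the statistical structure the analysis
pipeline assumes: subjects (controls and dystonia patients) × blocks (one
stiffness per block, order randomised) × trials.  Each block opens with 15
training trials under visual force feedback, followed by 36 reference/blind
pairs in which every blind slot is preceded by a reference trial and 12 of
the 36 blind slots are covertly replaced by catch trials (one catch per six
measured trials on average, exactly 12 per block).  Two extra blocks probe
sensor accuracy: blind force reproduction on an infinitely stiff spring
(recovers sigma_f) and blind position reproduction with no spring (recovers
sigma_x).

Subject-level noise parameters are drawn from truncated normal populations
matching the published group statistics: sigma_f 1.82 N (SD 1.06) for
controls and 2.31 N (SD 1.61) for patients; sigma_x 9.2 mm (SD 2.7) and
11.6 mm (SD 4.6).  Controls weight feedback by maximum likelihood; patients
default to a stiffness-independent force weight of 0.25 with a larger blind
overshoot.

Pressing the foot switch triggers a 0.6 s force measurement at 250 Hz
(150 samples per trial); accidental early presses occur with a small
probability and leave a near-zero force record for the 5 N exclusion rule to
catch.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .observer import EquilibriumError, SubjectParams, equilibrium_response
from .springs import CatchSpring, LinearSpring

__all__ = [
    "GROUP_STATS",
    "GroupBehavior",
    "CohortConfig",
    "ScheduleEntry",
    "Schedule",
    "TrialRecord",
    "make_schedule",
    "draw_subject",
    "simulate_trial",
    "simulate_subject",
    "simulate_cohort",
    "records_to_frame",
]

#: published population statistics: (mean, SD) of the subject-level sensory
#: noise parameters, sigma_f in N and sigma_x in m.
GROUP_STATS = {
    "control": {"sigma_f": (1.82, 1.06), "sigma_x": (0.0092, 0.0027)},
    "patient": {"sigma_f": (2.31, 1.61), "sigma_x": (0.0116, 0.0046)},
}

TRIAL_TYPES = ("training", "reference", "blind", "catch")
INFINITE = math.inf
ZERO = 0.0


@dataclass(frozen=True)
class GroupBehavior:
    """Weighting policy and blind overshoot of one subject group."""

    policy: str = "mle"
    rho: float = 1.0
    fixed_w_f: float | None = None
    bias: float = 2.0


@dataclass(frozen=True)
class CohortConfig:
    """Every knob of the synthetic experiment, with the study defaults.

    The four block stiffnesses span soft to stiff around the ~200 N/m
    crossover where force and position cues are equally reliable for an
    average control subject.  ``sensory_noise_scale`` multiplies the
    per-trial sensory noise draws (0 gives the noise-free oracle cohorts);
    ``sensor_noise_sd`` is force-transducer noise on the 150-sample
    measurement window and ``servo_noise_sd`` the residual visual-servo error
    in reference/training trials.
    """

    n_per_group: int = 10
    stiffness_list: tuple[float, ...] = (30.0, 100.0, 300.0, 1000.0)
    target_force: float = 10.0
    anchor_offset: float | None = None  # None -> 10% of target_force
    exponent: float = 2.0
    n_training: int = 15
    n_blind_slots: int = 36
    n_catch: int = 12
    accuracy_reps: int = 20
    include_accuracy: bool = True
    position_target: float = 0.1
    sample_rate: float = 250.0
    sample_duration: float = 0.6
    sensor_noise_sd: float = 0.05
    servo_noise_sd: float = 0.1
    slip_prob: float = 0.02
    sensory_noise_scale: float = 1.0
    keep_samples: bool = False
    control: GroupBehavior = field(default_factory=GroupBehavior)
    patient: GroupBehavior = field(
        default_factory=lambda: GroupBehavior(policy="fixed", fixed_w_f=0.25, bias=4.5)
    )

    def __post_init__(self) -> None:
        if len(self.stiffness_list) == 0:
            raise ValueError("stiffness_list must be non-empty")
        for k in self.stiffness_list:
            if not (k > 0 and math.isfinite(k)):
                raise ValueError(f"block stiffnesses must be positive finite, got {k!r}")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not 0 < self.n_catch <= self.n_blind_slots:
            raise ValueError("need 0 < n_catch <= n_blind_slots")

    @property
    def n_samples(self) -> int:
        return round(self.sample_rate * self.sample_duration)

    def behavior(self, group: str) -> GroupBehavior:
        if group == "control":
            return self.control
        if group == "patient":
            return self.patient
        raise ValueError(f"unknown group {group!r}")

    def catch_spring(self, stiffness: float) -> CatchSpring:
        return CatchSpring(
            stiffness=stiffness,
            target_force=self.target_force,
            anchor_offset=self.anchor_offset,
            exponent=self.exponent,
        )

    def to_dict(self) -> dict:
        out = asdict(self)
        out["stiffness_list"] = list(self.stiffness_list)
        return out

    @classmethod
    def from_dict(cls, obj: dict) -> "CohortConfig":
        obj = dict(obj)
        for group in ("control", "patient"):
            if group in obj and isinstance(obj[group], dict):
                obj[group] = GroupBehavior(**obj[group])
        if "stiffness_list" in obj:
            obj["stiffness_list"] = tuple(obj["stiffness_list"])
        return cls(**obj)


# ---------------------------------------------------------------------------
# trial schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScheduleEntry:
    block: int
    stiffness: float  # N/m; math.inf and 0.0 are the sensor-accuracy sentinels
    trial_type: str


@dataclass(frozen=True)
class Schedule:
    entries: tuple[ScheduleEntry, ...]
    stiffness_order: tuple[float, ...]

    def block_entries(self, block: int) -> list[ScheduleEntry]:
        return [e for e in self.entries if e.block == block]


def make_schedule(
    stiffness_list,
    seed: int,
    n_training: int = 15,
    n_blind_slots: int = 36,
    n_catch: int = 12,
) -> Schedule:
    """Seeded trial schedule for the main (finite-stiffness) blocks.

    Block order is a seeded permutation of ``stiffness_list``.  Each block:
    ``n_training`` training trials, then ``n_blind_slots`` reference/blind
    pairs with exactly ``n_catch`` blind slots (chosen uniformly without
    replacement) covertly turned into catch trials.
    """
    stiffness_list = tuple(float(k) for k in stiffness_list)
    if not stiffness_list:
        raise ValueError("stiffness_list must be non-empty")
    rng = np.random.default_rng(seed)
    order = tuple(stiffness_list[i] for i in rng.permutation(len(stiffness_list)))
    entries: list[ScheduleEntry] = []
    for block, stiffness in enumerate(order):
        for _ in range(n_training):
            entries.append(ScheduleEntry(block, stiffness, "training"))
        catch_slots = set(rng.choice(n_blind_slots, size=n_catch, replace=False).tolist())
        for slot in range(n_blind_slots):
            entries.append(ScheduleEntry(block, stiffness, "reference"))
            kind = "catch" if slot in catch_slots else "blind"
            entries.append(ScheduleEntry(block, stiffness, kind))
    return Schedule(entries=tuple(entries), stiffness_order=order)


def accuracy_entries(start_block: int, reps: int) -> list[ScheduleEntry]:
    """Sensor-accuracy blocks: blind force at K=inf, blind position at K=0."""
    out = [ScheduleEntry(start_block, INFINITE, "blind") for _ in range(reps)]
    out += [ScheduleEntry(start_block + 1, ZERO, "blind") for _ in range(reps)]
    return out


# ---------------------------------------------------------------------------
# subject populations
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _calibrated_loc(mean: float, sd: float, lower: float) -> float:
    """Parent location whose lower-truncated normal has the requested mean.

    Plain truncation of N(mean, sd) at ``lower`` inflates the mean; shifting
    the parent restores the published population mean exactly.
    """

    def truncated_mean(loc: float) -> float:
        a = (lower - loc) / sd
        return float(truncnorm.mean(a, np.inf, loc=loc, scale=sd))

    return float(brentq(lambda L: truncated_mean(L) - mean, mean - 8 * sd, mean))


def _draw_sigma(rng: np.random.Generator, mean: float, sd: float) -> float:
    lower = 0.1 * mean  # keeps every draw strictly positive
    loc = _calibrated_loc(mean, sd, lower)
    a = (lower - loc) / sd
    return float(truncnorm.rvs(a, np.inf, loc=loc, scale=sd, random_state=rng))


def draw_subject(
    group: str,
    seed: int,
    config: CohortConfig | None = None,
    subject_id: str | None = None,
) -> SubjectParams:
    """Draw one subject's noise parameters and attach the group policy."""
    config = config or CohortConfig()
    stats = GROUP_STATS.get(group)
    if stats is None:
        raise ValueError(f"unknown group {group!r}")
    behavior = config.behavior(group)
    rng = np.random.default_rng(seed)
    sigma_f = _draw_sigma(rng, *stats["sigma_f"])
    sigma_x = _draw_sigma(rng, *stats["sigma_x"])
    return SubjectParams(
        sigma_f=sigma_f,
        sigma_x=sigma_x,
        weight_policy=behavior.policy,
        rho=behavior.rho,
        fixed_w_f=behavior.fixed_w_f,
        bias=behavior.bias,
        group=group,
        seed=seed,
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------


@dataclass
class TrialRecord:
    """One trial's identity and outcome."""

    subject_id: str
    group: str
    block: int
    stiffness: float
    trial_type: str
    spring_kind: str
    position: float
    force_samples: np.ndarray | None
    mean_force: float
    valid: bool


def _measure(
    true_force: float, rng: np.random.Generator, config: CohortConfig
) -> tuple[np.ndarray, float]:
    samples = true_force + config.sensor_noise_sd * rng.standard_normal(config.n_samples)
    return samples, float(samples.mean())


def simulate_trial(
    subject: SubjectParams,
    entry: ScheduleEntry,
    rng: np.random.Generator,
    config: CohortConfig | None = None,
) -> TrialRecord:
    """Simulate one trial of the schedule for one subject.

    Per-trial sensory noise is drawn as ``n_f ~ N(0, sigma_f)`` and
    ``n_x ~ N(0, sigma_x)`` (scaled by ``sensory_noise_scale``); the produced
    position and force come from the observer's quasi-static equilibrium.
    The returned record carries the 150-sample force window (dropped when
    ``keep_samples`` is off, after the mean is taken).
    """
    config = config or CohortConfig()
    stiffness = entry.stiffness
    ttype = entry.trial_type
    if ttype not in TRIAL_TYPES:
        raise ValueError(f"unknown trial type {ttype!r}")
    scale = config.sensory_noise_scale
    # fixed draw order keeps the stream layout identical across branches
    n_f = scale * subject.sigma_f * rng.standard_normal()
    n_x = scale * subject.sigma_x * rng.standard_normal()
    slip_draw = rng.random()

    is_force_task = stiffness != ZERO
    spring_kind = "none"
    spring = None
    if math.isfinite(stiffness) and stiffness > 0:
        if ttype == "catch":
            spring = config.catch_spring(stiffness)
            spring_kind = "catch"
        else:
            spring = LinearSpring(stiffness)
            spring_kind = "linear"

    valid = True
    if is_force_task and config.slip_prob > 0 and slip_draw < config.slip_prob:
        # accidental foot-switch press: measurement taken while barely loading
        true_force = abs(1.0 + 0.5 * rng.standard_normal())
        position = spring.position_for_force(true_force) if spring else 0.0
    elif ttype in ("training", "reference"):
        if not is_force_task:
            true_force, position = 0.0, config.position_target
        else:
            true_force = max(
                0.0, config.target_force + config.servo_noise_sd * rng.standard_normal()
            )
            position = spring.position_for_force(true_force) if spring else 0.0
    else:  # blind or catch
        memory_force = config.target_force + subject.bias
        if stiffness == ZERO:
            position = max(0.0, config.position_target - n_x)
            true_force = 0.0
        elif math.isinf(stiffness):
            true_force = memory_force - n_f
            position = 0.0
            if true_force < 0:
                true_force, valid = math.nan, False
        else:
            try:
                position, true_force = equilibrium_response(
                    subject, spring, stiffness, memory_force, noise=(n_f, n_x)
                )
            except EquilibriumError:
                position, true_force, valid = math.nan, math.nan, False

    if valid:
        samples, mean_force = _measure(true_force, rng, config)
    else:
        samples, mean_force = None, math.nan
    return TrialRecord(
        subject_id=subject.subject_id or "S00",
        group=subject.group,
        block=entry.block,
        stiffness=stiffness,
        trial_type=ttype,
        spring_kind=spring_kind,
        position=position,
        force_samples=samples if config.keep_samples else None,
        mean_force=mean_force,
        valid=valid,
    )


def simulate_subject(
    subject: SubjectParams,
    schedule: Schedule,
    rng: np.random.Generator,
    config: CohortConfig | None = None,
) -> list[TrialRecord]:
    """Run one subject through a schedule plus the sensor-accuracy blocks."""
    config = config or CohortConfig()
    entries = list(schedule.entries)
    if config.include_accuracy:
        n_blocks = len(schedule.stiffness_order)
        entries += accuracy_entries(n_blocks, config.accuracy_reps)
    return [simulate_trial(subject, entry, rng, config) for entry in entries]


def simulate_cohort(
    n_per_group: int | None = None,
    stiffness_list=None,
    master_seed: int = 0,
    config: CohortConfig | None = None,
    as_frame: bool = True,
):
    """Simulate a full two-group cohort.

    Every subject gets independent seeded substreams (parameter draw, block
    order, trial noise) spawned from ``master_seed``, so the output table is
    byte-identical across runs with the same seed.  Returns a tidy DataFrame
    (one row per trial) or the raw record list with ``as_frame=False``.
    """
    config = config or CohortConfig()
    if n_per_group is not None or stiffness_list is not None:
        overrides = {}
        if n_per_group is not None:
            overrides["n_per_group"] = int(n_per_group)
        if stiffness_list is not None:
            overrides["stiffness_list"] = tuple(float(k) for k in stiffness_list)
        config = replace(config, **overrides)

    root = np.random.SeedSequence(master_seed)
    records: list[TrialRecord] = []
    for group, prefix in (("control", "C"), ("patient", "P")):
        for i in range(config.n_per_group):
            subject_id = f"{prefix}{i + 1:02d}"
            param_ss, sched_ss, trial_ss = root.spawn(1)[0].spawn(3)
            subject = draw_subject(
                group,
                seed=int(param_ss.generate_state(1)[0] % (2**31)),
                config=config,
                subject_id=subject_id,
            )
            schedule = make_schedule(
                config.stiffness_list,
                seed=int(sched_ss.generate_state(1)[0] % (2**31)),
                n_training=config.n_training,
                n_blind_slots=config.n_blind_slots,
                n_catch=config.n_catch,
            )
            rng = np.random.default_rng(trial_ss)
            records.extend(simulate_subject(subject, schedule, rng, config))
    return records_to_frame(records) if as_frame else records


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Tidy one-row-per-trial table with the pipeline's CSV schema."""
    return pd.DataFrame(
        {
            "subject": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "block": [r.block for r in records],
            "stiffness": [r.stiffness for r in records],
            "type": [r.trial_type for r in records],
            "spring": [r.spring_kind for r in records],
            "x_m": [r.position for r in records],
            "mean_force_N": [r.mean_force for r in records],
            "valid": [r.valid for r in records],
        }
    )
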