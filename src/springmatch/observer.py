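"""Maximum-likelihood observer producing forces in blind and catch trials.

The subject holds a handle against a spring and tries to reproduce a
remembered target force without visual feedback.  Two noisy sensory channels
inform the internal force estimate: direct force sense (SD ``sigma_f``, N)
and position sense (SD ``sigma_x``, m) mapped into force units through the
*trained* stiffness ``K`` (the subject is unaware of any covert spring swap).
Under maximum-likelihood fusion the force-channel weight is

    w_f = (rho / sigma_f^2) / (rho / sigma_f^2 + 1 / (K^2 sigma_x^2)),

i.e. precision-weighting of the two cues after expressing the position cue in
newtons; ``rho`` in (0, 1] optionally down-scales the trusted precision of
the force channel.  ``w_f`` rises from 0 on a zero-stiffness spring (position
is the only informative cue) to 1 on an infinitely stiff one.

A produced trial is modelled as a quasi-static equilibrium: the subject
settles at the position ``x*`` where the internally estimated force matches
the memorised target,

    w_f · (F_spring(x*) + n_f) + w_p · K_assumed · (x* + n_x) = F_memory,

with per-trial sensory noise draws ``n_f``, ``n_x``.  On the trained linear
spring with zero noise this reproduces ``F_memory`` exactly; on the catch
spring the two cues dissociate and the exerted force moves toward the trained
*position* in proportion to ``w_p = 1 - w_f``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

from .springs import CatchSpring, LinearSpring, Spring, SpringDomainError

__all__ = [
    "WeightPair",
    "SubjectParams",
    "EquilibriumError",
    "mle_force_weight",
    "weights_for",
    "equilibrium_response",
    "predict_delta_f",
]

WEIGHT_POLICIES = ("mle", "mle_scaled", "fixed")


class EquilibriumError(RuntimeError):
    """No admissible equilibrium position exists for the trial."""


@dataclass(frozen=True)
class WeightPair:
    """Complementary force/position feedback weights (w_f + w_p = 1)."""

    w_f: float
    w_p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.w_f <= 1.0):
            raise ValueError(f"w_f out of [0, 1]: {self.w_f!r}")
        if abs(self.w_f + self.w_p - 1.0) > 1e-12:
            raise ValueError(
                f"weights must sum to 1, got {self.w_f!r} + {self.w_p!r}"
            )

    @classmethod
    def from_force_weight(cls, w_f: float) -> "WeightPair":
        return cls(w_f=w_f, w_p=1.0 - w_f)


@dataclass(frozen=True)
class SubjectParams:
    """One simulated participant.

    ``sigma_f`` (N) and ``sigma_x`` (m) are the subject's sensory noise SDs —
    operationally the SDs of blind force reproduction on an infinitely stiff
    spring and blind position reproduction with no spring.  ``weight_policy``
    selects how feedback weights depend on stiffness: ``mle`` (optimal
    precision weighting), ``mle_scaled`` (MLE with force precision scaled by
    ``rho`` < 1, an unreliable-force-channel hypothesis) or ``fixed``
    (stiffness-independent ``fixed_w_f``, the flat weighting observed in
    dystonia patients).  ``bias`` (N, >= 0) is the blind overshoot of the
    memorised target: without visual feedback subjects under-estimate their
    exerted force and therefore push harder.
    """

    sigma_f: float
    sigma_x: float
    weight_policy: str = "mle"
    rho: float = 1.0
    fixed_w_f: float | None = None
    bias: float = 0.0
    group: str = "control"
    seed: int = 0
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sigma_f > 0:
            raise ValueError(f"sigma_f must be positive, got {self.sigma_f!r}")
        if not self.sigma_x > 0:
            raise ValueError(f"sigma_x must be positive, got {self.sigma_x!r}")
        if self.weight_policy not in WEIGHT_POLICIES:
            raise ValueError(
                f"weight_policy must be one of {WEIGHT_POLICIES}, "
                f"got {self.weight_policy!r}"
            )
        if self.weight_policy == "fixed":
            if self.fixed_w_f is None or not (0.0 <= self.fixed_w_f <= 1.0):
                raise ValueError(
                    f"fixed policy needs fixed_w_f in [0, 1], got {self.fixed_w_f!r}"
                )
        if not (0.0 < self.rho <= 1.0):
            raise ValueError(f"rho must lie in (0, 1], got {self.rho!r}")
        if self.bias < 0:
            raise ValueError(f"bias must be non-negative, got {self.bias!r}")

    def to_dict(self) -> dict:
        return {
            "sigma_f": self.sigma_f,
            "sigma_x": self.sigma_x,
            "weight_policy": self.weight_policy,
            "rho": self.rho,
            "fixed_w_f": self.fixed_w_f,
            "bias": self.bias,
            "group": self.group,
            "seed": self.seed,
            "subject_id": self.subject_id,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "SubjectParams":
        return cls(**obj)


def mle_force_weight(
    sigma_f: float, sigma_x: float, stiffness: float, rho: float = 1.0
) -> WeightPair:
    """Optimal force/position weights at a given stiffness.

    ``stiffness = 0`` and ``stiffness = inf`` act as sentinels for the pure
    position and pure force tasks (w_f -> 0 and 1 respectively); negative
    stiffness is a domain error.
    """
    if not sigma_f > 0 or not sigma_x > 0:
        raise SpringDomainError("sigma_f and sigma_x must be positive")
    if not (0.0 < rho <= 1.0):
        raise SpringDomainError(f"rho must lie in (0, 1], got {rho!r}")
    if stiffness < 0 or math.isnan(stiffness):
        raise SpringDomainError(f"stiffness must be >= 0, got {stiffness!r}")
    if stiffness == 0.0:
        return WeightPair.from_force_weight(0.0)
    if math.isinf(stiffness):
        return WeightPair.from_force_weight(1.0)
    force_precision = rho / sigma_f**2
    position_precision = 1.0 / (stiffness**2 * sigma_x**2)
    w_f = force_precision / (force_precision + position_precision)
    return WeightPair.from_force_weight(w_f)


def weights_for(subject: SubjectParams, stiffness: float) -> WeightPair:
    """Feedback weights a subject applies at the given (assumed) stiffness.

    The stiffness sentinels override every policy: with no spring only
    position is informative, with an infinitely stiff one only force.
    """
    if stiffness == 0.0:
        return WeightPair.from_force_weight(0.0)
    if math.isinf(stiffness):
        return WeightPair.from_force_weight(1.0)
    if subject.weight_policy == "mle":
        return mle_force_weight(subject.sigma_f, subject.sigma_x, stiffness, rho=1.0)
    if subject.weight_policy == "mle_scaled":
        return mle_force_weight(
            subject.sigma_f, subject.sigma_x, stiffness, rho=subject.rho
        )
    return WeightPair.from_force_weight(subject.fixed_w_f)


def equilibrium_response(
    subject: SubjectParams,
    spring: Spring,
    assumed_stiffness: float,
    memory_force: float,
    noise: tuple[float, float] | None = None,
    x_max: float = 2.0,
) -> tuple[float, float]:
    """Position and true force produced in one blind or catch trial.

    Solves the internal-estimate-equals-memory equation for ``x*`` and
    returns ``(x*, F_spring(x*))``.  ``assumed_stiffness`` is the trained
    (linear) stiffness through which the subject maps position into force;
    ``noise`` is the per-trial pair ``(n_f, n_x)`` of sensory perturbations
    (``None`` means noise-free).  Raises :class:`EquilibriumError` if no
    root exists in ``[0, x_max]``.
    """
    if not memory_force > 0:
        raise ValueError(f"memory_force must be positive, got {memory_force!r}")
    n_f, n_x = (0.0, 0.0) if noise is None else noise
    weights = weights_for(subject, assumed_stiffness)
    w_f, w_p = weights.w_f, weights.w_p
    effective = memory_force - w_f * n_f - w_p * assumed_stiffness * n_x
    if effective < 0:
        raise EquilibriumError(
            "sensory noise drove the internal estimate above the target at "
            "the zero-length position; no equilibrium with x >= 0"
        )
    if effective == 0.0:
        return 0.0, spring.force_at(0.0)

    linear_coeff = w_f * spring.stiffness + w_p * assumed_stiffness
    if isinstance(spring, LinearSpring) or w_f == 0.0:
        x_star = effective / linear_coeff
    elif isinstance(spring, CatchSpring) and spring.exponent == 2.0:
        # w_f (K x + c x^2) + w_p K_a x = effective, c = dF_ns / x_t^2
        a = w_f * spring.anchor_offset / spring.anchor_position**2
        b = linear_coeff
        x_star = (-b + math.sqrt(b * b + 4.0 * a * effective)) / (2.0 * a)
    else:
        hi = effective / linear_coeff  # residual >= 0 there (convex excess)
        x_star = brentq(
            lambda x: w_f * spring.force_at(x) + w_p * assumed_stiffness * x - effective,
            0.0,
            hi,
            xtol=1e-14,
            rtol=8.9e-16,
        )
    if x_star > x_max:
        raise EquilibriumError(
            f"equilibrium position {x_star:.4f} m exceeds the travel limit {x_max} m"
        )
    return x_star, spring.force_at(x_star)


def predict_delta_f(
    w_p: float, stiffness: float, catch: CatchSpring, memory_force: float
) -> float:
    """Noise-free catch-minus-blind force difference for position weight ``w_p``.

    On the trained linear spring a noise-free subject reproduces
    ``memory_force`` exactly, so the predicted difference is the catch-trial
    equilibrium force minus ``memory_force``.  It runs from 0 (pure force
    weighting) up to the force gap at the trained position (pure position
    weighting) and is strictly increasing in ``w_p``.
    """
    if not (0.0 <= w_p <= 1.0):
        raise ValueError(f"w_p must lie in [0, 1], got {w_p!r}")
    probe = SubjectParams(
        sigma_f=1.0,
        sigma_x=1.0,
        weight_policy="fixed",
        fixed_w_f=1.0 - w_p,
    )
    _, catch_force = equilibrium_response(probe, catch, stiffness, memory_force)
    return catch_force - memory_force
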