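"""Quasi-static force laws for the virtual springs of the force-matching task.

Two haptic environments are modelled.  The *linear* spring, used during
training, reference and blind trials, exerts ``F = K·x`` with stiffness ``K``
(N/m) and handle displacement ``x`` (m) from the zero-length position.  The
*catch* spring is a covert non-linear replacement whose force gap relative to
the linear spring is zero at the origin and grows monotonically with
displacement; it is anchored so that at the position where the linear spring
would exert the target force ``F_target`` it exerts ``F_target + dF_ns``
instead.  The default form is

    F_catch(x) = K·x + dF_ns · (x / x_t)^p ,   x_t = F_target / K,  p = 2,

which is smooth, zero at the origin, exact at the anchor, strictly increasing
and therefore invertible.  The gap between the two laws at a given position,
and the position gap at a given force, are the scaling denominators of the
sensory-weight estimators.

Units: positions in metres, forces in newtons, stiffness in N/m throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

__all__ = [
    "SpringDomainError",
    "SpringConfigError",
    "LinearSpring",
    "CatchSpring",
    "force_at",
    "position_for_force",
    "force_gap",
    "position_gap",
    "spring_from_dict",
]

#: absolute force tolerance for numerically inverted spring laws (N)
INVERSE_FORCE_TOL = 1e-10


class SpringDomainError(ValueError):
    """Raised for arguments outside a spring law's domain (x < 0 or F < 0)."""


class SpringConfigError(ValueError):
    """Raised for inconsistent or invalid spring parameters."""


def _check_position(x: float) -> None:
    if x < 0:
        raise SpringDomainError(
            f"position {x!r} m is negative; the handle cannot be pulled "
            "behind the zero-length position"
        )


def _check_force(force: float) -> None:
    if force < 0:
        raise SpringDomainError(f"force {force!r} N is negative")


@dataclass(frozen=True)
class LinearSpring:
    """Linear spring ``F = K·x`` with stiffness ``K`` > 0 (N/m)."""

    stiffness: float

    def __post_init__(self) -> None:
        if not (self.stiffness > 0 and math.isfinite(self.stiffness)):
            raise SpringConfigError(
                f"stiffness must be positive and finite, got {self.stiffness!r}"
            )

    def force_at(self, x: float) -> float:
        _check_position(x)
        return self.stiffness * x

    def position_for_force(self, force: float) -> float:
        _check_force(force)
        return force / self.stiffness

    def to_dict(self) -> dict:
        return {"kind": "linear", "K": self.stiffness}


@dataclass(frozen=True)
class CatchSpring:
    """Non-linear catch spring anchored ``dF_ns`` above the linear law.

    Parameters
    ----------
    stiffness
        Base (linear-term) stiffness ``K`` in N/m; must match the linear
        spring the subject trained on.
    target_force
        Target force ``F_target`` of the task (N).  The anchor position is
        ``x_t = F_target / K``, where the linear spring would exert
        ``F_target``.
    anchor_offset
        Force excess ``dF_ns`` (N) at the anchor position.  ``None`` resolves
        to 10 % of ``target_force`` (1.0 N at the 10 N target), scaling
        proportionally if the target is changed.
    exponent
        Shape exponent ``p`` of the excess term; ``p = 2`` by default, any
        value > 1 keeps the gap zero-at-origin and strictly increasing.
    """

    stiffness: float
    target_force: float = 10.0
    anchor_offset: float | None = field(default=None)
    exponent: float = 2.0

    def __post_init__(self) -> None:
        if not (self.stiffness > 0 and math.isfinite(self.stiffness)):
            raise SpringConfigError(
                f"stiffness must be positive and finite, got {self.stiffness!r}"
            )
        if not self.target_force > 0:
            raise SpringConfigError(
                f"target_force must be positive, got {self.target_force!r}"
            )
        if self.anchor_offset is None:
            object.__setattr__(self, "anchor_offset", 0.1 * self.target_force)
        if not self.anchor_offset > 0:
            raise SpringConfigError(
                f"anchor_offset must be positive, got {self.anchor_offset!r}"
            )
        if not self.exponent > 1:
            raise SpringConfigError(
                f"exponent must exceed 1 for a monotone gap, got {self.exponent!r}"
            )

    @property
    def anchor_position(self) -> float:
        """Position ``x_t`` where the linear spring exerts the target force."""
        return self.target_force / self.stiffness

    def force_at(self, x: float) -> float:
        _check_position(x)
        return self.stiffness * x + self.excess_at(x)

    def excess_at(self, x: float) -> float:
        """Force exceeding the linear law at position ``x`` (N, >= 0)."""
        _check_position(x)
        return self.anchor_offset * (x / self.anchor_position) ** self.exponent

    def position_for_force(self, force: float) -> float:
        _check_force(force)
        if force == 0.0:
            return 0.0
        if self.exponent == 2.0:
            # K x + c x^2 = F with c = dF_ns / x_t^2: positive quadratic root
            c = self.anchor_offset / self.anchor_position**2
            k = self.stiffness
            return (-k + math.sqrt(k * k + 4.0 * c * force)) / (2.0 * c)
        # general p: bracketed root of the monotone residual
        hi = force / self.stiffness  # F(hi) >= K*hi = F, residual >= 0
        return brentq(
            lambda x: self.force_at(x) - force, 0.0, hi, xtol=1e-14, rtol=8.9e-16
        )

    def to_dict(self) -> dict:
        return {
            "kind": "catch",
            "K": self.stiffness,
            "F_target": self.target_force,
            "dF_ns": self.anchor_offset,
            "p": self.exponent,
        }


Spring = LinearSpring | CatchSpring


def force_at(spring: Spring, x: float) -> float:
    """Force (N) exerted by *spring* at position *x* (m, >= 0)."""
    return spring.force_at(x)


def position_for_force(spring: Spring, force: float) -> float:
    """Position (m) at which *spring* exerts *force* (N, >= 0)."""
    return spring.position_for_force(force)


def _check_matched(stiffness: float, catch: CatchSpring) -> None:
    if not math.isclose(stiffness, catch.stiffness, rel_tol=1e-12):
        raise SpringConfigError(
            f"linear stiffness {stiffness!r} does not match catch-spring "
            f"stiffness {catch.stiffness!r}"
        )


def force_gap(stiffness: float, catch: CatchSpring, x: float) -> float:
    """Catch-minus-linear force difference (N) at position *x*.

    Both springs must share the same base stiffness; the gap is 0 at the
    origin and strictly increasing with position.
    """
    _check_matched(stiffness, catch)
    return catch.excess_at(x)


def position_gap(stiffness: float, catch: CatchSpring, force: float) -> float:
    """Linear-minus-catch position difference (m) at force *force*.

    This is the displacement saved by the catch spring to reach the same
    force; it is 0 at zero force and positive elsewhere.
    """
    _check_matched(stiffness, catch)
    _check_force(force)
    return force / stiffness - catch.position_for_force(force)


def spring_from_dict(obj: dict) -> Spring:
    """Rebuild a spring from its plain-JSON dict form (see ``to_dict``)."""
    kind = obj.get("kind")
    if kind == "linear":
        return LinearSpring(stiffness=obj["K"])
    if kind == "catch":
        return CatchSpring(
            stiffness=obj["K"],
            target_force=obj.get("F_target", 10.0),
            anchor_offset=obj.get("dF_ns"),
            exponent=obj.get("p", 2.0),
        )
    raise SpringConfigError(f"unknown spring kind {kind!r}")
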