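import pytest

from springmatch import CatchSpring, CohortConfig, GroupBehavior


@pytest.fixture
def default_catch() -> CatchSpring:
    """The worked-example catch spring: K=100 N/m, 10 N target, 1 N anchor."""
    return CatchSpring(stiffness=100.0, target_force=10.0, anchor_offset=1.0, exponent=2.0)


def noise_free_config(w_f: float | None = None, bias: float = 0.0, **kw) -> CohortConfig:
    """Cohort config with every noise source off.

    When ``w_f`` is given, both groups use a fixed weighting policy with that
    force weight; blind overshoot is ``bias`` for both groups.
    """
    behavior = {}
    if w_f is not None:
        b = GroupBehavior(policy="fixed", fixed_w_f=w_f, bias=bias)
        behavior = {"control": b, "patient": b}
    return CohortConfig(
        sensory_noise_scale=0.0,
        sensor_noise_sd=0.0,
        servo_noise_sd=0.0,
        slip_prob=0.0,
        **behavior,
        **kw,
    )
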