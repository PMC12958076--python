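"""Trial arms: four reminder framings crossed with three send timings, plus control.

The factorial design has 13 arms: a no-reminder control and the 4 x 3 grid of
message framing (neutral, positive = personal benefit, risk = personal risk,
social = pro-social benefit) by send timing (14 days before the due date, on
the due date, or 7 days after).
"""

from __future__ import annotations

from typing import NamedTuple, Optional

FRAMINGS = ("neutral", "positive", "risk", "social")
TIMINGS = (-14, 0, 7)

CONTROL_FRAMING = "control"


class Arm(NamedTuple):
    """One trial arm. ``timing`` is ``None`` exactly for the control arm."""

    framing: str
    timing: Optional[int]

    @property
    def is_control(self) -> bool:
        return self.framing == CONTROL_FRAMING

    @property
    def label(self) -> str:
        if self.is_control:
            return "control"
        sign = "+" if self.timing > 0 else ""
        return f"{self.framing}@day{sign}{self.timing}"


CONTROL = Arm(CONTROL_FRAMING, None)

#: All 13 arms, control first, then framing-major order over the 4 x 3 grid.
ARMS = (CONTROL,) + tuple(Arm(f, t) for f in FRAMINGS for t in TIMINGS)

SMS_ARMS = ARMS[1:]

ARM_INDEX = {arm: i for i, arm in enumerate(ARMS)}
ARM_BY_LABEL = {arm.label: arm for arm in ARMS}

N_ARMS = len(ARMS)
N_SMS_ARMS = len(SMS_ARMS)


def validate_arm(arm: Arm) -> Arm:
    """Check the framing/timing combination is one of the 13 valid arms."""
    if arm not in ARM_INDEX:
        raise ValueError(f"not a valid arm: {arm!r}")
    return arm
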