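"""Fragility index and fragility quotient of a significant 2x2 trial result.

The fragility index (FI) of a statistically significant dichotomous trial
result is the minimum number of patients whose outcome must flip from
non-event to event, within one arm and holding arm sizes fixed, for the
Fisher exact test to lose significance.  The fragility quotient (FQ)
normalizes the FI by the trial's total sample size and is reported as a
percentage.

Events are added to the arm with the fewer events by default (the Walsh
convention used by common web calculators): adding events to the arm that
already has more can only widen the observed difference and never nullify
it.  Fixed-arm conventions are available for sensitivity analyses.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .contingency import ArmCount, ContingencyTable, fisher_two_sided

__all__ = [
    "Arm",
    "ArmConvention",
    "FragilityConfig",
    "FragilityStep",
    "FragilityResult",
    "SaturationError",
    "select_target_arm",
    "add_event",
    "fragility_index",
    "fragility_quotient",
    "format_fq_percent",
]

logger = logging.getLogger(__name__)


class Arm(str, enum.Enum):
    EXPERIMENTAL = "experimental"
    CONTROL = "control"
    NONE = "none"


class ArmConvention(str, enum.Enum):
    """Which arm receives the added events during the FI iteration."""

    FEWEST_EVENTS = "fewest_events"
    EXPERIMENTAL = "experimental"
    CONTROL = "control"


class SaturationError(ValueError):
    """Raised when the target arm has no non-events left to convert."""


@dataclass(frozen=True)
class FragilityConfig:
    """Tunable knobs of the FI iteration.

    alpha is the significance threshold: a result is significant iff
    p < alpha, and is nullified at the first step where p >= alpha.
    """

    alpha: float = 0.05
    arm_convention: ArmConvention = ArmConvention.FEWEST_EVENTS

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not isinstance(self.arm_convention, ArmConvention):
            object.__setattr__(
                self, "arm_convention", ArmConvention(self.arm_convention)
            )


@dataclass(frozen=True)
class FragilityStep:
    """One event addition: the step index, arm modified, resulting table and p."""

    step: int
    arm: Arm
    table: ContingencyTable
    p_value: float


@dataclass(frozen=True)
class FragilityResult:
    fragility_index: int
    fragility_quotient_percent: float
    baseline_p: float
    final_p: float
    modified_arm: Arm
    trace: tuple[FragilityStep, ...] = field(default_factory=tuple)
    converged: bool = True


def select_target_arm(table: ContingencyTable, convention: ArmConvention) -> Arm:
    """Arm to which the next event is added.

    Under ``fewest_events`` the arm with the smaller event count is chosen
    (ties break to the experimental arm); the fixed conventions return their
    arm unconditionally.
    """
    convention = ArmConvention(convention)
    if convention is ArmConvention.EXPERIMENTAL:
        return Arm.EXPERIMENTAL
    if convention is ArmConvention.CONTROL:
        return Arm.CONTROL
    if table.experimental.events <= table.control.events:
        return Arm.EXPERIMENTAL
    return Arm.CONTROL


def add_event(table: ContingencyTable, arm: Arm) -> ContingencyTable:
    """Convert one non-event to an event in ``arm``; arm totals are fixed."""
    arm = Arm(arm)
    target = table.experimental if arm is Arm.EXPERIMENTAL else table.control
    if target.events >= target.total:
        raise SaturationError(f"{arm.value} arm has no non-events left to convert")
    bumped = ArmCount(target.events + 1, target.total)
    if arm is Arm.EXPERIMENTAL:
        return ContingencyTable(bumped, table.control)
    return ContingencyTable(table.experimental, bumped)


def fragility_index(
    table: ContingencyTable, config: FragilityConfig | None = None
) -> FragilityResult:
    """Compute the fragility index of a 2x2 trial table.

    If the baseline Fisher two-sided p is already >= alpha the FI is 0 (this
    occurs for trials whose reported significance came from a different
    test, e.g. a stratified log-rank on the time-to-event data).  Otherwise
    events are added one at a time to the convention-selected arm — the arm
    is re-selected after every step under ``fewest_events`` — until
    p >= alpha; the FI is the number of additions.

    If the target arm saturates before significance is lost the result
    carries ``converged=False`` with the steps taken so far, rather than
    raising, so cohort runs survive pathological tables.
    """
    if config is None:
        config = FragilityConfig()
    if not isinstance(config, FragilityConfig):
        raise TypeError(f"config must be a FragilityConfig, got {type(config)!r}")

    baseline_p = fisher_two_sided(table).p_two_sided
    n = table.grand_total

    if baseline_p >= config.alpha:
        return FragilityResult(
            fragility_index=0,
            fragility_quotient_percent=0.0,
            baseline_p=baseline_p,
            final_p=baseline_p,
            modified_arm=Arm.NONE,
        )

    trace: list[FragilityStep] = []
    current = table
    modified_arm = Arm.NONE
    converged = True
    while True:
        arm = select_target_arm(current, config.arm_convention)
        if modified_arm is Arm.NONE:
            modified_arm = arm
        try:
            current = add_event(current, arm)
        except SaturationError:
            logger.warning(
                "FI iteration did not converge: %s arm saturated after %d steps",
                arm.value,
                len(trace),
            )
            converged = False
            break
        p = fisher_two_sided(current).p_two_sided
        trace.append(FragilityStep(len(trace) + 1, arm, current, p))
        if p >= config.alpha:
            break

    fi = len(trace)
    final_p = trace[-1].p_value if trace else baseline_p
    return FragilityResult(
        fragility_index=fi,
        fragility_quotient_percent=fragility_quotient(fi, n),
        baseline_p=baseline_p,
        final_p=final_p,
        modified_arm=modified_arm,
        trace=tuple(trace),
        converged=converged,
    )


def fragility_quotient(fi: int, total_n: int) -> float:
    """FQ = 100 * FI / N, the fragility index as a percentage of sample size."""
    if fi < 0:
        raise ValueError("fragility index must be non-negative")
    if total_n < 2:
        raise ValueError("total sample size must be at least 2")
    return 100.0 * fi / total_n


def format_fq_percent(fq: float) -> str:
    """Render an FQ for reports: half-up rounding to 2 decimals, e.g. '3.41%'."""
    return f"{Decimal(repr(fq)).quantize(Decimal('0.01'), rounding=ROUND_HALF_UP)}%"
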