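"""Exact probability machinery for 2x2 contingency tables.

The fragility index rests on Fisher's exact test: conditional on the row and
column margins of a 2x2 table, the count in one cell follows a hypergeometric
distribution, and the two-sided p-value is the total probability of all
tables no more probable than the one observed.  Both the hypergeometric pmf
and the test are implemented here from first principles (log-gamma
accumulation over the full support) so that the enumeration itself is
available as an in-repo oracle; no statistical library is delegated to.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

__all__ = [
    "ArmCount",
    "ContingencyTable",
    "ExactTestResult",
    "hypergeom_pmf",
    "hypergeom_support",
    "fisher_two_sided",
]

logger = logging.getLogger(__name__)

# Relative tolerance for "no more probable than the observed table": two
# tables whose probabilities agree to ~1e-7 are treated as tied, matching
# the convention of mainstream exact-test implementations.
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ArmCount:
    """Event and patient counts for one arm of a two-arm trial.

    Parameters
    ----------
    events : int
        Number of patients with the dichotomous outcome (0 <= events <= total).
    total : int
        Arm sample size (>= 1).
    """

    events: int
    total: int

    def __post_init__(self) -> None:
        if not isinstance(self.events, int) or not isinstance(self.total, int):
            raise TypeError("events and total must be integers")
        if self.total < 1:
            raise ValueError(f"arm total must be positive, got {self.total}")
        if not 0 <= self.events <= self.total:
            raise ValueError(
                f"events must satisfy 0 <= events <= total, got "
                f"events={self.events}, total={self.total}"
            )

    @property
    def non_events(self) -> int:
        return self.total - self.events


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cross-tabulation of trial arm against event/non-event outcome."""

    experimental: ArmCount
    control: ArmCount

    @property
    def grand_total(self) -> int:
        return self.experimental.total + self.control.total

    @property
    def total_events(self) -> int:
        return self.experimental.events + self.control.events

    @classmethod
    def from_counts(
        cls, exp_events: int, exp_total: int, ctrl_events: int, ctrl_total: int
    ) -> "ContingencyTable":
        return cls(ArmCount(exp_events, exp_total), ArmCount(ctrl_events, ctrl_total))

    def swapped_arms(self) -> "ContingencyTable":
        return ContingencyTable(self.control, self.experimental)

    def swapped_outcomes(self) -> "ContingencyTable":
        """Relabel events as non-events and vice versa in both arms."""
        return ContingencyTable(
            ArmCount(self.experimental.non_events, self.experimental.total),
            ArmCount(self.control.non_events, self.control.total),
        )


@dataclass(frozen=True)
class ExactTestResult:
    """Outcome of a two-sided Fisher exact test."""

    p_two_sided: float
    observed_table_probability: float


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_support(population: int, successes: int, draws: int) -> range:
    """Support of the hypergeometric count: attainable values of k."""
    return range(max(0, draws + successes - population), min(draws, successes) + 1)


def hypergeom_pmf(k: int, population: int, successes: int, draws: int) -> float:
    """P(K = k) for K hypergeometric(population, successes, draws).

    Probability that k of the ``draws`` items sampled without replacement
    from a population containing ``successes`` marked items are marked:
    C(successes, k) * C(population - successes, draws - k) / C(population, draws),
    evaluated via log-gamma so trial-scale counts cannot overflow.

    Raises
    ------
    ValueError
        If the parameters are inconsistent or k lies outside the support.
    """
    if not 0 <= successes <= population:
        raise ValueError(f"need 0 <= successes <= population, got {successes}, {population}")
    if not 0 <= draws <= population:
        raise ValueError(f"need 0 <= draws <= population, got {draws}, {population}")
    if k not in hypergeom_support(population, successes, draws):
        raise ValueError(
            f"k={k} outside hypergeometric support "
            f"[{max(0, draws + successes - population)}, {min(draws, successes)}]"
        )
    log_p = (
        _log_binom(successes, k)
        + _log_binom(population - successes, draws - k)
        - _log_binom(population, draws)
    )
    return math.exp(log_p)


def _canonical_orientation(table: ContingencyTable) -> ContingencyTable:
    # The two-sided p is invariant under swapping the arms and under
    # swapping the event/non-event columns; picking a deterministic
    # representative of the 4-element orbit makes that invariance hold
    # bitwise, not just to rounding.
    variants = [
        table,
        table.swapped_arms(),
        table.swapped_outcomes(),
        table.swapped_arms().swapped_outcomes(),
    ]
    return min(
        variants,
        key=lambda t: (
            t.experimental.total,
            t.control.total,
            t.experimental.events,
            t.control.events,
        ),
    )


def fisher_two_sided(table: ContingencyTable) -> ExactTestResult:
    """Two-sided Fisher exact test by full enumeration of the conditional support.

    Conditions on the observed margins and sums the hypergeometric
    probabilities of every table that is no more probable than the observed
    one (minimum-likelihood two-sided convention), with a small relative
    tolerance so floating-point near-ties count as ties.

    A degenerate table (no events at all, or events in every patient) admits
    a single conditional table; p = 1 is returned with a warning rather than
    an error so iterative callers can terminate gracefully.
    """
    table = _canonical_orientation(table)
    n = table.grand_total
    k_total = table.total_events
    draws = table.experimental.total
    observed = table.experimental.events

    if k_total == 0 or k_total == n:
        logger.warning(
            "degenerate 2x2 table (all-zero event or non-event column); p = 1.0"
        )
        return ExactTestResult(p_two_sided=1.0, observed_table_probability=1.0)

    support = hypergeom_support(n, k_total, draws)
    log_pmf = {
        k: (
            _log_binom(k_total, k)
            + _log_binom(n - k_total, draws - k)
            - _log_binom(n, draws)
        )
        for k in support
    }
    p_obs = math.exp(log_pmf[observed])
    cutoff = p_obs * (1.0 + _TIE_RTOL)
    p = sum(math.exp(lp) for lp in log_pmf.values() if math.exp(lp) <= cutoff)
    return ExactTestResult(
        p_two_sided=min(p, 1.0), observed_table_probability=p_obs
    )
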