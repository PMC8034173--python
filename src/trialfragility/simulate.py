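"""Synthetic two-arm trial generator and fragility simulations.

Emulates the statistical structure the fragility analysis assumes: two-arm
1:1 trials whose per-arm event counts are independent binomial draws at
configurable event rates.  There is no time axis — the FI method itself
collapses time-to-event outcomes to end-of-study counts, so the generator
matches what the analysis actually sees.

The experiment here quantifies the direction of the relationship between a
significant trial's fragility index and its baseline p-value: across
simulated trials that reach significance, higher p-values should come with
lower FIs (a rank correlation below zero).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import spearmanr

from .cohort import EndpointRank, TrialRecord
from .contingency import ContingencyTable
from .fragility import FragilityConfig, fragility_index

__all__ = [
    "SimulationConfig",
    "InsufficientSampleError",
    "DEFAULT_EXPERIMENT_CONFIG",
    "simulate_trial",
    "simulate_trials",
    "fi_p_correlation_experiment",
]


class InsufficientSampleError(RuntimeError):
    """Too few significant trials, or no FI variance, for a rank correlation."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a batch of simulated 1:1 two-arm trials.

    The seed is mandatory: every draw is derived from (seed, trial index),
    so any single trial is reproducible without generating its predecessors.
    """

    n_per_arm: int
    event_rate_experimental: float
    event_rate_control: float
    n_trials: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")
        for name in ("event_rate_experimental", "event_rate_control"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        if not isinstance(self.seed, int):
            raise TypeError("seed must be an integer (no implicit entropy)")


# Defaults for the FI-vs-p experiment: a 0.5 vs 0.3 event-rate contrast at
# n=100/arm gives well over 50% power for Fisher's test at alpha 0.05, so
# the significant subset is large enough for a stable rank correlation.
DEFAULT_EXPERIMENT_CONFIG = SimulationConfig(
    n_per_arm=100,
    event_rate_experimental=0.5,
    event_rate_control=0.3,
    n_trials=1000,
    seed=0,
)


def simulate_trial(config: SimulationConfig, index: int) -> TrialRecord:
    """Draw one simulated trial; identical (config, index) give identical records."""
    if not 0 <= index < config.n_trials:
        raise ValueError(f"index must lie in [0, {config.n_trials}), got {index}")
    rng = np.random.default_rng([config.seed, index])
    exp_events = int(rng.binomial(config.n_per_arm, config.event_rate_experimental))
    ctrl_events = int(rng.binomial(config.n_per_arm, config.event_rate_control))
    return TrialRecord(
        study_label=f"sim-{index:05d}",
        registry_id=f"SIM{config.seed}-{index:05d}",
        comparison="simulated experimental vs. simulated control",
        endpoint_label="simulated dichotomous outcome",
        endpoint_rank=EndpointRank.PRIMARY,
        table=ContingencyTable.from_counts(
            exp_events, config.n_per_arm, ctrl_events, config.n_per_arm
        ),
        reported_p=None,
        allocation_ratio="1:1",
    )


def simulate_trials(config: SimulationConfig) -> list[TrialRecord]:
    return [simulate_trial(config, i) for i in range(config.n_trials)]


def fi_p_correlation_experiment(
    config: SimulationConfig = DEFAULT_EXPERIMENT_CONFIG,
    fragility_config: FragilityConfig | None = None,
    min_significant: int = 10,
) -> tuple[float, int]:
    """Spearman rank correlation between FI and baseline p over significant trials.

    Simulates ``config.n_trials`` trials, computes each trial's baseline
    Fisher p and fragility index, restricts to trials significant at the
    fragility alpha, and returns ``(rho, n_significant)``.

    Raises
    ------
    InsufficientSampleError
        If fewer than ``min_significant`` trials reach significance, or the
        significant trials' FIs (or p's) are all identical so a rank
        correlation is undefined.
    """
    if fragility_config is None:
        fragility_config = FragilityConfig()
    fis: list[int] = []
    ps: list[float] = []
    for record in simulate_trials(config):
        result = fragility_index(record.table, fragility_config)
        if result.baseline_p < fragility_config.alpha:
            fis.append(result.fragility_index)
            ps.append(result.baseline_p)
    if len(fis) < min_significant:
        raise InsufficientSampleError(
            f"only {len(fis)} significant trials (< {min_significant}); "
            "increase n_trials or the event-rate contrast"
        )
    if len(set(fis)) < 2 or len(set(ps)) < 2:
        raise InsufficientSampleError(
            "rank correlation undefined: no variance in FI or p across "
            "significant trials"
        )
    rho = float(spearmanr(fis, ps).statistic)
    return rho, len(fis)


def doubled_n_config(config: SimulationConfig) -> SimulationConfig:
    """Same rates and seed policy with twice the per-arm sample size."""
    return replace(config, n_per_arm=2 * config.n_per_arm)
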