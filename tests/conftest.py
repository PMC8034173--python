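"""Shared fixtures and independent oracles.

The Fisher oracle here deliberately avoids the package's log-space path:
it enumerates the conditional support with exact rational arithmetic
(``fractions`` + ``math.comb``), so agreement between the two is a real
cross-check and not a tautology.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from trialfragility import ContingencyTable


def exact_fisher_oracle(table: ContingencyTable) -> float:
    """Two-sided Fisher p by exact rational enumeration of all tables."""
    n = table.grand_total
    k_total = table.total_events
    draws = table.experimental.total
    if k_total == 0 or k_total == n:
        return 1.0
    denom = comb(n, draws)
    lo = max(0, draws + k_total - n)
    hi = min(draws, k_total)
    probs = {
        k: Fraction(comb(k_total, k) * comb(n - k_total, draws - k), denom)
        for k in range(lo, hi + 1)
    }
    p_obs = probs[table.experimental.events]
    return float(sum(p for p in probs.values() if p <= p_obs))


def random_table(rng: np.random.Generator, max_arm: int = 80) -> ContingencyTable:
    """One random 2x2 trial table with arm sizes in [2, max_arm]."""
    n_exp = int(rng.integers(2, max_arm + 1))
    n_ctrl = int(rng.integers(2, max_arm + 1))
    return ContingencyTable.from_counts(
        int(rng.integers(0, n_exp + 1)), n_exp, int(rng.integers(0, n_ctrl + 1)), n_ctrl
    )


@pytest.fixture(scope="session")
def table1_tables() -> dict[str, ContingencyTable]:
    """The six cohort 2x2 tables keyed by study label."""
    return {
        "SILIUS": ContingencyTable.from_counts(37, 102, 18, 103),
        "Wang Z": ContingencyTable.from_counts(46, 140, 82, 140),
        "Lee JH": ContingencyTable.from_counts(69, 114, 59, 112),
        "SHARP": ContingencyTable.from_counts(44, 299, 33, 303),
        "Wei W": ContingencyTable.from_counts(83, 116, 85, 118),
        "Geissler EK": ContingencyTable.from_counts(242, 252, 234, 256),
    }


TABLE1_EXPECTED_FI = {
    "SILIUS": 7,
    "Wang Z": 19,
    "Lee JH": 0,
    "SHARP": 0,
    "Wei W": 0,
    "Geissler EK": 1,
}

TABLE1_EXPECTED_FQ = {
    "SILIUS": "3.41%",
    "Wang Z": "6.79%",
    "Lee JH": "0.00%",
    "SHARP": "0.00%",
    "Wei W": "0.00%",
    "Geissler EK": "0.20%",
}
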