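"""Pure scoring primitives for metabolite availability and receptor expression.

All quantities are computed on linear (not log-transformed) per-cell-type mean
expression.  The combined score for one (sender, receiver, interaction) triple
is the Euclidean norm of the sender-side metabolite availability M and the
receiver-side receptor expression R; M itself is the Euclidean norm of the net
enzyme expression E and the transporter expression T.

Conventions (all configurable where noted):

* The geometric mean of an empty set is 0 — a metabolite with no annotated
  producers contributes nothing to the production term, and no transporters
  means T = 0.
* A zero anywhere in a geometric mean zeroes it (a receptor complex with one
  silent subunit is not expressed).
* E = gmean(producers) − gmean(consumers) may be negative; by default M
  squares E literally, a ``clamp`` policy replaces negative E with 0 first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

NEGATIVE_E_POLICIES = ("literal", "clamp")


def geometric_mean(values: Sequence[float]) -> float:
    """Geometric mean of non-negative values; empty input or any zero give 0.

    Computed as the direct product root when the running product stays in
    floating range, falling back to the log domain for long inputs whose
    product would under- or overflow.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        return 0.0
    if np.any(v < 0):
        raise ValueError("geometric_mean requires non-negative values")
    if np.any(v == 0):
        return 0.0
    prod = float(np.prod(v))
    if 0.0 < prod < math.inf:
        return prod ** (1.0 / v.size)
    # under/overflowed product: exact in the log domain
    return float(np.exp(np.mean(np.log(v))))


@dataclass
class EnzymeInputs:
    """Sender-side mean expression of producer (P_i) and consumer (S_j) enzymes."""

    producer_means: list[float]
    consumer_means: list[float]

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.producer_means) or any(
            s < 0 for s in self.consumer_means
        ):
            raise ValueError("enzyme mean expression must be non-negative")


@dataclass
class TransporterInputs:
    transporter_means: list[float]

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.transporter_means):
            raise ValueError("transporter mean expression must be non-negative")


@dataclass
class AvailabilityScore:
    E: float
    T: float
    M: float
    policy_applied: str


@dataclass
class ReceptorScore:
    R: float
    subunit_means: list[float] = field(default_factory=list)


@dataclass
class PairScore:
    MR: float


def enzyme_net_expression(inp: EnzymeInputs) -> float:
    """Net enzyme expression: gmean of producers minus gmean of consumers."""
    return geometric_mean(inp.producer_means) - geometric_mean(inp.consumer_means)


def transporter_expression(inp: TransporterInputs) -> float:
    """Transporter expression: gmean of transporter means (0 when none)."""
    return geometric_mean(inp.transporter_means)


def metabolite_availability(E: float, T: float, policy: str = "literal") -> AvailabilityScore:
    """Availability M = sqrt(E'^2 + T^2), with E' = E or max(E, 0) under clamp."""
    if T < 0:
        raise ValueError("transporter expression T must be non-negative")
    if policy not in NEGATIVE_E_POLICIES:
        raise ValueError(f"unknown negative-E policy {policy!r}")
    e_eff = E if policy == "literal" else max(E, 0.0)
    return AvailabilityScore(E=E, T=T, M=math.hypot(e_eff, T), policy_applied=policy)


def receptor_expression(subunit_means: Sequence[float]) -> ReceptorScore:
    """Receptor expression: gmean over the complex's subunit means (q >= 1)."""
    if len(subunit_means) == 0:
        raise ValueError("a receptor complex must have at least one subunit")
    return ReceptorScore(R=geometric_mean(subunit_means), subunit_means=list(subunit_means))


def mr_score(M: float, R: float) -> PairScore:
    """Combined communication score: Euclidean norm of M and R."""
    if M < 0 or R < 0:
        raise ValueError("M and R must be non-negative")
    return PairScore(MR=math.hypot(M, R))
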