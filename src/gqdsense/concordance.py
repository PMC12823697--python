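"""Cross-method / cross-phase trend agreement.

With only a handful of systems per table, robustness claims rest on rank
orderings and signs agreeing between functionals and phases, not on
magnitudes. The rank statistic is plain Kendall pair counting,
(concordant - discordant) / all pairs, with tied pairs counted as
neither (no tie-correction term — the defensible choice at n = 3-6).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .errors import GqdError


def rank_concordance(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Pair-counting rank concordance in [-1, 1] for label-paired lists.

    1.0 iff the orderings are identical (no ties), -1.0 iff exactly
    reversed; invariant under strictly monotone transforms of either list.
    """
    if len(values_a) != len(values_b):
        raise GqdError(f"length mismatch: {len(values_a)} vs {len(values_b)}")
    n = len(values_a)
    if n < 2:
        raise GqdError("rank concordance needs at least two paired values")
    concordant = discordant = 0
    for i, j in combinations(range(n), 2):
        da = values_a[i] - values_a[j]
        db = values_b[i] - values_b[j]
        prod = da * db
        if prod > 0:
            concordant += 1
        elif prod < 0:
            discordant += 1
        # ties in either list count as neither
    return (concordant - discordant) / (n * (n - 1) / 2)


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def sign_agreement(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Fraction of paired entries with equal sign (zero is its own sign)."""
    if len(values_a) != len(values_b):
        raise GqdError(f"length mismatch: {len(values_a)} vs {len(values_b)}")
    if not values_a:
        raise GqdError("sign agreement needs at least one pair")
    hits = sum(_sign(a) == _sign(b) for a, b in zip(values_a, values_b))
    return hits / len(values_a)


@dataclass(frozen=True)
class TrendReport:
    """Agreement of one quantity between two method/phase slices."""

    quantity: str
    labels: tuple[str, ...]
    tau_rank: float
    sign_agreement: float


def trend_report(
    quantity: str,
    labels: Sequence[str],
    values_a: Sequence[float],
    values_b: Sequence[float],
) -> TrendReport:
    if not (len(labels) == len(values_a) == len(values_b)):
        raise GqdError("labels and value lists must pair up one-to-one")
    return TrendReport(
        quantity=quantity,
        labels=tuple(labels),
        tau_rank=rank_concordance(values_a, values_b),
        sign_agreement=sign_agreement(values_a, values_b),
    )
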