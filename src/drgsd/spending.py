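"""Error-spending functions of Lan-DeMets type.

Two families are provided, both used for alpha- and for beta-spending:

* Pocock-like:            f(t) = level * ln(1 + (e - 1) * t)
* O'Brien-Fleming-like:   f(t) = 2 * (1 - Phi(Phi^{-1}(1 - level / 2) / sqrt(t)))

Both are nondecreasing with f(0) = 0 and f(1) = level (the OBF-like form to
machine precision).  The Pocock-like family spends error nearly uniformly on
the z-scale, producing roughly constant interim boundaries; the OBF-like
family spends almost nothing early, producing conservative interim
boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .design import SPENDING_FAMILIES

__all__ = ["SpendingSpec", "spend", "spending_increments", "DegenerateSpendError"]


class DegenerateSpendError(ValueError):
    """Raised when no error is left for the final analysis."""


@dataclass(frozen=True)
class SpendingSpec:
    """One spending function: family, total level to spend, and role.

    ``role`` is purely descriptive (``"alpha_spending"`` or
    ``"beta_spending"``); the functional form depends only on ``family`` and
    ``total_level``.
    """

    family: str
    total_level: float
    role: str = "alpha_spending"

    def __post_init__(self) -> None:
        if self.family not in SPENDING_FAMILIES:
            raise ValueError(f"unknown spending family {self.family!r}")
        if not 0.0 < self.total_level < 1.0:
            raise ValueError(f"total_level must be in (0, 1), got {self.total_level}")
        if self.role not in ("alpha_spending", "beta_spending"):
            raise ValueError(f"unknown spending role {self.role!r}")


def spend(t: float, spec: SpendingSpec) -> float:
    """Cumulative error spent by information fraction ``t`` in [0, 1]."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"information fraction must be in [0, 1], got {t}")
    if t == 0.0:
        return 0.0
    level = spec.total_level
    if spec.family == "pocock_like":
        return level * math.log1p((math.e - 1.0) * t)
    # O'Brien-Fleming-like
    return 2.0 * float(norm.sf(norm.isf(level / 2.0) / math.sqrt(t)))


def spending_increments(spec: SpendingSpec, t1: float) -> tuple[float, float]:
    """Split the total level into interim and final-stage increments.

    Returns ``(f(t1), level - f(t1))``; raises if either increment is not
    strictly positive (a two-stage design needs error at both analyses).
    """
    if not 0.0 < t1 < 1.0:
        raise ValueError(f"interim fraction must be in (0, 1), got {t1}")
    stage1 = spend(t1, spec)
    stage2 = spec.total_level - stage1
    if stage1 <= 0.0 or stage2 <= 0.0:
        raise DegenerateSpendError(
            f"degenerate spend at t1={t1}: stage-1 {stage1:.3e}, stage-2 {stage2:.3e}"
        )
    return stage1, stage2
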