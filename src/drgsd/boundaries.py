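"""Boundary solvers for the three two-stage designs.

All three designs spend a one-sided type-I error ``alpha`` and a type-II
error ``beta`` across the interim and final analyses via error-spending
functions evaluated at the interim information fraction ``I1``.  The solved
boundary set is ``{l1, u1, d1, d2}``:

* ``(l1, u1)`` — the interim continuation region for ``Z1``.  Crossing it
  stops recruitment (standard GSD: stops the trial).
* ``d1``      — decision critical value applied to the enlarged statistic
  ``Zt1`` after a recruitment stop (delayed-response designs only).
* ``d2``      — final critical value applied to the inverse-normal
  combination ``Z12`` when the trial continues.

The lower boundary is nonbinding throughout: ``u1`` and ``d2`` are computed
as if the trial always continues after ``Z1 < u1``, so ignoring a futility
signal can never inflate the type-I error above ``alpha``.

The design alternative ``delta_tilde`` is the effect at which the type-II
spending is anchored; it is calibrated per design so that, at the fixed
maximum sample size, the design's type-II spending partition sums to
``beta`` (equivalently, its power at ``delta_tilde`` is ``1 - beta``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .design import (
    DR_GSD,
    GSD,
    ROOT_XTOL,
    RR_GSD,
    Z_BRACKET,
    CanonicalModel,
    DesignSpec,
    InvalidDesignError,
    canonical_model,
    mvn_rect_prob,
)
from .spending import DegenerateSpendError, SpendingSpec, spending_increments

__all__ = [
    "BoundarySet",
    "solve_boundaries",
    "solve_gsd_boundaries",
    "solve_drgsd_boundaries",
    "solve_rrgsd_boundaries",
    "calibrate_design_alternative",
]

_INF = math.inf
RESIDUAL_TOL = 1e-6


@dataclass(frozen=True)
class BoundarySet:
    """Solved decision boundaries with spent errors and diagnostics.

    ``d1`` is ``None`` for the standard GSD (no decision analysis).
    ``diagnostics`` maps each defining equation to its residual in
    probability units, plus iteration metadata.
    """

    design_kind: str
    l1: float
    u1: float
    d1: float | None
    d2: float
    alpha1: float
    beta1: float
    delta_tilde: float
    diagnostics: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.l1 < self.u1:
            raise InvalidDesignError(
                f"continuation region empty: l1={self.l1:.4f} >= u1={self.u1:.4f}"
            )
        for name in ("l1", "u1", "d2"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidDesignError(f"{name} is not finite")

    def to_record(self) -> dict:
        """Flat record mirroring the standard reporting columns."""
        return {
            "design": self.design_kind,
            "l1": self.l1,
            "u1": self.u1,
            "d1": self.d1,
            "d2": self.d2,
            "alpha1": self.alpha1,
            "beta1": self.beta1,
            "delta_tilde": self.delta_tilde,
        }

    def to_json(self, path: str | Path) -> None:
        payload = dict(self.to_record(), diagnostics=self.diagnostics)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @property
    def max_residual(self) -> float:
        return max(
            (abs(v) for k, v in self.diagnostics.items() if k.startswith("residual")),
            default=math.nan,
        )


def _std_drift(spec: DesignSpec, delta: float, info: float) -> float:
    """Mean of the standardized statistic at information fraction ``info``."""
    return (delta / spec.sigma) * math.sqrt(info * spec.n_max / 2.0)


def _corr2(a: float, b: float) -> np.ndarray:
    r = math.sqrt(a / b)
    return np.array([[1.0, r], [r, 1.0]])


def _bracketed_root(f: Callable[[float], float], lo: float, hi: float) -> float:
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0.0:
        raise InvalidDesignError(
            f"no sign change in bracket [{lo}, {hi}]: f(lo)={flo:.3e}, f(hi)={fhi:.3e}"
        )
    return float(brentq(f, lo, hi, xtol=ROOT_XTOL))


def calibrate_design_alternative(
    spec: DesignSpec,
    power_fn: Callable[[float], float],
    max_std_drift: float = 10.0,
) -> float:
    """Solve for the design alternative ``delta_tilde > 0``.

    ``power_fn(delta)`` must return the design's power at effect ``delta``
    (with the effect-dependent lower boundary folded in); the returned
    ``delta_tilde`` satisfies ``power_fn(delta_tilde) == 1 - beta`` to the
    root tolerance.  The search is on the standardized final-analysis drift
    in ``(0, max_std_drift]``, converted back to outcome units.
    """
    target = 1.0 - spec.beta
    scale = spec.sigma / math.sqrt(spec.n_max / 2.0)  # delta per unit drift

    def f(theta: float) -> float:
        return power_fn(theta * scale) - target

    lo, hi = 1e-8, max_std_drift
    if f(hi) < 0.0:
        raise InvalidDesignError(
            "design alternative calibration failed: power below target even at "
            f"standardized drift {max_std_drift}"
        )
    theta = _bracketed_root(f, lo, hi)
    return theta * scale


# ---------------------------------------------------------------------------
# Standard error-spending GSD
# ---------------------------------------------------------------------------


def _spending_levels(spec: DesignSpec) -> tuple[float, float, float, float]:
    alpha_spec = SpendingSpec(spec.spending_family, spec.alpha, "alpha_spending")
    beta_spec = SpendingSpec(spec.spending_family, spec.beta, "beta_spending")
    a1, a2 = spending_increments(alpha_spec, spec.info_interim)
    b1, b2 = spending_increments(beta_spec, spec.info_interim)
    return a1, a2, b1, b2


def _solve_gsd_core(spec: DesignSpec) -> tuple[float, float, float, float, float, float]:
    """Shared {l1, u1, d2, delta_tilde} solve for GSD and DR-GSD."""
    I1 = spec.info_interim
    a1, a2, b1, b2 = _spending_levels(spec)
    u1 = float(norm.isf(a1))
    corr_1f = _corr2(I1, 1.0)

    # Final critical value: exhaust the remaining alpha assuming continuation
    # whenever Z1 < u1 (nonbinding lower boundary).
    def g_d2(d: float) -> float:
        return mvn_rect_prob([-_INF, d], [u1, _INF], [0.0, 0.0], corr_1f) - a2

    d2 = _bracketed_root(g_d2, 0.0, Z_BRACKET[1])

    z_b1 = float(norm.ppf(b1))

    def l1_of(delta: float) -> float:
        # Interim beta-spend: P_delta(Z1 <= l1) = b1.
        return z_b1 + _std_drift(spec, delta, I1)

    def power(delta: float) -> float:
        th1 = _std_drift(spec, delta, I1)
        thf = _std_drift(spec, delta, 1.0)
        l1 = l1_of(delta)
        p_int = float(norm.sf(u1 - th1))
        if l1 >= u1:  # continuation region empty at this probe effect
            return p_int
        p_fin = mvn_rect_prob([l1, d2], [u1, _INF], [th1, thf], corr_1f)
        return p_int + p_fin

    delta_tilde = calibrate_design_alternative(spec, power)
    l1 = l1_of(delta_tilde)
    return l1, u1, d2, delta_tilde, a1, b1


def solve_gsd_boundaries(spec: DesignSpec) -> BoundarySet:
    """Standard two-stage error-spending design with nonbinding futility.

    ``u1 = Phi^{-1}(1 - alpha1)``; ``d2`` exhausts the remaining alpha under
    the null assuming continuation below ``u1``; ``(l1, delta_tilde)`` solve
    the interim beta-spend together with the power-calibration identity.
    """
    l1, u1, d2, delta_tilde, a1, b1 = _solve_gsd_core(spec)
    diag = _gsd_diagnostics(spec, l1, u1, d2, delta_tilde, a1, b1)
    return BoundarySet(
        design_kind=GSD,
        l1=l1,
        u1=u1,
        d1=None,
        d2=d2,
        alpha1=a1,
        beta1=b1,
        delta_tilde=delta_tilde,
        diagnostics=diag,
    )


def _gsd_diagnostics(spec, l1, u1, d2, delta_tilde, a1, b1) -> dict:
    I1 = spec.info_interim
    corr_1f = _corr2(I1, 1.0)
    th1 = _std_drift(spec, delta_tilde, I1)
    thf = _std_drift(spec, delta_tilde, 1.0)
    return {
        "residual_u1": float(norm.sf(u1)) - a1,
        "residual_d2": mvn_rect_prob([-_INF, d2], [u1, _INF], [0, 0], corr_1f)
        - (spec.alpha - a1),
        "residual_l1": float(norm.cdf(l1 - th1)) - b1,
        "residual_power": (
            float(norm.sf(u1 - th1))
            + mvn_rect_prob([l1, d2], [u1, _INF], [th1, thf], corr_1f)
            - (1.0 - spec.beta)
        ),
    }


# ---------------------------------------------------------------------------
# Delayed-response GSD (nonbinding recruitment-stopping boundary)
# ---------------------------------------------------------------------------


def solve_drgsd_boundaries(spec: DesignSpec) -> BoundarySet:
    """Delayed-response design: GSD boundaries plus a balanced ``d1``.

    ``{l1, u1, d2, delta_tilde}`` coincide with the standard GSD solution.
    The decision value ``d1`` balances, under the null, the probability of a
    promising recruitment stop followed by non-rejection against a futility
    stop followed by rejection:
    ``P0(Z1 >= u1, Zt1 < d1) = P0(Z1 <= l1, Zt1 >= d1)``.
    That balance makes the design spend exactly ``alpha1`` at the decision
    analysis when the lower boundary is respected, and less when it is
    ignored — hence nonbinding type-I control.
    """
    if spec.info_pipeline <= 0.0:
        raise InvalidDesignError(
            "DR_GSD requires info_pipeline > 0 (otherwise any d1 in [l1, u1] "
            "trivially satisfies the balance equation)"
        )
    l1, u1, d2, delta_tilde, a1, b1 = _solve_gsd_core(spec)
    corr_1t = _corr2(spec.info_interim, spec.info_decision)

    def g(d1: float) -> float:
        promising_miss = mvn_rect_prob([u1, -_INF], [_INF, d1], [0, 0], corr_1t)
        futility_hit = mvn_rect_prob([-_INF, d1], [l1, _INF], [0, 0], corr_1t)
        return promising_miss - futility_hit

    d1 = _bracketed_root(g, *Z_BRACKET)
    diag = _gsd_diagnostics(spec, l1, u1, d2, delta_tilde, a1, b1)
    diag["residual_d1_balance"] = g(d1)
    return BoundarySet(
        design_kind=DR_GSD,
        l1=l1,
        u1=u1,
        d1=d1,
        d2=d2,
        alpha1=a1,
        beta1=b1,
        delta_tilde=delta_tilde,
        diagnostics=diag,
    )


# ---------------------------------------------------------------------------
# Repeated-rejection GSD
# ---------------------------------------------------------------------------


def solve_rrgsd_boundaries(spec: DesignSpec) -> BoundarySet:
    """Repeated-rejection design: interim rejection needs Z1 and Zt1.

    ``d1`` is fixed at ``Phi^{-1}(1 - alpha)``; ``u1`` spends ``alpha1`` on
    the joint event ``{Z1 >= u1, Zt1 >= d1}``; ``d2`` exhausts the remaining
    alpha assuming continuation below ``u1``; the interim type-II spend
    covers both futility routes
    ``{Z1 <= l1}`` and ``{Z1 >= u1, Zt1 < d1}``.
    """
    if spec.info_pipeline <= 0.0:
        raise InvalidDesignError("RR_GSD requires info_pipeline > 0")
    I1, It1 = spec.info_interim, spec.info_decision
    a1, a2, b1, b2 = _spending_levels(spec)
    corr_1t = _corr2(I1, It1)
    corr_1f = _corr2(I1, 1.0)
    d1 = float(norm.isf(spec.alpha))

    # u1: P0(Z1 >= u1, Zt1 >= d1) = alpha1  (decreasing in u1).
    def g_u1(u: float) -> float:
        return mvn_rect_prob([u, d1], [_INF, _INF], [0, 0], corr_1t) - a1

    u1 = _bracketed_root(g_u1, *Z_BRACKET)

    def g_d2(d: float) -> float:
        return mvn_rect_prob([-_INF, d], [u1, _INF], [0, 0], corr_1f) - a2

    d2 = _bracketed_root(g_d2, 0.0, Z_BRACKET[1])

    z_cache: dict[float, float] = {}

    def l1_of(delta: float) -> float:
        # Interim beta-spend shared by the two futility routes:
        # P(Z1 <= l1) + P(Z1 >= u1, Zt1 < d1) = beta1.
        th1 = _std_drift(spec, delta, I1)
        tht = _std_drift(spec, delta, It1)
        p_promising_miss = mvn_rect_prob([u1, -_INF], [_INF, d1], [th1, tht], corr_1t)
        remainder = b1 - p_promising_miss
        if remainder <= 0.0:
            raise DegenerateSpendError(
                "no interim type-II error left for the lower boundary at "
                f"delta={delta:.4f} (promising-miss probability "
                f"{p_promising_miss:.4e} >= beta1={b1:.4e})"
            )
        return float(norm.ppf(remainder)) + th1

    def power(delta: float) -> float:
        th1 = _std_drift(spec, delta, I1)
        tht = _std_drift(spec, delta, It1)
        thf = _std_drift(spec, delta, 1.0)
        l1 = l1_of(delta)
        p_int = mvn_rect_prob([u1, d1], [_INF, _INF], [th1, tht], corr_1t)
        if l1 >= u1:  # continuation region empty at this probe effect
            return p_int
        p_fin = mvn_rect_prob([l1, d2], [u1, _INF], [th1, thf], corr_1f)
        return p_int + p_fin

    delta_tilde = calibrate_design_alternative(spec, power)
    l1 = l1_of(delta_tilde)
    if l1 >= u1:
        raise InvalidDesignError(
            f"RR_GSD continuation region empty: l1={l1:.4f} >= u1={u1:.4f}"
        )

    th1 = _std_drift(spec, delta_tilde, I1)
    tht = _std_drift(spec, delta_tilde, It1)
    thf = _std_drift(spec, delta_tilde, 1.0)
    diag = {
        "residual_u1": g_u1(u1),
        "residual_d2": g_d2(d2),
        "residual_beta1": (
            float(norm.cdf(l1 - th1))
            + mvn_rect_prob([u1, -_INF], [_INF, d1], [th1, tht], corr_1t)
            - b1
        ),
        "residual_power": (
            mvn_rect_prob([u1, d1], [_INF, _INF], [th1, tht], corr_1t)
            + mvn_rect_prob([l1, d2], [u1, _INF], [th1, thf], corr_1f)
            - (1.0 - spec.beta)
        ),
    }
    return BoundarySet(
        design_kind=RR_GSD,
        l1=l1,
        u1=u1,
        d1=d1,
        d2=d2,
        alpha1=a1,
        beta1=b1,
        delta_tilde=delta_tilde,
        diagnostics=diag,
    )


_SOLVERS = {
    GSD: solve_gsd_boundaries,
    DR_GSD: solve_drgsd_boundaries,
    RR_GSD: solve_rrgsd_boundaries,
}


def solve_boundaries(spec: DesignSpec) -> BoundarySet:
    """Dispatch to the solver matching ``spec.design_kind``."""
    return _SOLVERS[spec.design_kind](spec)
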