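"""Analytic operating characteristics of a solved design.

Global characteristics at a true effect ``delta`` are evaluated under the
canonical model.  The interim outcome classification differs by design:

========  ==========================================  =================================
design    P(futility)                                 P(reject at interim)
========  ==========================================  =================================
GSD       P(Z1 <= l1)                                 P(Z1 >= u1)
DR_GSD    P(Z1 not in (l1,u1), Zt1 < d1)              P(Z1 not in (l1,u1), Zt1 >= d1)
RR_GSD    P(Z1 <= l1) + P(Z1 >= u1, Zt1 < d1)         P(Z1 >= u1, Zt1 >= d1)
========  ==========================================  =================================

For the DR design "futility" means recruitment stop followed by
non-rejection, whichever side of the continuation region was crossed.  All
three designs continue with probability ``P(l1 < Z1 < u1)``, so the three
interim outcomes always partition the sample space.

Expected sample size counts pipeline patients even when their data never
inform a decision: a trial stopped at interim has still randomized
``2 * n1_tilde`` patients, and a continued trial runs to ``2 * n_max``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .boundaries import BoundarySet, solve_boundaries
from .design import (
    DR_GSD,
    GSD,
    RR_GSD,
    DesignSpec,
    derive_sample_sizes,
    mvn_rect_prob,
)

__all__ = [
    "PerformanceSummary",
    "stopping_probabilities",
    "global_power",
    "expected_sample_size",
    "conditional_power",
    "fixed_design_sample_size",
    "evaluate_design",
    "evaluate_scenario_grid",
    "default_scenario_grid",
]

_INF = math.inf

GRID_COLUMNS = [
    "design",
    "spending_family",
    "info_interim",
    "info_pipeline",
    "delta",
    "p_futility",
    "p_reject_interim",
    "p_continue",
    "power",
    "expected_n_total",
]


@dataclass(frozen=True)
class PerformanceSummary:
    """Global operating characteristics of one design at one effect size."""

    design_kind: str
    effect: float
    p_futility: float
    p_reject_interim: float
    p_continue: float
    power: float
    expected_n_total: float

    def to_record(self) -> dict:
        return {
            "design": self.design_kind,
            "delta": self.effect,
            "p_futility": self.p_futility,
            "p_reject_interim": self.p_reject_interim,
            "p_continue": self.p_continue,
            "power": self.power,
            "expected_n_total": self.expected_n_total,
        }


def _check_kind(spec: DesignSpec, bounds: BoundarySet) -> None:
    if spec.design_kind != bounds.design_kind:
        raise ValueError(
            f"boundary set solved for {bounds.design_kind}, spec asks for "
            f"{spec.design_kind}"
        )


def _drifts(spec: DesignSpec, delta: float) -> tuple[float, float, float]:
    f = delta / spec.sigma
    return (
        f * math.sqrt(spec.info_interim * spec.n_max / 2.0),
        f * math.sqrt(spec.info_decision * spec.n_max / 2.0),
        f * math.sqrt(spec.n_max / 2.0),
    )


def _corr2(a: float, b: float) -> np.ndarray:
    r = math.sqrt(a / b)
    return np.array([[1.0, r], [r, 1.0]])


def stopping_probabilities(
    spec: DesignSpec, bounds: BoundarySet, delta: float
) -> tuple[float, float, float]:
    """(p_futility, p_reject_interim, p_continue) at true effect ``delta``."""
    _check_kind(spec, bounds)
    th1, tht, _ = _drifts(spec, delta)
    l1, u1 = bounds.l1, bounds.u1
    p_continue = float(norm.cdf(u1 - th1) - norm.cdf(l1 - th1))
    if spec.design_kind == GSD:
        p_fut = float(norm.cdf(l1 - th1))
        p_rej = float(norm.sf(u1 - th1))
        return p_fut, p_rej, p_continue
    d1 = bounds.d1
    corr = _corr2(spec.info_interim, spec.info_decision)
    mean = [th1, tht]
    hi_miss = mvn_rect_prob([u1, -_INF], [_INF, d1], mean, corr)
    hi_hit = mvn_rect_prob([u1, d1], [_INF, _INF], mean, corr)
    lo_miss = mvn_rect_prob([-_INF, -_INF], [l1, d1], mean, corr)
    lo_hit = mvn_rect_prob([-_INF, d1], [l1, _INF], mean, corr)
    if spec.design_kind == DR_GSD:
        return hi_miss + lo_miss, hi_hit + lo_hit, p_continue
    # RR_GSD: a rejection needs both Z1 >= u1 and Zt1 >= d1; a low crossing
    # is always futility.
    p_fut = float(norm.cdf(l1 - th1)) + hi_miss
    return p_fut, hi_hit, p_continue


def global_power(spec: DesignSpec, bounds: BoundarySet, delta: float) -> float:
    """P(reject at interim or final) at true effect ``delta``."""
    _, p_rej, _ = stopping_probabilities(spec, bounds, delta)
    th1, _, thf = _drifts(spec, delta)
    corr = _corr2(spec.info_interim, 1.0)
    p_final = mvn_rect_prob(
        [bounds.l1, bounds.d2], [bounds.u1, _INF], [th1, thf], corr
    )
    return p_rej + p_final


def expected_sample_size(
    spec: DesignSpec, bounds: BoundarySet, delta: float
) -> float:
    """Expected total (both-arms) sample size, pipeline patients included.

    ``E[N] = 2 * (n1_tilde + P(continue) * (n_max - n1_tilde))``: every trial
    randomizes at least the interim plus pipeline patients, and a continued
    trial recruits up to the planned maximum.
    """
    _check_kind(spec, bounds)
    plan = derive_sample_sizes(spec)
    _, _, p_cont = stopping_probabilities(spec, bounds, delta)
    return 2.0 * (plan.n1_tilde + p_cont * (spec.n_max - plan.n1_tilde))


def conditional_power(spec: DesignSpec, bounds: BoundarySet, delta: float) -> float:
    """P(final rejection | interim statistic in the continuation region)."""
    _check_kind(spec, bounds)
    th1, _, thf = _drifts(spec, delta)
    p_cont = float(norm.cdf(bounds.u1 - th1) - norm.cdf(bounds.l1 - th1))
    if p_cont <= 0.0:
        raise ValueError("conditional power undefined: P(continue) = 0")
    corr = _corr2(spec.info_interim, 1.0)
    p_joint = mvn_rect_prob(
        [bounds.l1, bounds.d2], [bounds.u1, _INF], [th1, thf], corr
    )
    return p_joint / p_cont


def fixed_design_sample_size(
    alpha: float, beta: float, delta: float, sigma: float
) -> float:
    """Per-group sample size of the single-stage two-arm z-test.

    ``n = 2 * (z_{1-alpha} + z_{1-beta})^2 * (sigma / delta)^2``; real-valued,
    round up for a whole-patient plan.
    """
    if delta == 0.0:
        raise ValueError("fixed-design sample size undefined at delta = 0")
    z = float(norm.isf(alpha) + norm.isf(beta))
    return 2.0 * z * z * (sigma / delta) ** 2


def evaluate_design(
    spec: DesignSpec, bounds: BoundarySet, delta: float
) -> PerformanceSummary:
    """All global characteristics of one design at one effect size."""
    p_fut, p_rej, p_cont = stopping_probabilities(spec, bounds, delta)
    power = global_power(spec, bounds, delta)
    en = expected_sample_size(spec, bounds, delta)
    return PerformanceSummary(
        design_kind=spec.design_kind,
        effect=delta,
        p_futility=p_fut,
        p_reject_interim=p_rej,
        p_continue=p_cont,
        power=power,
        expected_n_total=en,
    )


def default_scenario_grid() -> list[DesignSpec]:
    """The standard comparison grid of parameter constellations.

    alpha 0.025, beta 0.2, sigma 1, n_max 200 per arm; both spending
    families; interim fractions {0.3, 0.4, 0.5} crossed with pipeline
    fractions {0.1, 0.2, 0.3}; all three designs.
    """
    from .fixtures import load_scenario_grid_config

    cfg = load_scenario_grid_config()
    specs = []
    for family in cfg["spending_family"]:
        for i1 in cfg["info_interim"]:
            for idt in cfg["info_pipeline"]:
                for kind in (GSD, DR_GSD, RR_GSD):
                    specs.append(
                        DesignSpec(
                            alpha=cfg["alpha"],
                            beta=cfg["beta"],
                            sigma=cfg["sigma"],
                            n_max=cfg["n_max_per_arm"],
                            info_interim=i1,
                            info_pipeline=idt,
                            spending_family=family,
                            design_kind=kind,
                        )
                    )
    return specs


def evaluate_scenario_grid(
    scenarios: Iterable[DesignSpec] | None = None,
    deltas: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Tidy table of global characteristics over a scenario-by-effect grid.

    One row per (design, spending family, I1, I_dt, delta), in deterministic
    scenario order.  With no arguments, evaluates the packaged default grid
    on effects from -0.4 to 0.8.
    """
    if scenarios is None:
        scenarios = default_scenario_grid()
    scenarios = list(scenarios)
    if deltas is None:
        from .fixtures import load_scenario_grid_config

        cfg = load_scenario_grid_config()
        lo, hi = cfg["delta_range"]
        deltas = np.linspace(lo, hi, cfg["delta_points"])
    rows = []
    for spec in scenarios:
        try:
            bounds = solve_boundaries(spec)
        except Exception as exc:  # propagate with scenario identifier
            raise RuntimeError(
                f"scenario {spec.design_kind}/{spec.spending_family}/"
                f"I1={spec.info_interim}/Idt={spec.info_pipeline} failed: {exc}"
            ) from exc
        for delta in deltas:
            summary = evaluate_design(spec, bounds, float(delta))
            rows.append(
                {
                    "design": spec.design_kind,
                    "spending_family": spec.spending_family,
                    "info_interim": spec.info_interim,
                    "info_pipeline": spec.info_pipeline,
                    "delta": float(delta),
                    "p_futility": summary.p_futility,
                    "p_reject_interim": summary.p_reject_interim,
                    "p_continue": summary.p_continue,
                    "power": summary.power,
                    "expected_n_total": summary.expected_n_total,
                }
            )
    return pd.DataFrame(rows, columns=GRID_COLUMNS)
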