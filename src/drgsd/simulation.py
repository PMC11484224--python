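"""Monte-Carlo validation of the analytic machinery.

Two generators are provided:

* ``canonical`` mode draws the statistic vector ``(Z1, Zt1, Z12)`` directly
  from its multivariate normal law and applies the design's decision logic.
  This is the efficient protocol for estimating the sampling variability of
  empirical power and expected sample size.
* ``patient_level`` mode synthesizes normally distributed outcomes for every
  randomized patient (control mean 0, intervention mean ``delta``, common
  ``sigma``), computes the pooled-SD test statistics from the raw data, and
  applies the same decision logic.  It exercises the full pipeline and, for
  moderate interim sample sizes, agrees with the canonical mode up to the
  t-versus-z approximation.

Each run uses one seed; replications consume independent spawned substreams,
so results are bit-for-bit reproducible for a fixed configuration and seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .boundaries import BoundarySet
from .design import DR_GSD, GSD, RR_GSD, DesignSpec, canonical_model, derive_sample_sizes

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate_canonical_statistics",
    "simulate_patient_level_trial",
    "summarize_empirical",
    "apply_decision_logic",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Size, seeding and mode of a simulation experiment.

    ``n_sim`` trials are simulated per replication and the experiment is
    repeated ``n_reps`` times to obtain an empirical distribution of the
    per-replication power and expected sample size.
    """

    n_sim: int = 10_000
    n_reps: int = 100
    seed: int = 0
    mode: str = "canonical"
    apply_futility_stop: bool = True

    def __post_init__(self) -> None:
        if self.n_sim < 1 or self.n_reps < 1:
            raise ValueError("n_sim and n_reps must be >= 1")
        if self.mode not in ("canonical", "patient_level"):
            raise ValueError(f"unknown simulation mode {self.mode!r}")


@dataclass(frozen=True)
class SimulationResult:
    """Per-replication empirical operating characteristics."""

    per_rep_power: np.ndarray
    per_rep_expected_n: np.ndarray
    config: SimulationConfig
    bounds_record: dict
    delta: float
    statistics: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def summaries(self) -> dict:
        def _summ(x: np.ndarray) -> dict:
            q = np.quantile(x, [0.0, 0.25, 0.5, 0.75, 1.0]) if x.size else []
            return {
                "mean": float(np.mean(x)),
                "variance": float(np.var(x, ddof=1)) if x.size > 1 else float("nan"),
                "min": float(q[0]),
                "q25": float(q[1]),
                "median": float(q[2]),
                "q75": float(q[3]),
                "max": float(q[4]),
            }

        return {
            "power": _summ(self.per_rep_power),
            "expected_n_total": _summ(self.per_rep_expected_n),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rep": np.arange(1, len(self.per_rep_power) + 1),
                "design": self.bounds_record["design"],
                "empirical_power": self.per_rep_power,
                "empirical_expected_n": self.per_rep_expected_n,
            }
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": {
                "n_sim": self.config.n_sim,
                "n_reps": self.config.n_reps,
                "seed": self.config.seed,
                "mode": self.config.mode,
                "apply_futility_stop": self.config.apply_futility_stop,
            },
            "delta": self.delta,
            "bounds": self.bounds_record,
            "per_rep_power": self.per_rep_power.tolist(),
            "per_rep_expected_n": self.per_rep_expected_n.tolist(),
            "summaries": self.summaries,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def apply_decision_logic(
    design_kind: str,
    bounds: BoundarySet,
    z1: np.ndarray,
    zt1: np.ndarray,
    z12: np.ndarray,
    apply_futility_stop: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """(reject, continued) for arrays of simulated statistics.

    With ``apply_futility_stop=False`` a low interim statistic never stops
    the trial (the nonbinding worst case for type-I error): the trial
    continues to the final analysis, except that a high crossing still
    triggers the design's interim efficacy assessment.
    """
    l1, u1, d2 = bounds.l1, bounds.u1, bounds.d2
    high = z1 >= u1
    low = z1 <= l1 if apply_futility_stop else np.zeros_like(high)
    continued = ~(high | low)
    if design_kind == GSD:
        reject = high | (continued & (z12 >= d2))
    elif design_kind == DR_GSD:
        reject = ((high | low) & (zt1 >= bounds.d1)) | (continued & (z12 >= d2))
    elif design_kind == RR_GSD:
        reject = (high & (zt1 >= bounds.d1)) | (continued & (z12 >= d2))
    else:
        raise ValueError(f"unknown design kind {design_kind!r}")
    return reject, continued


def _tally(
    spec: DesignSpec,
    bounds: BoundarySet,
    z1: np.ndarray,
    zt1: np.ndarray,
    z12: np.ndarray,
    config: SimulationConfig,
) -> tuple[float, float]:
    plan = derive_sample_sizes(spec)
    reject, continued = apply_decision_logic(
        spec.design_kind, bounds, z1, zt1, z12, config.apply_futility_stop
    )
    n_total = 2.0 * (plan.n1_tilde + continued * (spec.n_max - plan.n1_tilde))
    return float(np.mean(reject)), float(np.mean(n_total))


def simulate_canonical_statistics(
    spec: DesignSpec,
    bounds: BoundarySet,
    delta: float,
    config: SimulationConfig,
    keep_statistics: bool = False,
) -> SimulationResult:
    """Simulate ``(Z1, Zt1, Z12)`` from the canonical law and tally decisions."""
    if spec.design_kind != bounds.design_kind:
        raise ValueError("boundary set does not match spec.design_kind")
    model = canonical_model(spec)
    chol = np.linalg.cholesky(model.corr)
    mean = model.drift(delta)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    powers = np.empty(config.n_reps)
    exp_ns = np.empty(config.n_reps)
    kept = [] if keep_statistics else None
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        z = rng.standard_normal((config.n_sim, 3)) @ chol.T + mean
        powers[r], exp_ns[r] = _tally(spec, bounds, z[:, 0], z[:, 1], z[:, 2], config)
        if kept is not None:
            kept.append(z)
    return SimulationResult(
        per_rep_power=powers,
        per_rep_expected_n=exp_ns,
        config=config,
        bounds_record=bounds.to_record(),
        delta=delta,
        statistics=np.concatenate(kept) if kept is not None else None,
    )


def _pooled_z(
    x_int: np.ndarray, x_ctl: np.ndarray
) -> np.ndarray:
    """Pooled-SD two-sample statistic, vectorized over trials (axis 0)."""
    n = x_int.shape[1]
    if n < 2:
        raise ValueError("need at least 2 patients per arm for a pooled SD")
    mi = x_int.mean(axis=1)
    mc = x_ctl.mean(axis=1)
    ss = ((x_int - mi[:, None]) ** 2).sum(axis=1) + (
        (x_ctl - mc[:, None]) ** 2
    ).sum(axis=1)
    s_pool = np.sqrt(ss / (2 * n - 2))
    return (mi - mc) / s_pool * math.sqrt(n / 2.0)


def simulate_patient_level_trial(
    spec: DesignSpec,
    bounds: BoundarySet,
    delta: float,
    config: SimulationConfig,
    keep_statistics: bool = False,
) -> SimulationResult:
    """Synthesize patient outcomes, compute pooled-SD statistics, tally.

    Per-arm analysis counts are the information fractions rounded to whole
    patients.  Statistics use pooled-SD denominators (as an analyst would)
    against the analytic normal-theory boundaries.
    """
    if spec.design_kind != bounds.design_kind:
        raise ValueError("boundary set does not match spec.design_kind")
    plan = derive_sample_sizes(spec)
    n1 = round(plan.n1)
    nt1 = round(plan.n1_tilde)
    n_max = round(plan.n_max)
    n2 = n_max - n1
    if min(n1, nt1 - n1 if nt1 > n1 else n1, n2, n_max - nt1) < 0 or n1 < 2 or n2 < 2:
        raise ValueError("degenerate rounded per-arm counts")
    w1 = math.sqrt(n1 / n_max)
    w2 = math.sqrt(n2 / n_max)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    powers = np.empty(config.n_reps)
    exp_ns = np.empty(config.n_reps)
    kept = [] if keep_statistics else None
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        x_int = rng.normal(delta, spec.sigma, size=(config.n_sim, n_max))
        x_ctl = rng.normal(0.0, spec.sigma, size=(config.n_sim, n_max))
        z1 = _pooled_z(x_int[:, :n1], x_ctl[:, :n1])
        zt1 = _pooled_z(x_int[:, :nt1], x_ctl[:, :nt1])
        z2 = _pooled_z(x_int[:, n1:], x_ctl[:, n1:])
        z12 = w1 * z1 + w2 * z2  # w1^2 + w2^2 == 1
        powers[r], exp_ns[r] = _tally(spec, bounds, z1, zt1, z12, config)
        if kept is not None:
            kept.append(np.column_stack([z1, zt1, z12]))
    return SimulationResult(
        per_rep_power=powers,
        per_rep_expected_n=exp_ns,
        config=config,
        bounds_record=bounds.to_record(),
        delta=delta,
        statistics=np.concatenate(kept) if kept is not None else None,
    )


def summarize_empirical(result: SimulationResult) -> pd.DataFrame:
    """Mean/variance/quartile summary of the empirical distributions."""
    if result.per_rep_power.size == 0:
        raise ValueError("empty simulation result")
    s = result.summaries
    rows = []
    for metric in ("power", "expected_n_total"):
        rows.append({"metric": metric, "design": result.bounds_record["design"], **s[metric]})
    return pd.DataFrame(rows)
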