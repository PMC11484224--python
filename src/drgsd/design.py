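"""Design parameterization and the canonical trivariate normal model.

A two-stage, two-arm group-sequential trial with a normally distributed
endpoint is described by a :class:`DesignSpec`.  At the interim analysis
``n1 = I1 * n_max`` patients per arm have observed outcomes, while a further
``n_dt = I_dt * n_max`` patients per arm are already recruited but still in
the pipeline (their outcomes arrive with a delay).  Three standardized test
statistics drive all decisions:

* ``Z1``    — interim statistic on the first ``n1`` patients per arm,
* ``Zt1``   — decision statistic on ``n1 + n_dt`` patients per arm, used once
  recruitment has been stopped and the pipeline has emptied,
* ``Z12``   — inverse-normal combination of the stage-1 and stage-2
  statistics, used at the final analysis of a continued trial.

Under the usual sequential-sampling assumptions the vector
``(Z1, Zt1, Z12)`` is multivariate normal with unit variances, correlations
``corr(Za, Zb) = sqrt(Ia / Ib)`` for information fractions ``Ia <= Ib``, and
mean ``(delta / sigma) * sqrt(I_k * n_max / 2)`` at effect ``delta``.  That
canonical model is materialized by :func:`canonical_model`, and every
probability statement in the package is evaluated through
:func:`mvn_rect_prob`, a deterministic rectangle-probability routine for
dimensions one to three.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import ndtr

__all__ = [
    "GSD",
    "DR_GSD",
    "RR_GSD",
    "DESIGN_KINDS",
    "SPENDING_FAMILIES",
    "InvalidDesignError",
    "DesignSpec",
    "SampleSizePlan",
    "CanonicalModel",
    "derive_sample_sizes",
    "canonical_model",
    "correlation_matrix",
    "mvn_rect_prob",
]

# Design-kind and spending-family identifiers used throughout the package.
GSD = "GSD"
DR_GSD = "DR_GSD"
RR_GSD = "RR_GSD"
DESIGN_KINDS = (GSD, DR_GSD, RR_GSD)
SPENDING_FAMILIES = ("pocock_like", "obrien_fleming_like")

# Numerical policy (shared by all modules): rectangle probabilities are
# accurate to well below 1e-7 absolute; root finders bracket on [-10, 10]
# (z-scale) with tolerance 1e-8.
MVN_ABS_TOL = 1e-7
Z_BRACKET = (-10.0, 10.0)
ROOT_XTOL = 1e-8
# Standard-normal mass beyond +-9 is ~1e-19; integration intervals are
# truncated there.
_TRUNC = 9.0


class InvalidDesignError(ValueError):
    """Raised when a design parameterization violates its invariants."""


# ---------------------------------------------------------------------------
# Design specification
# ---------------------------------------------------------------------------

_CONFIG_KEYS = (
    "alpha",
    "beta",
    "sigma",
    "n_max_per_arm",
    "info_interim",
    "info_pipeline",
    "spending_family",
    "design_kind",
)


@dataclass(frozen=True)
class DesignSpec:
    """Immutable description of a two-stage delayed-response design problem.

    Parameters
    ----------
    alpha
        One-sided type-I error level.
    beta
        Type-II error level (target power is ``1 - beta``).
    sigma
        Common outcome standard deviation (outcome units).
    n_max
        Maximum per-arm sample size.
    info_interim
        Interim information fraction ``I1`` (fraction of ``n_max`` with
        observed outcomes per arm at the interim analysis).
    info_pipeline
        Pipeline information fraction ``I_dt`` (fraction of ``n_max``
        recruited but unobserved at interim).
    spending_family
        ``"pocock_like"`` or ``"obrien_fleming_like"``; used for both the
        alpha- and the beta-spending function.
    design_kind
        ``"GSD"`` (standard error-spending design), ``"DR_GSD"``
        (delayed-response design with nonbinding recruitment-stopping
        boundary) or ``"RR_GSD"`` (repeated-rejection variant).
    """

    alpha: float
    beta: float
    sigma: float
    n_max: float
    info_interim: float
    info_pipeline: float = 0.0
    spending_family: str = "pocock_like"
    design_kind: str = GSD

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InvalidDesignError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.beta < 1.0:
            raise InvalidDesignError(f"beta must be in (0, 1), got {self.beta}")
        if self.sigma <= 0.0:
            raise InvalidDesignError(f"sigma must be positive, got {self.sigma}")
        if self.n_max <= 0.0:
            raise InvalidDesignError(f"n_max must be positive, got {self.n_max}")
        if not 0.0 < self.info_interim < 1.0:
            raise InvalidDesignError(
                f"info_interim must be in (0, 1), got {self.info_interim}"
            )
        if self.info_pipeline < 0.0:
            raise InvalidDesignError(
                f"info_pipeline must be nonnegative, got {self.info_pipeline}"
            )
        if self.info_interim + self.info_pipeline >= 1.0:
            raise InvalidDesignError(
                "info_interim + info_pipeline must be < 1 "
                f"(got {self.info_interim} + {self.info_pipeline}); designs that "
                "wait for the full planned sample are not supported"
            )
        if self.spending_family not in SPENDING_FAMILIES:
            raise InvalidDesignError(
                f"spending_family must be one of {SPENDING_FAMILIES}, "
                f"got {self.spending_family!r}"
            )
        if self.design_kind not in DESIGN_KINDS:
            raise InvalidDesignError(
                f"design_kind must be one of {DESIGN_KINDS}, got {self.design_kind!r}"
            )
        if self.design_kind in (DR_GSD, RR_GSD) and self.info_pipeline <= 0.0:
            raise InvalidDesignError(
                f"{self.design_kind} requires info_pipeline > 0"
            )

    @property
    def info_decision(self) -> float:
        """Information fraction at the recruitment-stop decision analysis."""
        return self.info_interim + self.info_pipeline

    def with_kind(self, design_kind: str) -> "DesignSpec":
        """Copy of this spec with a different design kind."""
        return replace(self, design_kind=design_kind)

    # -- flat config serialization -----------------------------------------
    def to_config(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "sigma": self.sigma,
            "n_max_per_arm": self.n_max,
            "info_interim": self.info_interim,
            "info_pipeline": self.info_pipeline,
            "spending_family": self.spending_family,
            "design_kind": self.design_kind,
        }

    @classmethod
    def from_config(cls, config: dict) -> "DesignSpec":
        unknown = set(config) - set(_CONFIG_KEYS)
        if unknown:
            raise InvalidDesignError(
                f"unknown config keys: {sorted(unknown)}; expected {_CONFIG_KEYS}"
            )
        missing = {"alpha", "beta", "sigma", "n_max_per_arm", "info_interim"} - set(
            config
        )
        if missing:
            raise InvalidDesignError(f"missing config keys: {sorted(missing)}")
        return cls(
            alpha=float(config["alpha"]),
            beta=float(config["beta"]),
            sigma=float(config["sigma"]),
            n_max=float(config["n_max_per_arm"]),
            info_interim=float(config["info_interim"]),
            info_pipeline=float(config.get("info_pipeline", 0.0)),
            spending_family=str(config.get("spending_family", "pocock_like")),
            design_kind=str(config.get("design_kind", GSD)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_config(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DesignSpec":
        return cls.from_config(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Sample sizes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSizePlan:
    """Per-arm sample sizes implied by the information fractions.

    All counts are real-valued; :meth:`rounded` provides the whole-patient
    reporting view.  ``n1 + n_pipeline + n2_continue == n_max`` holds exactly.
    """

    n1: float
    n_pipeline: float
    n1_tilde: float
    n2_continue: float
    n_max: float

    @property
    def totals(self) -> dict:
        """Both-arms totals for each per-arm count."""
        return {
            "interim": 2.0 * self.n1,
            "pipeline": 2.0 * self.n_pipeline,
            "decision": 2.0 * self.n1_tilde,
            "continuation": 2.0 * self.n2_continue,
            "maximum": 2.0 * self.n_max,
        }

    def rounded(self) -> dict:
        """Whole-patient per-arm view (nearest integer)."""
        return {
            "n1": round(self.n1),
            "n_pipeline": round(self.n_pipeline),
            "n1_tilde": round(self.n1_tilde),
            "n2_continue": round(self.n2_continue),
            "n_max": round(self.n_max),
        }


def derive_sample_sizes(spec: DesignSpec) -> SampleSizePlan:
    """Translate information fractions into per-arm patient counts.

    Counts are kept real-valued so that boundary computations are exact in
    the stated fractions; rounding is confined to reporting.
    """
    n1 = spec.info_interim * spec.n_max
    n_dt = spec.info_pipeline * spec.n_max
    n1_tilde = n1 + n_dt
    n2 = spec.n_max - n1_tilde
    if n2 <= 0.0:
        raise InvalidDesignError("no patients left for the continuation stage")
    return SampleSizePlan(
        n1=n1, n_pipeline=n_dt, n1_tilde=n1_tilde, n2_continue=n2, n_max=spec.n_max
    )


# ---------------------------------------------------------------------------
# Canonical model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CanonicalModel:
    """Canonical multivariate normal law of ``(Z1, Zt1, Z12)``.

    ``info_levels`` is the ordered triple ``(I1, I1 + I_dt, 1)``; ``corr`` has
    entries ``sqrt(Ia / Ib)`` for ``Ia <= Ib``; ``drift(delta)`` maps an
    effect (outcome units) to the mean vector
    ``(delta / sigma) * sqrt(I_k * n_max / 2)``.
    """

    info_levels: tuple
    corr: np.ndarray
    drift: Callable[[float], np.ndarray] = field(repr=False)
    weights: tuple = ()

    def drift_at(self, delta: float, level: int) -> float:
        """Mean of the statistic at index ``level`` (0-based) at ``delta``."""
        return float(self.drift(delta)[level])


def canonical_model(spec: DesignSpec) -> CanonicalModel:
    """Build the canonical model of ``(Z1, Zt1, Z12)`` for a design spec.

    The inverse-normal weights ``w1 = sqrt(n1 / n_max)`` and
    ``w2 = sqrt((n_max - n1) / n_max)`` make the combination statistic behave
    exactly like the full-data statistic, which is what gives the final entry
    its information level 1 and the familiar ``sqrt(I)`` correlations.
    """
    info = (spec.info_interim, spec.info_decision, 1.0)
    if info[1] >= 1.0:
        raise InvalidDesignError(
            "decision-analysis information fraction must be below 1"
        )
    levels = np.asarray(info)
    corr = np.sqrt(np.minimum.outer(levels, levels) / np.maximum.outer(levels, levels))
    sigma, n_max = spec.sigma, spec.n_max
    scale = np.sqrt(levels * n_max / 2.0)

    def drift(delta: float) -> np.ndarray:
        return (delta / sigma) * scale

    w1 = math.sqrt(spec.info_interim)
    w2 = math.sqrt(1.0 - spec.info_interim)
    return CanonicalModel(info_levels=info, corr=corr, drift=drift, weights=(w1, w2))


def correlation_matrix(spec: DesignSpec) -> np.ndarray:
    """The 3x3 canonical correlation matrix (convenience accessor)."""
    return canonical_model(spec).corr


# ---------------------------------------------------------------------------
# Rectangle probabilities
# ---------------------------------------------------------------------------

# Composite Gauss-Legendre rule: the truncated integration interval is split
# into unit-length panels with a 24-point rule each; for smooth integrands of
# the kind below this is accurate far beyond the 1e-7 policy.
_GL_NODES, _GL_WEIGHTS = leggauss(24)


def _panels(a: float, b: float) -> tuple[np.ndarray, np.ndarray]:
    """Composite Gauss-Legendre nodes/weights on [a, b]."""
    n_panels = max(1, int(math.ceil(b - a)))
    edges = np.linspace(a, b, n_panels + 1)
    half = np.diff(edges) / 2.0
    mid = (edges[:-1] + edges[1:]) / 2.0
    nodes = (mid[:, None] + half[:, None] * _GL_NODES[None, :]).ravel()
    weights = (half[:, None] * _GL_WEIGHTS[None, :]).ravel()
    return nodes, weights


def _phi(x: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)


def _rect1(a: float, b: float) -> float:
    return float(ndtr(b) - ndtr(a))


def _cond_interval(x: np.ndarray, rho: float, a: float, b: float) -> np.ndarray:
    """P(a < Y < b | X = x) for standard bivariate normal with corr rho."""
    s2 = 1.0 - rho * rho
    if s2 < 1e-14:
        # Degenerate: Y == rho * X almost surely.
        y = rho * x
        return ((y > a) & (y < b)).astype(float)
    s = math.sqrt(s2)
    return ndtr((b - rho * x) / s) - ndtr((a - rho * x) / s)


def _rect2(lower: np.ndarray, upper: np.ndarray, rho: float) -> float:
    a1 = max(lower[0], -_TRUNC)
    b1 = min(upper[0], _TRUNC)
    if b1 <= a1:
        return 0.0
    x, w = _panels(a1, b1)
    return float(np.sum(w * _phi(x) * _cond_interval(x, rho, lower[1], upper[1])))


def _rect3(lower: np.ndarray, upper: np.ndarray, corr: np.ndarray) -> float:
    a1 = max(lower[0], -_TRUNC)
    b1 = min(upper[0], _TRUNC)
    if b1 <= a1:
        return 0.0
    r12, r13, r23 = corr[0, 1], corr[0, 2], corr[1, 2]
    s2_2, s2_3 = 1.0 - r12 * r12, 1.0 - r13 * r13
    if s2_2 < 1e-14 or s2_3 < 1e-14:
        # A perfectly correlated pair collapses to a 2-D rectangle.
        if s2_2 < 1e-14:  # X2 == r12 * X1
            sgn = math.copysign(1.0, r12)
            lo = max(lower[0], min(sgn * lower[1], sgn * upper[1]))
            hi = min(upper[0], max(sgn * lower[1], sgn * upper[1]))
            return _rect2(
                np.array([lo, lower[2]]), np.array([hi, upper[2]]), r13
            )
        sgn = math.copysign(1.0, r13)
        lo = max(lower[0], min(sgn * lower[2], sgn * upper[2]))
        hi = min(upper[0], max(sgn * lower[2], sgn * upper[2]))
        return _rect2(np.array([lo, lower[1]]), np.array([hi, upper[1]]), r12)
    # Condition on X1 = x: (X2, X3) | x is bivariate normal with means
    # (r12 x, r13 x), variances s2_2, s2_3 and residual correlation rho_c.
    rho_c = (r23 - r12 * r13) / math.sqrt(s2_2 * s2_3)
    rho_c = min(1.0, max(-1.0, rho_c))
    s2, s3 = math.sqrt(s2_2), math.sqrt(s2_3)
    x, w = _panels(a1, b1)
    lo2 = (lower[1] - r12 * x) / s2
    hi2 = (upper[1] - r12 * x) / s2
    lo3 = (lower[2] - r13 * x) / s3
    hi3 = (upper[2] - r13 * x) / s3
    # Inner standardized bivariate rectangle, one quadrature per outer node,
    # vectorized over outer nodes.
    inner = _rect2_vec(lo2, hi2, lo3, hi3, rho_c)
    return float(np.sum(w * _phi(x) * inner))


def _rect2_vec(
    a1: np.ndarray, b1: np.ndarray, a2: np.ndarray, b2: np.ndarray, rho: float
) -> np.ndarray:
    """Vectorized standard-bivariate rectangle probabilities.

    Each entry i is P(a1[i] < X < b1[i], a2[i] < Y < b2[i]).  A shared
    node grid per entry keeps the computation a single array expression.
    """
    lo = np.maximum(a1, -_TRUNC)
    hi = np.minimum(b1, _TRUNC)
    width = np.clip(hi - lo, 0.0, None)
    # 96 nodes on each (possibly different) interval; integrand is smooth.
    n_nodes = 96
    u, wu = leggauss(n_nodes)
    x = lo[:, None] + (u[None, :] + 1.0) / 2.0 * width[:, None]
    wx = width[:, None] / 2.0 * wu[None, :]
    s2 = 1.0 - rho * rho
    if s2 < 1e-14:
        y = rho * x
        inner = (y > a2[:, None]) & (y < b2[:, None])
        vals = np.sum(wx * _phi(x) * inner, axis=1)
    else:
        s = math.sqrt(s2)
        inner = ndtr((b2[:, None] - rho * x) / s) - ndtr((a2[:, None] - rho * x) / s)
        vals = np.sum(wx * _phi(x) * inner, axis=1)
    return np.where(width > 0.0, vals, 0.0)


def mvn_rect_prob(
    lower: Sequence[float],
    upper: Sequence[float],
    mean: Sequence[float] | None = None,
    corr: np.ndarray | float | None = None,
) -> float:
    """P(lower < X < upper) for a multivariate normal X, dimensions 1-3.

    Deterministic composite Gauss-Legendre reduction (no Monte-Carlo
    component), absolute error well below 1e-7 for dimension <= 3.  Infinite
    bounds are allowed; ``corr`` must be a correlation matrix (unit
    variances).
    """
    lower = np.asarray(lower, dtype=float).ravel()
    upper = np.asarray(upper, dtype=float).ravel()
    d = lower.size
    if upper.size != d or not 1 <= d <= 3:
        raise ValueError("lower/upper must be conformable vectors of length 1-3")
    if np.any(upper <= lower):
        raise ValueError("upper must exceed lower elementwise")
    if mean is None:
        mean = np.zeros(d)
    mean = np.asarray(mean, dtype=float).ravel()
    if mean.size != d:
        raise ValueError("mean length does not match bounds")
    lo = lower - mean
    hi = upper - mean
    if d == 1:
        return _rect1(lo[0], hi[0])
    if corr is None:
        corr_mat = np.eye(d)
    else:
        corr_mat = np.atleast_2d(np.asarray(corr, dtype=float))
    if corr_mat.shape != (d, d):
        raise ValueError(f"corr must be {d}x{d}")
    if not np.allclose(corr_mat, corr_mat.T, atol=1e-12) or not np.allclose(
        np.diag(corr_mat), 1.0, atol=1e-12
    ):
        raise ValueError("corr must be symmetric with unit diagonal")
    eigmin = float(np.linalg.eigvalsh(corr_mat)[0])
    if eigmin < -1e-10:
        raise ValueError("corr is not positive semi-definite")
    if d == 2:
        return min(1.0, max(0.0, _rect2(lo, hi, float(corr_mat[0, 1]))))
    return min(1.0, max(0.0, _rect3(lo, hi, corr_mat)))
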