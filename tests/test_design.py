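"""Design parameterization, sample sizes and the canonical normal model."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import multivariate_normal, norm

from drgsd import (
    DR_GSD,
    DesignSpec,
    InvalidDesignError,
    canonical_model,
    correlation_matrix,
    derive_sample_sizes,
    mvn_rect_prob,
)

from conftest import example_spec


# ---------------------------------------------------------------------------
# DesignSpec validation and serialization
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "overrides",
    [
        {"alpha": 0.0},
        {"alpha": 1.0},
        {"beta": -0.1},
        {"sigma": 0.0},
        {"n_max": 0.0},
        {"info_interim": 0.0},
        {"info_interim": 1.0},
        {"info_pipeline": -0.2},
        {"info_interim": 0.7, "info_pipeline": 0.3},  # pipeline reaches maximum
        {"spending_family": "linear"},
        {"design_kind": "K_STAGE"},
    ],
)
def test_invalid_specs_rejected(overrides):
    base = dict(
        alpha=0.025, beta=0.2, sigma=1.0, n_max=200.0, info_interim=0.5,
        info_pipeline=0.2,
    )
    base.update(overrides)
    with pytest.raises((InvalidDesignError, ValueError)):
        DesignSpec(**base)


def test_delayed_designs_need_pipeline():
    with pytest.raises(InvalidDesignError):
        DesignSpec(
            alpha=0.025, beta=0.2, sigma=1.0, n_max=200.0, info_interim=0.5,
            info_pipeline=0.0, design_kind=DR_GSD,
        )


def test_config_round_trip(tmp_path):
    spec = example_spec()
    path = tmp_path / "spec.json"
    spec.to_json(path)
    assert DesignSpec.from_json(path) == spec
    with pytest.raises(InvalidDesignError, match="unknown config keys"):
        DesignSpec.from_config(dict(spec.to_config(), bogus=1))


# ---------------------------------------------------------------------------
# Sample sizes
# ---------------------------------------------------------------------------


def test_example_sample_sizes():
    """Worked example: 200/207/~407 total patients at interim/pipeline/decision."""
    plan = derive_sample_sizes(example_spec())
    totals = plan.totals
    assert totals["interim"] == pytest.approx(200.1)
    assert totals["pipeline"] == pytest.approx(207.0)
    assert totals["decision"] == pytest.approx(407.1)
    rounded = plan.rounded()
    assert rounded["n1_tilde"] == 204  # 408 over both arms


@pytest.mark.parametrize(
    "i1,idt,n_max,expected",
    [
        (0.5, 0.0, 200.0, dict(n1=100.0, n_pipeline=0.0, n1_tilde=100.0, n2=100.0)),
        (0.3, 0.3, 200.0, dict(n1=60.0, n_pipeline=60.0, n1_tilde=120.0, n2=80.0)),
    ],
)
def test_sample_size_arithmetic(i1, idt, n_max, expected):
    spec = DesignSpec(
        alpha=0.025, beta=0.2, sigma=1.0, n_max=n_max, info_interim=i1,
        info_pipeline=idt,
    )
    plan = derive_sample_sizes(spec)
    assert plan.n1 == pytest.approx(expected["n1"])
    assert plan.n_pipeline == pytest.approx(expected["n_pipeline"])
    assert plan.n1_tilde == pytest.approx(expected["n1_tilde"])
    assert plan.n2_continue == pytest.approx(expected["n2"])
    assert plan.n1 + plan.n_pipeline + plan.n2_continue == pytest.approx(n_max)


# ---------------------------------------------------------------------------
# Canonical model
# ---------------------------------------------------------------------------


def test_example_correlations():
    corr = correlation_matrix(example_spec())
    assert corr[0, 1] == pytest.approx(math.sqrt(0.29 / 0.59), abs=1e-12)
    assert corr[0, 2] == pytest.approx(math.sqrt(0.29), abs=1e-12)
    assert corr[1, 2] == pytest.approx(math.sqrt(0.59), abs=1e-12)
    assert np.allclose(corr, corr.T)
    assert np.allclose(np.diag(corr), 1.0)
    assert np.linalg.eigvalsh(corr)[0] > 0.0


@given(
    i1=st.floats(0.05, 0.9),
    idt_frac=st.floats(0.0, 0.95),
)
def test_correlation_product_rule(i1, idt_frac):
    """Markov structure: corr(Z1,Z12) == corr(Z1,Zt1) * corr(Zt1,Z12)."""
    idt = idt_frac * (1.0 - i1) * 0.99
    spec = DesignSpec(
        alpha=0.025, beta=0.2, sigma=1.0, n_max=100.0, info_interim=i1,
        info_pipeline=idt,
    )
    corr = correlation_matrix(spec)
    assert corr[0, 2] == pytest.approx(corr[0, 1] * corr[1, 2], abs=1e-12)
    eig = np.linalg.eigvalsh(corr)
    assert eig[0] >= -1e-12


def test_drift_and_weights():
    spec = example_spec()
    model = canonical_model(spec)
    delta = 1.6
    # Final-analysis drift equals (delta/sigma) * sqrt(n_max/2).
    assert model.drift_at(delta, 2) == pytest.approx(
        (delta / spec.sigma) * math.sqrt(spec.n_max / 2.0), abs=1e-12
    )
    assert np.allclose(model.drift(0.0), 0.0)
    assert np.allclose(model.drift(2 * delta), 2 * np.asarray(model.drift(delta)))
    w1, w2 = model.weights
    assert w1**2 + w2**2 == pytest.approx(1.0, abs=1e-12)


def test_no_pipeline_means_identical_statistics():
    spec = DesignSpec(
        alpha=0.025, beta=0.2, sigma=1.0, n_max=200.0, info_interim=0.5,
        info_pipeline=0.0,
    )
    corr = correlation_matrix(spec)
    assert corr[0, 1] == pytest.approx(1.0, abs=1e-14)
    assert corr[0, 2] == pytest.approx(math.sqrt(0.5), abs=1e-14)


# ---------------------------------------------------------------------------
# Rectangle probabilities
# ---------------------------------------------------------------------------


def test_rect_prob_1d_quantile():
    assert mvn_rect_prob([-np.inf], [1.96], [0.0]) == pytest.approx(
        norm.cdf(1.96), abs=1e-12
    )


def test_rect_prob_independence_factorizes():
    p1 = norm.cdf(1.0) - norm.cdf(-1.0)
    p2 = norm.cdf(0.5) - norm.cdf(-2.0)
    got = mvn_rect_prob([-1.0, -2.0], [1.0, 0.5], [0.0, 0.0], np.eye(2))
    assert got == pytest.approx(p1 * p2, abs=1e-10)


def test_rect_prob_3d_marginal_reduction():
    """Bounds on one coordinate only: trivariate reduces to the 1-D marginal."""
    corr = correlation_matrix(example_spec())
    got = mvn_rect_prob(
        [0.259, -np.inf, -np.inf], [2.322, np.inf, np.inf], np.zeros(3), corr
    )
    assert got == pytest.approx(norm.cdf(2.322) - norm.cdf(0.259), abs=1e-9)


def test_rect_prob_3d_against_monte_carlo():
    """Independent brute-force oracle: 2e6 draws, agreement within 3 SE."""
    corr = correlation_matrix(example_spec())
    lower = np.array([0.259, -0.5, -np.inf])
    upper = np.array([2.322, 2.0, 1.0])
    mean = np.array([0.3, 0.4, 0.5])
    rng = np.random.default_rng(20240901)
    n = 2_000_000
    z = rng.standard_normal((n, 3)) @ np.linalg.cholesky(corr).T + mean
    inside = np.all((z > lower) & (z < upper), axis=1)
    p_hat = inside.mean()
    se = math.sqrt(p_hat * (1 - p_hat) / n)
    assert mvn_rect_prob(lower, upper, mean, corr) == pytest.approx(
        p_hat, abs=3 * se
    )


def test_rect_prob_against_scipy():
    """scipy's (randomized) integrator as an independent numerical oracle."""
    rng = np.random.default_rng(11)
    for _ in range(4):
        a = rng.normal(size=(3, 3))
        cov = a @ a.T
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        mean = rng.normal(size=3)
        lower = mean + rng.uniform(-3, -0.5, 3)
        upper = lower + rng.uniform(0.5, 4, 3)
        ref = multivariate_normal.cdf(
            upper, mean, corr, lower_limit=lower, maxpts=1_000_000, abseps=1e-8,
            releps=0,
        )
        assert mvn_rect_prob(lower, upper, mean, corr) == pytest.approx(
            float(ref), abs=1e-6
        )


def test_rect_prob_input_validation():
    with pytest.raises(ValueError, match="upper must exceed lower"):
        mvn_rect_prob([1.0], [0.5])
    with pytest.raises(ValueError, match="positive semi-definite"):
        mvn_rect_prob(
            [-1, -1, -1], [1, 1, 1], np.zeros(3),
            np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]]),
        )
    with pytest.raises(ValueError):
        mvn_rect_prob([-1, -1, -1, -1], [1, 1, 1, 1])
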