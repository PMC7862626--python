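"""PCA mediator blocks, natural effect models, PM, bootstrap, sequential steps."""

import numpy as np
import pandas as pd
import pytest

import medchain as mc
from medchain.mediation import bootstrap_ci, pct_change, sequential_mediation


def linear_gaussian(n=5000, a=0.5, b=0.3, c=0.1, seed=0):
    """X -> M (slope a), M -> Y (slope b), X -> Y direct (slope c)."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 3, n).astype(float)
    M = a * x[:, None] + rng.standard_normal((n, 1))
    y = c * x + b * M[:, 0] + 0.5 * rng.standard_normal(n)
    return x, M, y


# ---------------------------------------------------------------------------
# PCA summaries
# ---------------------------------------------------------------------------

def test_single_gene_pca():
    expr = pd.DataFrame(np.random.default_rng(0).standard_normal((1, 100)), index=["G1"])
    pcs = mc.pca_summarize(expr, ["G1"], 0.5)
    assert pcs.k == 1 and np.isclose(pcs.cumvar, 1.0)


def test_isotropic_genes_need_half_the_components():
    rng = np.random.default_rng(1)
    expr = pd.DataFrame(rng.standard_normal((10, 20000)),
                        index=[f"G{i}" for i in range(10)])
    pcs = mc.pca_summarize(expr, list(expr.index), 0.5)
    assert pcs.k == 5
    assert abs(pcs.cumvar - 0.5) < 0.03


def test_variance_fractions_match_correlation_eigenvalues():
    rng = np.random.default_rng(2)
    expr = pd.DataFrame(rng.standard_normal((50, 500)), index=[f"G{i}" for i in range(50)])
    pcs = mc.pca_summarize(expr, list(expr.index), 0.5)
    Z = ((expr.T - expr.mean(axis=1)) / expr.std(axis=1, ddof=1)).to_numpy()
    eig = np.sort(np.linalg.eigvalsh(np.corrcoef(expr.to_numpy())))[::-1]
    np.testing.assert_allclose(pcs.explained_ratio, eig / eig.sum(), atol=1e-8)


def test_component_count_monotone_in_target_variance():
    rng = np.random.default_rng(3)
    base = rng.standard_normal((5, 300))
    expr = pd.DataFrame(np.vstack([base + 0.3 * rng.standard_normal((5, 300)) for _ in range(4)]),
                        index=[f"G{i}" for i in range(20)])
    ks = [mc.pca_summarize(expr, list(expr.index), tv).k for tv in (0.30, 0.45, 0.60)]
    assert ks == sorted(ks)


def test_zero_variance_gene_dropped_with_warning():
    expr = pd.DataFrame(np.vstack([np.zeros(50), np.random.default_rng(4).standard_normal(50)]),
                        index=["flat", "ok"])
    with pytest.warns(UserWarning):
        pcs = mc.pca_summarize(expr, ["flat", "ok"], 0.5)
    assert list(pcs.loadings.index) == ["ok"]


def test_scores_uncorrelated():
    rng = np.random.default_rng(5)
    expr = pd.DataFrame(rng.standard_normal((8, 400)), index=[f"G{i}" for i in range(8)])
    pcs = mc.pca_summarize(expr, list(expr.index), 0.9)
    if pcs.k > 1:
        corr = np.corrcoef(pcs.scores.T)
        off = corr[~np.eye(pcs.k, dtype=bool)]
        assert np.abs(off).max() < 1e-10


# ---------------------------------------------------------------------------
# natural effect models
# ---------------------------------------------------------------------------

def test_null_mediator_gives_null_indirect_effect():
    rng = np.random.default_rng(6)
    x = rng.integers(0, 3, 5000).astype(float)
    M = rng.standard_normal((5000, 3))  # independent of x
    y = 0.1 * x + 0.5 * rng.standard_normal(5000)
    ne = mc.fit_natural_effects(y, x, M)
    se_rough = 0.5 / np.sqrt(5000 * x.var())
    assert abs(ne.beta_ie) < 2 * se_rough


def test_product_of_coefficients_recovered():
    a, b, c = 0.5, 0.3, 0.1
    x, M, y = linear_gaussian(a=a, b=b, c=c, seed=7)
    ne = mc.fit_natural_effects(y, x, M)
    n = len(x)
    se_de = 0.5 / np.sqrt(n * x.var())
    se_ie = np.sqrt((a * 0.1) ** 2 + b**2 / (n * x.var())) + 0.01
    assert abs(ne.beta_de - c) < 3 * se_de
    assert abs(ne.beta_ie - a * b) < 3 * se_ie


def test_total_effect_matches_direct_regression():
    x, M, y = linear_gaussian(seed=8)
    C = np.random.default_rng(8).standard_normal(len(x))
    ne = mc.fit_natural_effects(y, x, M, C)
    X = np.column_stack([np.ones(len(x)), x, C])
    slope = np.linalg.lstsq(X, y, rcond=None)[0][1]
    assert abs(pct_change(ne.beta_de + ne.beta_ie) - pct_change(slope)) < 1e-6


def test_pm_identity_between_scales():
    x, M, y = linear_gaussian(seed=9)
    ne = mc.fit_natural_effects(y, x, M)
    pm_from_pct = mc.proportion_mediated(ne.te_pct, ne.ie_pct)
    assert abs(pm_from_pct - ne.beta_ie / (ne.beta_de + ne.beta_ie)) < 1e-10


def test_binary_mode_same_sign_indirect_effect():
    x, M, y = linear_gaussian(n=8000, seed=10)
    y_bin = (y > np.median(y)).astype(float)
    ne_cont = mc.fit_natural_effects(y, x, M)
    ne_bin = mc.fit_natural_effects(y_bin, x, M, binary=True)
    assert ne_bin.scale == "logit"
    assert np.sign(ne_bin.beta_ie) == np.sign(ne_cont.beta_ie)


def test_non_finite_outcome_rejected():
    x, M, y = linear_gaussian(n=100, seed=11)
    y[0] = np.nan
    with pytest.raises(ValueError):
        mc.fit_natural_effects(y, x, M)


def test_collinear_mediators_rejected():
    x, M, y = linear_gaussian(n=100, seed=12)
    M2 = np.hstack([M, M])
    with pytest.raises(ValueError, match="collinear"):
        mc.fit_natural_effects(y, x, M2)


# ---------------------------------------------------------------------------
# proportion mediated
# ---------------------------------------------------------------------------

def test_pm_equal_effects_is_one():
    assert np.isclose(mc.proportion_mediated(15.0, 15.0), 1.0)


def test_pm_zero_total_effect_undefined():
    with pytest.raises(ValueError):
        mc.proportion_mediated(0.0, 5.0)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_deterministic_and_tight_for_degenerate_data():
    x = np.tile([0.0, 1.0, 2.0], 100)
    y = 0.1 * x  # zero noise
    M = np.zeros((300, 1))

    def fn(idx, rng):
        ne = mc.fit_natural_effects(y[idx], x[idx], M[idx] + 1e-8 * rng.standard_normal((len(idx), 1)))
        return {"te": ne.te_pct}

    ci1 = bootstrap_ci(fn, n=300, B=200, seed=5)
    ci2 = bootstrap_ci(fn, n=300, B=200, seed=5)
    assert ci1 == ci2
    lo, hi = ci1["te"]
    assert hi - lo < 1e-4


def test_bootstrap_minimum_draws():
    with pytest.raises(ValueError):
        bootstrap_ci(lambda idx, rng: {"a": 1.0}, n=10, B=50)


def test_bootstrap_failure_rate_guard():
    def fn(idx, rng):
        raise ValueError("always fails")

    with pytest.raises(RuntimeError):
        bootstrap_ci(fn, n=10, B=100, seed=1)


# ---------------------------------------------------------------------------
# sequential mediation
# ---------------------------------------------------------------------------

def test_independent_second_block_adds_nothing():
    x, M, y = linear_gaussian(seed=13)
    M2 = np.random.default_rng(13).standard_normal((len(x), 2))
    steps = sequential_mediation(y, x, [M, M2])
    assert abs(steps["incremental_beta_ie"].iloc[1]) < 0.01


def test_two_block_increments_match_path_products():
    rng = np.random.default_rng(14)
    n = 8000
    x = rng.integers(0, 3, n).astype(float)
    a1, b1, a2, b2, c = 0.4, 0.25, 0.3, 0.2, 0.05
    M1 = a1 * x[:, None] + rng.standard_normal((n, 1))
    M2 = a2 * x[:, None] + rng.standard_normal((n, 1))
    y = c * x + b1 * M1[:, 0] + b2 * M2[:, 0] + 0.5 * rng.standard_normal(n)
    steps = sequential_mediation(y, x, [M1, M2])
    tol = 3 * 0.6 / np.sqrt(n * x.var())
    assert abs(steps["beta_ie"].iloc[0] - a1 * b1) < tol
    assert abs(steps["incremental_beta_ie"].iloc[1] - a2 * b2) < tol


def test_joint_indirect_effect_invariant_to_block_order():
    x, M, y = linear_gaussian(seed=15)
    M2 = np.random.default_rng(15).standard_normal((len(x), 2))
    fwd = sequential_mediation(y, x, [M, M2])
    rev = sequential_mediation(y, x, [M2, M])
    assert abs(fwd["beta_ie"].iloc[-1] - rev["beta_ie"].iloc[-1]) < 1e-10


def test_overlapping_blocks_rejected():
    x, M, y = linear_gaussian(n=100, seed=16)
    with pytest.raises(ValueError, match="disjoint"):
        sequential_mediation(y, x, [M, M])


# ---------------------------------------------------------------------------
# per-gene associations
# ---------------------------------------------------------------------------

def test_per_gene_type_one_error_controlled():
    rng = np.random.default_rng(17)
    expr = pd.DataFrame(rng.standard_normal((1000, 400)),
                        index=[f"G{i}" for i in range(1000)])
    x = rng.permutation(np.repeat([0.0, 1.0, 2.0], 134))[:400]
    res = mc.per_gene_association(expr, x)
    assert 0.03 <= res["significant"].mean() <= 0.07


def test_strong_deterministic_association_detected():
    rng = np.random.default_rng(18)
    x = rng.integers(0, 3, 200).astype(float)
    expr = pd.DataFrame([2.0 * x + 1e-6 * rng.standard_normal(200)], index=["G"])
    res = mc.per_gene_association(expr, x)
    assert np.isclose(res["slope"].iloc[0], 2.0, atol=1e-4)
    assert res["p"].iloc[0] < 1e-12
    assert res["direction"].iloc[0] == "increased"


def test_constant_transcript_skipped():
    expr = pd.DataFrame([np.ones(50)], index=["flat"])
    x = np.tile([0.0, 1.0], 25)
    with pytest.warns(UserWarning):
        res = mc.per_gene_association(expr, x)
    assert res.empty
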