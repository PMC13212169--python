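import logging
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats as sps
from scipy.special import gammaln

import playvis as pv
from playvis import nb_glmm
from playvis.nb_glmm import (
    M0,
    M1,
    M2,
    M3,
    ModelFit,
    fit_model,
    compare_models,
    group_effects,
    predicted_counts,
    check_overdispersion,
    marginal_loglik,
)
from playvis.synthetic_data import GeneratorConfig, GroupParams, generate_cell_counts, simulate_scene


@pytest.fixture(scope="module")
def small_scene():
    cfg = GeneratorConfig(
        template="random-obstacles", boundary_size=(11.7, 11.7), n_random_obstacles=4, n_random_zones=4
    )
    return cfg, simulate_scene(cfg, seed=3)


@pytest.fixture(scope="module")
def small_counts(small_scene):
    cfg, sc = small_scene
    counts, truth = generate_cell_counts(sc.layout, sc.lattice, sc.vmd, cfg, seed=5)
    return counts, truth


@pytest.fixture(scope="module")
def m3_fit(small_counts):
    counts, _ = small_counts
    return fit_model(M3, counts)


# ---------------------------------------------------------------------------
# Likelihood correctness
# ---------------------------------------------------------------------------

def _nb2_logpmf(y, mu, theta):
    return (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


def test_marginal_loglik_matches_numeric_integration():
    """AGQ marginal log-likelihood equals brute-force numeric integration
    of the NB2 x Normal integrand, zone by zone."""
    rng = np.random.default_rng(4)
    n = 40
    data = pd.DataFrame(
        {
            "count": rng.poisson(3.0, n),
            "vmd": rng.uniform(1, 3, n),
            "group": "all",
            "zone": np.repeat(["za", "zb"], n // 2),
        }
    )
    beta = np.array([0.8, 0.1])
    theta, sigma = 1.7, 0.6
    ours = marginal_loglik(data, M2, beta, theta, sigma)

    expected = 0.0
    for z in ("za", "zb"):
        sub = data[data.zone == z]
        eta = beta[0] + beta[1] * sub["vmd"].to_numpy()
        y = sub["count"].to_numpy()

        def logf(u):
            return _nb2_logpmf(y, np.exp(eta + u), theta).sum() + sps.norm.logpdf(u, 0, sigma)

        # rescale by the peak so quad integrates an O(1) function
        grid = np.linspace(-6 * sigma, 6 * sigma, 201)
        c = max(logf(u) for u in grid)
        val, err = integrate.quad(lambda u: np.exp(logf(u) - c), -8 * sigma, 8 * sigma, limit=400)
        assert err < 1e-7 * val
        expected += c + np.log(val)
    ours_hi = marginal_loglik(data, M2, beta, theta, sigma, n_quad=60)
    assert ours_hi == pytest.approx(expected, abs=1e-6)
    # the default 15-node rule is itself accurate here
    assert ours == pytest.approx(expected, abs=1e-4)


def test_poisson_limit_of_fixed_effect_loglik():
    """With sigma = 0 and theta very large the NB2 log-likelihood at fixed
    parameters matches an independent Poisson summation within 1e-6."""
    rng = np.random.default_rng(11)
    n = 10
    data = pd.DataFrame(
        {
            "count": rng.poisson(2.0, n),
            "vmd": rng.uniform(1, 2, n),
            "group": "all",
            "zone": "z",
        }
    )
    beta = np.array([0.4, 0.2])
    ours = marginal_loglik(data, M1, beta, theta=1e8, sigma=0.0)
    mu = np.exp(beta[0] + beta[1] * data["vmd"].to_numpy())
    poisson = sps.poisson.logpmf(data["count"].to_numpy(), mu).sum()
    assert ours == pytest.approx(poisson, abs=1e-6)


def test_quadrature_stability(small_counts):
    """Estimates with 7 vs 25 quadrature nodes differ by < 1e-3."""
    counts, _ = small_counts
    f7 = fit_model(M3, counts, n_quad=7)
    f25 = fit_model(M3, counts, n_quad=25)
    assert np.abs(f7.params - f25.params).max() < 1e-3


def test_sigma_zero_limit_matches_statsmodels(small_scene):
    """M1 (sigma = 0) agrees with the independent statsmodels NB2 MLE."""
    import statsmodels.api as sm

    cfg, sc = small_scene
    groups = tuple(GroupParams(g.gender, g.year_group, 0.0, -0.4, 0.0) for g in pv.DEFAULT_GROUPS)
    cfg0 = GeneratorConfig(
        template="random-obstacles",
        boundary_size=(11.7, 11.7),
        n_random_obstacles=4,
        n_random_zones=4,
        groups=groups,
        sigma_zone=0.0,
    )
    counts, _ = generate_cell_counts(sc.layout, sc.lattice, sc.vmd, cfg0, seed=9)
    ours = fit_model(M1, counts)
    X = np.column_stack([np.ones(len(counts)), counts["vmd"]])
    ref = sm.NegativeBinomial(counts["count"].to_numpy(), X).fit(disp=0)
    assert ours.loglik == pytest.approx(ref.llf, abs=1e-4)
    assert np.allclose(ours.beta.to_numpy(), ref.params[:2], atol=2e-4)
    assert ours.theta == pytest.approx(1.0 / ref.params[-1], rel=1e-3)


def test_m2_reduces_to_m1_when_sigma_zero(small_scene):
    """On data generated without zone effects, M2's fixed-effect estimates
    agree with M1's within one standard error."""
    cfg, sc = small_scene
    cfg0 = GeneratorConfig(
        template="random-obstacles",
        boundary_size=(11.7, 11.7),
        n_random_obstacles=4,
        n_random_zones=4,
        sigma_zone=0.0,
    )
    counts, _ = generate_cell_counts(sc.layout, sc.lattice, sc.vmd, cfg0, seed=21)
    f1 = fit_model(M1, counts)
    f2 = fit_model(M2, counts)
    for name in ("intercept", "slope"):
        se = f1.beta_se[name]
        assert abs(f1.beta[name] - f2.beta[name]) < se
    assert f2.sigma_zone < 0.1


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_m3_matches_glmmtmb(small_counts, tmp_path):
    """Independent oracle: glmmTMB (R) on the same data reproduces the M3
    coefficients, dispersion, zone variance and log-likelihood."""
    counts, _ = small_counts
    fit = fit_model(M3, counts)
    csv = tmp_path / "counts.csv"
    counts.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        f"""
suppressMessages(library(glmmTMB))
d <- read.csv("{csv}")
d$group <- factor(d$group); d$zone <- factor(d$zone)
m <- glmmTMB(count ~ 0 + group + group:vmd + (1|zone), family = nbinom2, data = d)
co <- fixef(m)$cond
cat("loglik", sprintf("%.6f", as.numeric(logLik(m))), "\\n")
cat("sigma", sprintf("%.6f", sqrt(VarCorr(m)$cond$zone[1,1])), "\\n")
cat("theta", sprintf("%.6f", sigma(m)), "\\n")
for (n in names(co)) cat(n, sprintf("%.6f", co[[n]]), "\\n")
"""
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr[-2000:]
    ref = {}
    for line in out.stdout.strip().splitlines():
        parts = line.split()
        if len(parts) >= 2:
            ref[parts[0]] = float(parts[1])
    assert fit.loglik == pytest.approx(ref["loglik"], abs=0.05)
    assert fit.theta == pytest.approx(ref["theta"], rel=0.02)
    assert fit.sigma_zone == pytest.approx(ref["sigma"], rel=0.05)
    for g in fit.groups:
        assert fit.beta[f"slope[{g}]"] == pytest.approx(ref[f"group{g}:vmd"], abs=2e-3)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def test_sequence_loglik_non_decreasing(small_counts):
    counts, _ = small_counts
    fits = [fit_model(m, counts) for m in (M0, M1, M2, M3)]
    lls = [f.loglik for f in fits]
    assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))
    report = compare_models(fits)
    # LRT equals the hand-recomputed 2 * delta logLik
    for prev, cur in zip(fits[:-1], fits[1:]):
        assert report.loc[cur.spec.name, "lrt"] == pytest.approx(
            2 * (cur.loglik - prev.loglik), abs=1e-9
        )
        assert report.loc[cur.spec.name, "lrt_df"] == cur.k_params - prev.k_params
    # the variance-addition step uses the 50:50 boundary mixture
    assert bool(report.loc["M2", "boundary_mixture"])
    assert not bool(report.loc["M1", "boundary_mixture"])
    assert report["selected"].sum() == 1


def test_identical_fits_give_lrt_zero_p_one(m3_fit):
    """A duplicate fit adds parameters but no likelihood: LRT = 0, p = 1."""
    from dataclasses import replace

    inflated = replace(m3_fit, k_params=m3_fit.k_params + 1)
    report = compare_models([m3_fit, inflated])
    assert report["lrt"].iloc[-1] == pytest.approx(0, abs=1e-9)
    assert report["lrt_p"].iloc[-1] == pytest.approx(1.0)


def test_compare_models_rejects_different_data(small_scene, small_counts):
    cfg, sc = small_scene
    counts, _ = small_counts
    other, _ = generate_cell_counts(sc.layout, sc.lattice, sc.vmd, cfg, seed=99)
    f2 = fit_model(M2, counts)
    f3 = fit_model(M3, other)
    with pytest.raises(ValueError, match="identical data"):
        compare_models([f2, f3])


def test_compare_models_rejects_non_extension(m3_fit):
    with pytest.raises(ValueError):
        compare_models([m3_fit, m3_fit])


# ---------------------------------------------------------------------------
# Group effects and predictions
# ---------------------------------------------------------------------------

def test_effect_transforms_roundtrip(m3_fit):
    """slope -> IRR -> percent change transforms: 0 -> +0%,
    ln(0.53) -> -47%, ln(2) -> +100%."""
    effects = group_effects(m3_fit)
    assert {e.group for e in effects} == set(m3_fit.groups)
    for e in effects:
        assert e.irr == pytest.approx(np.exp(e.slope), rel=1e-12)
        assert e.pct_change == pytest.approx(100 * (np.exp(e.slope) - 1), rel=1e-12)
        assert np.sign(e.pct_change) == np.sign(e.slope)
        assert e.pct_change > -100
    assert 100 * (np.exp(0.0) - 1) == 0.0
    assert round(100 * (np.exp(np.log(0.53)) - 1)) == -47
    assert 100 * (np.exp(np.log(2.0)) - 1) == pytest.approx(100.0)


def test_group_effects_requires_interaction_fit(small_counts):
    counts, _ = small_counts
    f1 = fit_model(M1, counts)
    with pytest.raises(ValueError, match="group"):
        group_effects(f1)


def test_predicted_counts_log_linearity(m3_fit):
    """mu(v + 1) / mu(v) equals the group IRR for every v (flat when the
    slope is zero), and the band widens away from the VMD mean."""
    g = m3_fit.groups[0]
    irr = [e for e in group_effects(m3_fit) if e.group == g][0].irr
    grid = np.linspace(*m3_fit.vmd_range, 9)
    pred = predicted_counts(m3_fit, grid, group=g)
    pred1 = predicted_counts(m3_fit, grid + (grid[1] - grid[0]), group=g)
    # ratio across one grid step matches IRR^step
    step = grid[1] - grid[0]
    ratios = pred1["mu"].to_numpy() / pred["mu"].to_numpy()
    assert np.allclose(ratios, irr**step, rtol=1e-9)
    widths = np.log(pred["hi"].to_numpy()) - np.log(pred["lo"].to_numpy())
    centre = np.argmin(widths)
    assert widths[0] >= widths[centre] and widths[-1] >= widths[centre]


def test_predicted_counts_match_parametric_bootstrap(m3_fit):
    """Delta-rule bands agree with 1,000-draw parametric-bootstrap bands."""
    rng = np.random.default_rng(17)
    g = m3_fit.groups[1]
    grid = np.linspace(*m3_fit.vmd_range, 5)
    pred = predicted_counts(m3_fit, grid, group=g)
    p = m3_fit.p_mean
    draws = rng.multivariate_normal(m3_fit.params[:p], m3_fit.cov[:p, :p], size=1000)
    names = m3_fit.param_names[:p]
    X = np.zeros((len(grid), p))
    X[:, names.index("intercept")] = 1.0
    off = f"offset[{g}]"
    if off in names:
        X[:, names.index(off)] = 1.0
    X[:, names.index(f"slope[{g}]")] = grid
    boot = np.exp(draws @ X.T)  # (1000, grid)
    lo, hi = np.quantile(boot, [0.025, 0.975], axis=0)
    assert np.allclose(pred["lo"], lo, rtol=0.15)
    assert np.allclose(pred["hi"], hi, rtol=0.15)


def test_predicted_counts_extrapolation_warning(m3_fit, caplog):
    with caplog.at_level(logging.WARNING, logger="playvis"):
        predicted_counts(m3_fit, [m3_fit.vmd_range[1] + 2.0], group=m3_fit.groups[0])
    assert any("extrapolat" in r.message.lower() for r in caplog.records)


def test_flat_curve_when_slope_zero():
    fit = ModelFit(
        spec=M3,
        param_names=["intercept", "offset[b]", "slope[a]", "slope[b]", "log_theta", "log_sigma"],
        params=np.array([1.0, 0.5, 0.0, -0.3, 0.0, np.log(0.4)]),
        cov=np.eye(6) * 1e-4,
        loglik=0.0,
        n_obs=10,
        k_params=6,
        groups=["a", "b"],
        zones=["z1", "z2"],
        vmd_range=(1.0, 3.0),
        data_hash="x",
        converged=True,
    )
    pred = predicted_counts(fit, [1.0, 2.0, 3.0], group="a")
    assert np.allclose(pred["mu"], np.exp(1.0))


# ---------------------------------------------------------------------------
# Dispersion diagnostics
# ---------------------------------------------------------------------------

def test_overdispersion_poisson_data_ratio_near_one():
    rng = np.random.default_rng(31)
    n = 5000
    vmd = rng.uniform(1, 3, n)
    mu = np.exp(0.5 + 0.3 * vmd)
    data = pd.DataFrame({"count": rng.poisson(mu), "vmd": vmd, "group": "all", "zone": "z"})
    diag = check_overdispersion(data)
    assert 0.8 <= diag.pearson_ratio <= 1.2
    assert not diag.overdispersed
    assert abs(diag.zero_observed - diag.zero_expected) < 0.02


def test_overdispersion_nb_data_flagged():
    rng = np.random.default_rng(32)
    n = 5000
    vmd = rng.uniform(1, 3, n)
    mu = np.exp(0.5 + 0.3 * vmd)
    theta = 0.5
    y = rng.poisson(rng.gamma(theta, mu / theta))
    data = pd.DataFrame({"count": y, "vmd": vmd, "group": "all", "zone": "z"})
    diag = check_overdispersion(data)
    assert diag.pearson_ratio > 1.5
    assert diag.overdispersed


def test_overdispersion_degenerate_inputs(caplog):
    const = pd.DataFrame({"count": [3] * 50, "vmd": np.linspace(1, 2, 50), "group": "all", "zone": "z"})
    with caplog.at_level(logging.WARNING, logger="playvis"):
        diag = check_overdispersion(const)
    assert diag.pearson_ratio < 0.05
    zeros = pd.DataFrame({"count": [0] * 50, "vmd": np.linspace(1, 2, 50), "group": "all", "zone": "z"})
    with pytest.raises(ValueError, match="zero"):
        check_overdispersion(zeros)


# ---------------------------------------------------------------------------
# Fit guards
# ---------------------------------------------------------------------------

def test_fit_requires_columns_and_zones(small_counts):
    counts, _ = small_counts
    with pytest.raises(ValueError, match="columns"):
        fit_model(M3, counts.drop(columns=["vmd"]))
    single_zone = counts.assign(zone="only")
    with pytest.raises(ValueError, match="zones"):
        fit_model(M2, single_zone)
    zero = counts.assign(count=0)
    with pytest.raises(ValueError, match="zero"):
        fit_model(M1, zero)
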