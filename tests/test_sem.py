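"""SEM engine: implied moments, discrepancy, fitting, indices,
standardization, reliability, nested comparison.

The two-group oracle test cross-checks the engine against an independently
coded brute-force minimizer of the same normal-theory discrepancy
(different parametrization, numeric gradients, no shared code).
"""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from sleepsem import sem
from sleepsem.sem import GroupMoments, SemSpec


def _exact_cov_data(S, n=60, mean=None, seed=0):
    """Data whose sample covariance (ddof=0) equals S exactly."""
    rng = np.random.default_rng(seed)
    p = S.shape[0]
    X = rng.standard_normal((n, p))
    X -= X.mean(axis=0)
    K = np.linalg.cholesky(np.cov(X.T, ddof=0))
    # whiten (post-multiply by K^-T), then color by chol(S)
    X = X @ np.linalg.inv(K).T @ np.linalg.cholesky(S).T
    if mean is not None:
        X += mean
    return pd.DataFrame(X, columns=[f"y{i}" for i in range(1, p + 1)])


# ----------------------------------------------------------------------
# implied moments


def test_implied_no_common_factors_sigma_equals_theta():
    spec = SemSpec(["all"])
    spec.add_factor("f", ["y1", "y2"], variance=1.0, loadings=[0.0, 0.0])
    spec.set_parameter("theta", "y1", "y1", free=False, value=2.0)
    spec.set_parameter("theta", "y2", "y2", free=False, value=3.0)
    spec.set_parameter("nu", "y1", "", free=False, value=0.0)
    spec.set_parameter("nu", "y2", "", free=False, value=0.0)
    Sigma, mu = sem.implied_moments(spec)["all"]
    np.testing.assert_allclose(Sigma, np.diag([2.0, 3.0]))
    np.testing.assert_allclose(mu, 0.0)


def test_implied_one_factor_unit_loadings():
    spec = SemSpec(["all"])
    spec.add_factor("f", ["y1", "y2", "y3"], variance=1.0, loadings=[1, 1, 1])
    for v in ("y1", "y2", "y3"):
        spec.set_parameter("theta", v, v, free=False, value=0.5)
        spec.set_parameter("nu", v, "", free=False, value=0.0)
    Sigma, _ = sem.implied_moments(spec)["all"]
    expected = np.full((3, 3), 1.0)
    np.fill_diagonal(expected, 1.5)
    np.testing.assert_allclose(Sigma, expected)


def test_implied_bifactor_shared_g_only():
    # two items sharing only the general factor: implied covariance is the
    # product of their G loadings (hand expansion of Lam Psi Lam')
    spec = SemSpec(["all"])
    spec.add_factor("g", ["y1", "y2", "y3", "y4"], variance=1.0,
                    loadings=[0.7, 0.6, 0.5, 0.4])
    spec.add_factor("s1", ["y1", "y2"], variance=1.0, loadings=[0.3, 0.2])
    spec.add_factor("s2", ["y3", "y4"], variance=1.0, loadings=[0.4, 0.3])
    for v in spec.observed:
        spec.set_parameter("theta", v, v, free=False, value=0.3)
        spec.set_parameter("nu", v, "", free=False, value=0.0)
    Sigma, _ = sem.implied_moments(spec)["all"]
    # y1 (g, s1) and y3 (g, s2) share only g
    assert Sigma[0, 2] == pytest.approx(0.7 * 0.5)
    assert Sigma[1, 3] == pytest.approx(0.6 * 0.4)
    # y1 and y2 share g and s1
    assert Sigma[0, 1] == pytest.approx(0.7 * 0.6 + 0.3 * 0.2)


def test_nonrecursive_model_rejected():
    spec = SemSpec(["all"])
    spec.add_manifest("a")
    spec.add_manifest("b")
    spec.add_regression("a", "b", free=False, value=1.0)
    spec.add_regression("b", "a", free=False, value=1.0)
    with pytest.raises(ValueError, match="singular"):
        sem.implied_moments(spec)


# ----------------------------------------------------------------------
# discrepancy


def test_ml_discrepancy_zero_at_saturation(rng):
    A = rng.standard_normal((4, 4))
    S = A @ A.T + 4 * np.eye(4)
    mo = {"all": GroupMoments(S=S, mean=rng.standard_normal(4), n=100)}
    F = sem.ml_discrepancy(mo, {"all": (S, mo["all"].mean)})
    assert F == pytest.approx(0.0, abs=1e-12)


def test_ml_discrepancy_scalar_hand_value():
    mo = {"all": GroupMoments(S=np.array([[2.0]]), mean=np.zeros(1), n=10)}
    F = sem.ml_discrepancy(mo, {"all": (np.array([[1.0]]), np.zeros(1))})
    assert F == pytest.approx(np.log(1) - np.log(2) + 2 - 1, abs=1e-10)
    assert F == pytest.approx(0.3069, abs=5e-5)


def test_ml_discrepancy_nonnegative_random_pd(rng):
    for _ in range(50):
        A = rng.standard_normal((3, 3))
        S = A @ A.T + 3 * np.eye(3)
        B = rng.standard_normal((3, 3))
        Sig = B @ B.T + 3 * np.eye(3)
        mo = {"all": GroupMoments(S=S, mean=np.zeros(3), n=50)}
        assert sem.ml_discrepancy(mo, {"all": (Sig, np.zeros(3))}) >= -1e-12


# ----------------------------------------------------------------------
# fitting


def test_saturated_model_reproduces_moments(rng):
    A = rng.standard_normal((3, 3))
    S = A @ A.T + 3 * np.eye(3)
    data = _exact_cov_data(S, mean=np.array([1.0, -2.0, 0.5]))
    data["gender"] = "all"
    spec = SemSpec(["all"])
    for v in ("y1", "y2", "y3"):
        spec.add_manifest(v)
    for i, a in enumerate(("y1", "y2", "y3")):
        for b in ("y1", "y2", "y3")[i + 1:]:
            spec.add_covariance(a, b)
    res = sem.fit(spec, data=data, se=False)
    assert res.df == 0
    assert res.chi2 == pytest.approx(0.0, abs=1e-6)
    for i, v in enumerate(("y1", "y2", "y3")):
        assert res.param("psi", v, v, "all") == pytest.approx(S[i, i], abs=1e-5)
    assert res.param("psi", "y1", "y2", "all") == pytest.approx(S[0, 1], abs=1e-5)
    assert res.param("alpha", "y1", "", "all") == pytest.approx(1.0, abs=1e-5)


def test_one_factor_closed_form_loadings():
    # just-identified: unit variances, equal covariances 0.5 ->
    # lam_i lam_j = 0.5 solved by lam = sqrt(0.5), theta = 0.5
    S = np.full((3, 3), 0.5)
    np.fill_diagonal(S, 1.0)
    mo = {"all": GroupMoments(S=S, mean=np.zeros(3), n=500)}
    spec = SemSpec(["all"])
    spec.add_factor("f", ["y1", "y2", "y3"], variance=1.0)
    res = sem.fit(spec, moments=mo, se=False)
    assert res.converged
    for v in ("y1", "y2", "y3"):
        assert res.param("lam", v, "f", "all") == pytest.approx(np.sqrt(0.5), abs=1e-6)
        assert res.param("theta", v, v, "all") == pytest.approx(0.5, abs=1e-6)
    assert res.chi2 == pytest.approx(0.0, abs=1e-6)


def test_two_group_separability(rng):
    A = rng.standard_normal((3, 3))
    S = A @ A.T + 3 * np.eye(3)
    d1 = _exact_cov_data(S, seed=1)
    d1["gender"] = "g1"
    d2 = d1.copy()
    d2["gender"] = "g2"
    both = pd.concat([d1, d2], ignore_index=True)
    spec2 = SemSpec(["g1", "g2"])
    spec2.add_factor("f", ["y1", "y2", "y3"], variance=1.0)
    res2 = sem.fit(spec2, data=both, se=False)
    spec1 = SemSpec(["g1"])
    spec1.add_factor("f", ["y1", "y2", "y3"], variance=1.0)
    res1 = sem.fit(spec1, data=d1, se=False)
    for v in ("y1", "y2", "y3"):
        lam1 = res1.param("lam", v, "f", "g1")
        assert res2.param("lam", v, "f", "g1") == pytest.approx(lam1, abs=1e-5)
        assert res2.param("lam", v, "f", "g2") == pytest.approx(lam1, abs=1e-5)


def test_chi2_central_under_true_model():
    """Null calibration: chi-square/df averages near 1 over 200 one-factor
    simulations from the true model."""
    rng = np.random.default_rng(555)
    lam = np.array([0.8, 0.7, 0.6, 0.5])
    theta = 1 - lam**2
    ratios = []
    spec = SemSpec(["all"])
    spec.add_factor("f", ["y1", "y2", "y3", "y4"], variance=1.0)
    for _ in range(200):
        n = 500
        f = rng.standard_normal(n)
        X = f[:, None] * lam + rng.standard_normal((n, 4)) * np.sqrt(theta)
        df = pd.DataFrame(X, columns=["y1", "y2", "y3", "y4"])
        df["gender"] = "all"
        res = sem.fit(spec, data=df, se=False)
        assert res.df == 2
        ratios.append(res.chi2 / res.df)
    assert 0.9 < np.mean(ratios) < 1.1


def test_wishart_chisq_option(rng):
    S = np.full((3, 3), 0.4)
    np.fill_diagonal(S, 1.0)
    data = _exact_cov_data(S, n=80, seed=5)
    data["gender"] = "all"
    spec = SemSpec(["all"])
    spec.add_factor("f", ["y1", "y2", "y3"], variance=1.0)
    # over-identify by constraining two loadings equal
    spec.constrain_equal("lam", "y1", "f")  # no-op single group; keep free
    res_ml = sem.fit(spec, data=data, se=False, chisq_mode="ml")
    res_w = sem.fit(spec, data=data, se=False, chisq_mode="wishart")
    # ml uses n, wishart n-1 (estimates at a saturated optimum: chi2 ~ 0)
    assert res_ml.chi2 == pytest.approx(0.0, abs=1e-6)
    assert res_w.chi2 == pytest.approx(0.0, abs=1e-6)


def test_oracle_equivalence_two_group_one_factor():
    """Engine vs an independent brute-force ML minimizer on a two-group,
    six-indicator one-factor fixture (n = 500/group)."""
    rng = np.random.default_rng(4242)
    lam_true = {"g1": np.array([0.8, 0.75, 0.7, 0.65, 0.6, 0.55]),
                "g2": np.array([0.7, 0.65, 0.72, 0.6, 0.55, 0.5])}
    frames = []
    for g, lt in lam_true.items():
        n = 500
        f = rng.standard_normal(n)
        X = f[:, None] * lt + rng.standard_normal((n, 6)) * np.sqrt(1 - lt**2)
        d = pd.DataFrame(X, columns=[f"y{i}" for i in range(1, 7)])
        d["gender"] = g
        frames.append(d)
    data = pd.concat(frames, ignore_index=True)

    spec = SemSpec(["g1", "g2"])
    spec.add_factor("f", [f"y{i}" for i in range(1, 7)], variance=1.0)
    res = sem.fit(spec, data=data, se=False)
    assert res.converged

    # independent oracle: per-group direct minimization over (lam, log theta)
    # of ln|Sigma| - ln|S| + tr(S Sigma^-1) - p, numeric gradients
    for g in ("g1", "g2"):
        sub = data[data.gender == g][[f"y{i}" for i in range(1, 7)]].to_numpy()
        S = np.cov(sub.T, ddof=0)
        _, logdet_s = np.linalg.slogdet(S)

        def F(par):
            lam, logth = par[:6], par[6:]
            Sig = np.outer(lam, lam) + np.diag(np.exp(logth))
            sign, logdet = np.linalg.slogdet(Sig)
            if sign <= 0:
                return 1e9
            return logdet - logdet_s + np.trace(S @ np.linalg.inv(Sig)) - 6

        x0 = np.concatenate([np.full(6, 0.6), np.log(np.full(6, 0.5))])
        best = optimize.minimize(F, x0, method="Nelder-Mead",
                                 options={"maxiter": 20000, "xatol": 1e-10,
                                          "fatol": 1e-12})
        best = optimize.minimize(F, best.x, method="BFGS",
                                 options={"gtol": 1e-10, "maxiter": 2000})
        lam_o = best.x[:6] * np.sign(best.x[:6].sum())
        th_o = np.exp(best.x[6:])
        for i, v in enumerate([f"y{i}" for i in range(1, 7)]):
            assert res.param("lam", v, "f", g) == pytest.approx(lam_o[i], abs=1e-4)
            assert res.param("theta", v, v, g) == pytest.approx(th_o[i], abs=1e-4)


def test_standard_errors_reasonable():
    rng = np.random.default_rng(8)
    n = 800
    f = rng.standard_normal(n)
    lam = np.array([0.8, 0.7, 0.6, 0.5])
    X = f[:, None] * lam + rng.standard_normal((n, 4)) * np.sqrt(1 - lam**2)
    d = pd.DataFrame(X, columns=["y1", "y2", "y3", "y4"])
    d["gender"] = "all"
    spec = SemSpec(["all"])
    spec.add_factor("f", ["y1", "y2", "y3", "y4"], variance=1.0)
    res = sem.fit(spec, data=d, se=True)
    se = res.param("lam", "y1", "f", "all", "se")
    # rough asymptotic order: SE(lambda) ~ 1/sqrt(n)
    assert 0.01 < se < 0.08


# ----------------------------------------------------------------------
# indices, standardization, reliability, nesting


def test_fit_indices_hand_example():
    out = sem.fit_indices(100, 50, 1000, 60, 450, G=1)
    assert out["rmsea"] == pytest.approx(0.0471, abs=1e-4)
    assert out["cfi"] == pytest.approx(0.9468, abs=1e-4)
    assert out["tli"] == pytest.approx(0.9362, abs=1e-4)


def test_fit_indices_perfect_and_undefined():
    out = sem.fit_indices(50, 50, 500, 60, 300)
    assert out["rmsea"] == 0.0 and out["cfi"] == 1.0
    assert sem.fit_indices(10, 0, 100, 10, 300)["rmsea"] is None


def test_srmr_zero_at_exact_fit(rng):
    A = rng.standard_normal((3, 3))
    S = A @ A.T + 3 * np.eye(3)
    mo = {"all": GroupMoments(S=S, mean=np.ones(3), n=100)}
    assert sem.srmr(mo, {"all": (S, np.ones(3))}) == pytest.approx(0.0, abs=1e-12)


def test_standardize_identity_and_ratio():
    spec = SemSpec(["all"])
    spec.add_factor("f", ["y1", "y2"], variance=1.0, loadings=[2.0, 1.0])
    spec.set_parameter("theta", "y1", "y1", free=False, value=2.25)
    spec.set_parameter("theta", "y2", "y2", free=False, value=0.5)
    spec.set_parameter("nu", "y1", "", free=False, value=0.0)
    spec.set_parameter("nu", "y2", "", free=False, value=0.0)
    mo = {"all": GroupMoments(S=np.array([[6.25, 2.0], [2.0, 1.5]]),
                              mean=np.zeros(2), n=100)}
    res = sem.fit(spec, moments=mo, se=False)
    std = sem.standardize(res)
    row = std[(std.matrix == "lam") & (std.row == "y1")]
    # loading 2 on SD-1 factor, implied indicator SD 2.5 -> 0.8
    assert float(row["std"].iloc[0]) == pytest.approx(0.8)


def test_standardized_loadings_are_factor_correlations():
    rng = np.random.default_rng(77)
    lam = np.array([0.9, 0.6, 0.3])
    n = 2000
    f = rng.standard_normal(n)
    X = f[:, None] * lam + rng.standard_normal((n, 3)) * np.sqrt(1 - lam**2)
    d = pd.DataFrame(X, columns=["y1", "y2", "y3"])
    d["gender"] = "all"
    spec = SemSpec(["all"])
    spec.add_factor("f", ["y1", "y2", "y3"], variance=1.0)
    res = sem.fit(spec, data=d, se=False)
    std = sem.standardize(res)
    for v in ("y1", "y2", "y3"):
        lam_hat = res.param("lam", v, "f", "all")
        th_hat = res.param("theta", v, v, "all")
        expected = lam_hat / np.sqrt(lam_hat**2 + th_hat)
        got = float(std[(std.matrix == "lam") & (std.row == v)]["std"].iloc[0])
        assert got == pytest.approx(expected, abs=1e-8)


def test_reliability_hand_values():
    # perfectly parallel pair -> alpha = 1
    rng = np.random.default_rng(11)
    y = rng.standard_normal(60)
    pair = pd.DataFrame({"a": y, "b": y})
    alpha, _ = sem.reliability(pair)
    assert alpha == pytest.approx(1.0)
    # 3 items, unit variances, covariances 0.5 -> alpha = 0.75 (= omega,
    # tau-equivalent case)
    S = np.full((3, 3), 0.5)
    np.fill_diagonal(S, 1.0)
    items = _exact_cov_data(S, n=120, seed=13)
    alpha, omega = sem.reliability(items)
    assert alpha == pytest.approx(0.75, abs=1e-9)
    assert omega == pytest.approx(0.75, abs=1e-3)
    # independent items -> alpha = 0
    eye = _exact_cov_data(np.eye(3), n=120, seed=14)
    alpha0, _ = sem.reliability(eye)
    assert alpha0 == pytest.approx(0.0, abs=1e-9)


def test_chisq_diff_bookkeeping(rng):
    A = rng.standard_normal((3, 3))
    S = A @ A.T + 3 * np.eye(3)
    d1 = _exact_cov_data(S, seed=21)
    d1["gender"] = "g1"
    d2 = d1.copy()
    d2["gender"] = "g2"
    both = pd.concat([d1, d2], ignore_index=True)

    def build():
        s = SemSpec(["g1", "g2"])
        s.add_factor("f", ["y1", "y2", "y3"], variance=1.0)
        return s

    full = sem.fit(build(), data=both, se=False)
    same = sem.chisq_diff(full, full)
    assert same == (0.0, 0)
    constrained = build()
    constrained.constrain_equal("lam", "y1", "f")
    nested = sem.fit(constrained, data=both, se=False)
    dchi, ddf = sem.chisq_diff(nested, full)
    assert ddf == 1  # one newly constrained free parameter
    assert dchi == pytest.approx(0.0, abs=1e-4)  # identical groups
    with pytest.raises(ValueError, match="not nested"):
        sem.chisq_diff(full, nested)


def test_spec_serialization_round_trip():
    from sleepsem.models import primary_mediation_spec

    spec = primary_mediation_spec()
    back = SemSpec.from_dict(spec.to_dict())
    assert back.observed == spec.observed
    assert back.eta == spec.eta
    assert back.n_free() == spec.n_free()


def test_unidentified_spec_rejected():
    spec = SemSpec(["all"])
    spec.add_factor("f", ["y1", "y2", "y3"], variance="free")
    with pytest.raises(ValueError, match="scaling rule"):
        spec.validate()
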