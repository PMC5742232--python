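"""Meta-regressions, prediction, confidence intervals, and the meta-NCA."""

import numpy as np
import pandas as pd
import pytest

from ncaskew import (
    PUBLISHED_EFFECT_CE,
    PUBLISHED_EFFECT_CR,
    PUBLISHED_SE_CE,
    PUBLISHED_SE_CR,
    assess_observed,
    confidence_interval,
    expected_table,
    fit_effect_model,
    fit_se_model,
    inv_logit,
    meta_nca,
    predict_effect,
    predict_se,
)
from ncaskew.errors import UnfittableModelError


def make_records(sx, sy, eff_ce, eff_cr=None, n=200):
    k = len(sx)
    return pd.DataFrame({
        "cell": np.zeros(k, dtype=int), "rep": np.arange(k), "seed": 0,
        "n": np.full(k, n),
        "pop_skew_x": sx, "pop_skew_y": sy,
        "skew_x_obs": sx, "skew_y_obs": sy,
        "ce": eff_ce, "cr": eff_ce if eff_cr is None else eff_cr,
    })


# ------------------------------------------------------------ effect model

def test_effect_model_noiseless_recovery():
    rng = np.random.default_rng(0)
    sx = rng.uniform(-2, 2, 200)
    sy = rng.uniform(-2, 2, 200)
    z = -3.0 - 1.0 * sx + 1.0 * sy
    rec = make_records(sx, sy, 1 / (1 + np.exp(-z)))
    m = fit_effect_model(rec, "CE-FDH")
    assert m.b0 == pytest.approx(-3.0, abs=1e-9)
    assert m.b_x == pytest.approx(-1.0, abs=1e-9)
    assert m.b_y == pytest.approx(1.0, abs=1e-9)
    assert m.b_xy == pytest.approx(0.0, abs=1e-9)
    assert m.r2 == pytest.approx(1.0, abs=1e-9)


def test_effect_model_matches_normal_equations():
    # small fixed design, checked against the normal equations solved
    # directly in the test
    sx = np.array([-1.5, -0.5, 0.0, 0.4, 1.0, 1.5, -1.0, 0.8, 0.1, -0.3,
                   0.6, -0.9])
    sy = np.array([1.0, -0.5, 0.3, -1.2, 0.8, 0.0, 1.4, -0.7, 0.2, 0.9,
                   -1.1, 0.5])
    eff = np.array([0.4, 0.1, 0.15, 0.05, 0.08, 0.03, 0.5, 0.04, 0.12,
                    0.2, 0.02, 0.3])
    m = fit_effect_model(make_records(sx, sy, eff), "CE-FDH")
    X = np.column_stack([np.ones_like(sx), sx, sy, sx * sy])
    z = np.log(eff / (1 - eff))
    beta = np.linalg.solve(X.T @ X, X.T @ z)
    assert [m.b0, m.b_x, m.b_y, m.b_xy] == pytest.approx(beta.tolist(),
                                                          abs=1e-8)
    sse = float(np.sum((z - X @ beta) ** 2))
    sst = float(np.sum((z - z.mean()) ** 2))
    assert m.r2 == pytest.approx(1 - sse / sst, abs=1e-10)


def test_effect_model_excludes_boundary_records():
    rng = np.random.default_rng(1)
    sx = rng.uniform(-1, 1, 50)
    sy = rng.uniform(-1, 1, 50)
    eff = 1 / (1 + np.exp(3.0 + sx - sy))
    eff[:5] = 0.0   # boundary effects: logit undefined, must be dropped
    eff[5] = 1.0
    rec = make_records(sx, sy, eff)
    m = fit_effect_model(rec, "CE-FDH")
    assert m.n_used == 44


def test_effect_model_noise_recovery():
    # with additive logit-scale noise the fit converges to the truth
    rng = np.random.default_rng(42)
    k = 10_000
    sx = rng.uniform(-1.5, 1.5, k)
    sy = rng.uniform(-1.5, 1.5, k)
    z = -3.19 - 1.14 * sx + 1.14 * sy + 0.10 * sx * sy
    eff = 1 / (1 + np.exp(-(z + rng.normal(0, 0.8, k))))
    m = fit_effect_model(make_records(sx, sy, eff), "CE-FDH")
    for got, want in [(m.b0, -3.19), (m.b_x, -1.14), (m.b_y, 1.14),
                      (m.b_xy, 0.10)]:
        assert got == pytest.approx(want, abs=0.05)


def test_effect_model_too_few_records():
    rec = make_records(np.array([0.0, 1.0, 2.0]), np.array([1.0, 0.0, 2.0]),
                       np.array([0.1, 0.2, 0.3]))
    with pytest.raises(UnfittableModelError):
        fit_effect_model(rec, "CE-FDH")


# ---------------------------------------------------------------- SE model

def make_cells(n, sx, sy, se):
    k = len(se)
    return pd.DataFrame({
        "cell": np.arange(k), "n": n,
        "pop_skew_x": sx, "pop_skew_y": sy,
        "mean_ce": 0.1, "mean_cr": 0.1,
        "se_ce": se, "se_cr": se,
        "n_valid_cr": 100, "reps": 100,
    })


def test_se_model_noiseless_recovery():
    n = np.array([50, 200, 800, 3200, 12800, 50, 200, 800])
    sx = np.array([-1.0, 0.5, 0.0, 1.0, -0.5, 0.3, -0.2, 0.8])
    sy = np.array([0.5, -1.0, 0.3, 0.0, 1.0, -0.4, 0.9, -0.6])
    se = np.exp(-3.0 - 0.01 * np.sqrt(n) - 0.5 * sx + 0.4 * sy)
    m = fit_se_model(make_cells(n, sx, sy, se), "CE-FDH")
    assert m.c0 == pytest.approx(-3.0, abs=1e-9)
    assert m.c_n == pytest.approx(-0.01, abs=1e-11)
    assert m.c_x == pytest.approx(-0.5, abs=1e-9)
    assert m.c_y == pytest.approx(0.4, abs=1e-9)
    assert m.r2 == pytest.approx(1.0, abs=1e-9)


def test_se_model_matches_normal_equations():
    n = np.array([50, 200, 800, 3200, 12800])
    sx = np.array([-1.0, 0.5, 0.0, 1.0, -0.5])
    sy = np.array([0.5, -1.0, 0.3, 0.0, 1.0])
    se = np.array([0.2, 0.05, 0.1, 0.02, 0.15])
    m = fit_se_model(make_cells(n, sx, sy, se), "CE-FDH")
    X = np.column_stack([np.ones(5), np.sqrt(n), sx, sy])
    beta = np.linalg.solve(X.T @ X, X.T @ np.log(se))
    assert [m.c0, m.c_n, m.c_x, m.c_y] == pytest.approx(beta.tolist(),
                                                         abs=1e-8)


def test_se_model_excludes_zero_se_cells():
    n = np.repeat([50, 200, 800, 3200, 12800], 2)
    rng = np.random.default_rng(2)
    sx = rng.uniform(-1, 1, 10)
    sy = rng.uniform(-1, 1, 10)
    se = np.exp(-3.0 - 0.01 * np.sqrt(n) - 0.5 * sx + 0.4 * sy)
    se[0] = 0.0
    m = fit_se_model(make_cells(n, sx, sy, se), "CE-FDH")
    assert m.n_used == 9


# ------------------------------------------------------------- prediction

def test_predict_effect_published_values():
    assert predict_effect(PUBLISHED_EFFECT_CE, -1.0, 2.2) == pytest.approx(
        0.56, abs=0.005)
    assert predict_effect(PUBLISHED_EFFECT_CR, 0.0, 2.2) == pytest.approx(
        0.28, abs=0.005)
    assert predict_effect(PUBLISHED_EFFECT_CE, 0.0, 0.0) == pytest.approx(
        inv_logit(-3.19), abs=1e-12)


def test_predict_se_positive_and_decreasing_in_n():
    s1 = predict_se(PUBLISHED_SE_CE, 1594, 0.0, 2.2)
    assert s1 == pytest.approx(0.108, abs=0.002)
    assert predict_se(PUBLISHED_SE_CE, 50, 0.0, 2.2) > s1 > 0
    assert predict_se(PUBLISHED_SE_CR, 12800, -1.47, -1.47) > 0


def test_confidence_interval_plain_two_se():
    assert confidence_interval(0.5, 0.1) == (pytest.approx(0.3),
                                             pytest.approx(0.7))
    with pytest.raises(ValueError):
        confidence_interval(0.5, 0.0)


# ----------------------------------------------------------- expectations

TABLE2_EXPECTED = {  # skew_x -> (CE, CR) at skew_y = 2.2
    -1.0: (0.56, 0.50), -0.5: (0.44, 0.39), 0.0: (0.33, 0.28),
    0.5: (0.24, 0.20), 1.0: (0.17, 0.13),
}
TABLE2_CI_1594 = {  # skew_x -> (CE low, CE high, CR low, CR high)
    -1.0: (0.13, 0.98, 0.21, 0.79), -0.5: (0.14, 0.75, 0.15, 0.62),
    0.0: (0.12, 0.55, 0.09, 0.48), 0.5: (0.09, 0.40, 0.04, 0.36),
    1.0: (0.06, 0.28, 0.00, 0.26),
}


def test_expected_table_reproduces_published_expectations():
    df = expected_table(sorted(TABLE2_EXPECTED), 2.2, [1594, 255])
    for sx, (ce, cr) in TABLE2_EXPECTED.items():
        row_ce = df[(df.skew_x == sx) & (df.estimator == "CE-FDH")].iloc[0]
        row_cr = df[(df.skew_x == sx) & (df.estimator == "CR-FDH")].iloc[0]
        assert row_ce.expected == pytest.approx(ce, abs=0.01)
        assert row_cr.expected == pytest.approx(cr, abs=0.01)
        lo_ce, hi_ce, lo_cr, hi_cr = TABLE2_CI_1594[sx]
        assert row_ce.ci_low_n1594 == pytest.approx(lo_ce, abs=0.02)
        assert row_ce.ci_high_n1594 == pytest.approx(hi_ce, abs=0.02)
        assert row_cr.ci_low_n1594 == pytest.approx(lo_cr, abs=0.02)
        assert row_cr.ci_high_n1594 == pytest.approx(hi_cr, abs=0.02)
        assert row_ce.ci_low_n1594 < row_ce.expected < row_ce.ci_high_n1594


def test_expected_table_monotone_in_skews():
    df = expected_table(np.linspace(-1.5, 1.5, 7), 2.2, [100])
    for est in ("CE-FDH", "CR-FDH"):
        e = df[df.estimator == est].sort_values("skew_x")["expected"]
        assert (np.diff(e) < 0).all()  # decreasing in skew_x
    lo = expected_table([0.0], 0.5, [100])
    hi = expected_table([0.0], 2.0, [100])
    assert (hi["expected"].values > lo["expected"].values).all()


def test_ci_bounds_reported_untruncated():
    # at small n the band legitimately leaves [0, 1], as with a strongly
    # negative predictor skewness and n = 255
    df = expected_table([-1.0], 2.2, [255])
    row = df[df.estimator == "CE-FDH"].iloc[0]
    assert row.ci_low_n255 < 0.0 or row.ci_high_n255 > 1.0


# ----------------------------------------------------------- observed data

def test_assess_observed_verdicts():
    ce_rep, cr_rep = assess_observed(0.25, 0.21, 0.0, 2.2, 1594)
    assert ce_rep.verdict == "within"  # inside the expected band
    assert cr_rep.verdict == "within"
    ce_hi, _ = assess_observed(0.99, None, 0.0, 2.2, 1594)
    assert ce_hi.verdict == "above"
    ce_eq, _ = assess_observed(ce_rep.expected, None, 0.0, 2.2, 1594)
    assert ce_eq.verdict == "within"
    ce_lo, _ = assess_observed(0.0, None, 0.0, 2.2, 1594)
    assert ce_lo.verdict == "below"


# ---------------------------------------------------------------- meta-NCA

def test_meta_nca_synthetic_frontier():
    # records built so that low skew_x and high skew_y cap the outcome:
    # cr <= 0.4 - 0.2 * sx and cr <= 0.1 + 0.2 * sy
    rng = np.random.default_rng(3)
    k = 4000
    sx = rng.uniform(-1.5, 1.5, k)
    sy = rng.uniform(-1.5, 1.5, k)
    cap = np.minimum(0.4 - 0.2 * sx, 0.1 + 0.2 * sy)
    cr = np.clip(cap * rng.uniform(0, 1, k), 1e-4, None)
    rec = make_records(sx, sy, cr, cr, n=rng.choice([50, 200, 800], k))
    res = meta_nca(rec)
    eff = res.effects.set_index(["predictor", "method"])["effect"]
    assert eff[("skew_x", "CE-FDH")] > 0.1
    assert eff[("skew_y", "CE-FDH")] > 0.1
    assert res.bottleneck_skew_x.direction == "at-most"
    assert res.bottleneck_skew_y.direction == "at-least"
    # inverted requirements move the right way: a higher target level
    # demands lower skew_x and higher skew_y
    req_x = res.bottleneck_skew_x.required
    req_y = res.bottleneck_skew_y.required
    assert req_x[2] < req_x[0]
    assert req_y[2] > req_y[0]


def test_meta_nca_drops_missing_cr():
    rng = np.random.default_rng(4)
    k = 500
    sx = rng.uniform(-1, 1, k)
    sy = rng.uniform(-1, 1, k)
    cr = rng.uniform(0.01, 0.5, k)
    rec = make_records(sx, sy, cr, cr, n=rng.choice([50, 200, 800], k))
    rec.loc[:49, "cr"] = np.nan
    res = meta_nca(rec)
    assert np.isfinite(res.effects["effect"].astype(float)).all()
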