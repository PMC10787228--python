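import numpy as np
import pandas as pd
import pytest

from mmbreast import (
    correlation_matrix,
    fdh,
    one_way_anova,
    percentage_difference,
    separation_report,
    two_group_test,
)
from mmbreast.mueller import ElementAverages, MuellerImage
from mmbreast.stats import (
    FDH,
    overlap_coefficient,
    round_half_up,
    significance_stars,
)

from conftest import run_with_retry

# printed percentage differences between healthy and cancer element means
TABLE1 = {
    "m12": 5.4, "m13": 8.2, "m14": 7.4, "m21": 2.7, "m22": 3.4,
    "m23": 70.1, "m24": 7.8, "m31": 21.0, "m32": 60.6, "m33": 10.1,
    "m34": 14.4, "m41": 5.7, "m42": 8.3, "m43": 3.3, "m44": 45.4,
}


def test_percentage_difference_reproduces_all_reported_rows(profiles):
    h = profiles["healthy"]
    c = profiles["grade3"]  # the cancer column of the two-group table
    for element, printed in TABLE1.items():
        got = round_half_up(
            percentage_difference(h.mean_of(element), c.mean_of(element)), 1
        )
        assert got == printed, element
    assert percentage_difference(1.0, 1.0) == 0.0


def test_percentage_difference_symmetric_scale_invariant():
    rng = np.random.default_rng(1)
    for _ in range(50):
        h, c = rng.uniform(0.01, 1.0, 2)
        k = rng.uniform(0.1, 10.0)
        assert percentage_difference(h, c) == pytest.approx(
            percentage_difference(c, h)
        )
        assert percentage_difference(k * h, k * c) == pytest.approx(
            percentage_difference(h, c)
        )
    assert percentage_difference(0.0, 0.0) == 0.0
    with pytest.raises(ValueError):
        percentage_difference(-0.1, 0.5)


def test_identical_groups_t_is_zero_p_is_one():
    a = np.full(10, 0.5)
    res = two_group_test(a, a.copy())
    assert res.statistic == 0.0
    assert res.p_value == 1.0
    assert res.stars == "ns"


def test_degenerate_separation_tiny_p():
    a = np.full(10, 0.2) + np.random.default_rng(0).normal(0, 1e-12, 10)
    b = np.full(10, 0.8) + np.random.default_rng(1).normal(0, 1e-12, 10)
    res = two_group_test(a, b)
    assert res.p_value < 1e-10
    assert res.stars == "****"


def test_paired_variant_requires_equal_n():
    with pytest.raises(ValueError, match="equal group lengths"):
        two_group_test(np.arange(5.0), np.arange(6.0), variant="paired")
    res = two_group_test(
        np.array([1.0, 2, 3, 4]), np.array([1.1, 2.2, 2.9, 4.3]), variant="paired"
    )
    assert res.test == "t-paired"


def test_welch_p_matches_permutation_oracle():
    """Welch two-sided p-value agrees with a 1e5-resample permutation test
    of the same statistic (equal variances, n=20 per group)."""
    rng = np.random.default_rng(42)
    a = rng.normal(0.00, 1.0, 20)
    b = rng.normal(0.55, 1.0, 20)
    res = two_group_test(a, b)

    def welch_t(x, y):
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        return (x.mean() - y.mean()) / np.sqrt(vx + vy)

    pooled = np.concatenate([a, b])
    n_perm = 100_000
    perm_rng = np.random.default_rng(7)
    idx = np.argsort(perm_rng.random((n_perm, pooled.size)), axis=1)
    shuffled = pooled[idx]
    xs, ys = shuffled[:, :20], shuffled[:, 20:]
    vx = xs.var(axis=1, ddof=1) / 20
    vy = ys.var(axis=1, ddof=1) / 20
    t_perm = (xs.mean(axis=1) - ys.mean(axis=1)) / np.sqrt(vx + vy)
    p_perm = (np.abs(t_perm) >= abs(welch_t(a, b)) - 1e-12).mean()
    # MC sd at p ~ 0.1 with 1e5 resamples is ~1e-3; allow permutation-vs-t
    # distributional slack on top
    assert res.p_value == pytest.approx(p_perm, abs=0.01)


def test_two_group_type_I_calibration():
    """Under the null the Welch test rejects at ~alpha (binomial 95% CI,
    2000 replicates; two-stage seeded check)."""
    from scipy.stats import ttest_ind

    def check(seed):
        rng = np.random.default_rng(seed)
        reps, n = 2000, 20
        a = rng.normal(0, 1, (reps, n))
        b = rng.normal(0, 1, (reps, n))
        p = ttest_ind(a, b, axis=1, equal_var=False).pvalue
        rate = (p < 0.05).mean()
        half = 1.96 * np.sqrt(0.05 * 0.95 / reps)
        assert 0.05 - half <= rate <= 0.05 + half

    run_with_retry(check, (11, 12))


def test_anova_two_groups_F_is_t_squared():
    rng = np.random.default_rng(2)
    a, b = rng.normal(0, 1, 15), rng.normal(0.4, 1, 15)
    res = one_way_anova([a, b])
    # classical identity against the pooled-variance t statistic
    from scipy.stats import ttest_ind

    t = ttest_ind(a, b, equal_var=True).statistic
    assert res.statistic == pytest.approx(t**2, rel=1e-10)


def test_anova_power_at_reported_m32_effect_sizes(profiles):
    """With the four reported m32 means/stds and n=20/group, ANOVA p-values
    fall below 1e-4 in >= 99% of replicates (the effects are enormous)."""
    from scipy.stats import f_oneway

    rng = np.random.default_rng(5)
    reps, n = 200, 20
    groups = [
        rng.normal(profiles[c].mean_of("m32"), profiles[c].std_of("m32"), (reps, n))
        for c in ("healthy", "benign", "grade2", "grade3")
    ]
    p = f_oneway(*groups, axis=1).pvalue
    assert (p < 1e-4).mean() >= 0.99


def test_anova_posthoc_table_shape():
    rng = np.random.default_rng(3)
    groups = {c: rng.normal(i * 0.5, 1, 12) for i, c in enumerate("wxyz")}
    res = one_way_anova(groups, element="m32")
    assert len(res.posthoc) == 6  # all pairs of 4 groups
    assert set(res.posthoc.columns) >= {"group_a", "group_b", "p_value", "stars"}
    bon = one_way_anova(groups, element="m32", bonferroni=True)
    assert (bon.posthoc["p_value"] >= res.posthoc["p_value"] - 1e-15).all()


def test_star_bands():
    assert significance_stars(0.5) == "ns"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.002) == "**"
    assert significance_stars(0.00015) == "***"
    assert significance_stars(0.00005) == "****"


def _avg(values, sid="S0", label="healthy"):
    v = np.ones(16)
    v[1:] = values
    return ElementAverages(sample_id=sid, values=v, label=label)


def test_correlation_matrix_against_direct_formula():
    rng = np.random.default_rng(8)
    X = rng.uniform(0, 1, (12, 15))
    samples = [_avg(X[i], sid=f"S{i}") for i in range(12)]
    C = correlation_matrix(samples)
    assert C.shape == (15, 15)
    # textbook covariance-formula oracle
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (len(X) - 1)
    sd = np.sqrt(np.diag(cov))
    expected = cov / np.outer(sd, sd)
    np.testing.assert_allclose(C.to_numpy(), expected, atol=1e-12)
    np.testing.assert_allclose(C.to_numpy(), C.to_numpy().T, atol=1e-15)
    np.testing.assert_allclose(np.diag(C.to_numpy()), 1.0)


def test_correlation_duplicated_column_and_zero_variance():
    rng = np.random.default_rng(9)
    X = rng.uniform(0, 1, (10, 15))
    X[:, 1] = X[:, 0]  # duplicate -> off-diagonal 1
    X[:, 2] = 0.42  # constant -> undefined
    C = correlation_matrix([_avg(X[i], sid=f"S{i}") for i in range(10)])
    assert C.iloc[0, 1] == pytest.approx(1.0)
    assert np.isnan(C.iloc[0, 2])
    assert C.iloc[2, 2] == 1.0
    with pytest.raises(ValueError):
        correlation_matrix([_avg(X[0]), _avg(X[1])])


def _const_image(value, label, shape=(8, 8)):
    el = np.full((16,) + shape, float(value))
    el[0] = 1.0
    return MuellerImage(sample_id="S0", elements=el, normalized=True, label=label)


def test_fdh_constant_image_single_bin():
    h = fdh([_const_image(0.25, "healthy")], "m23", bins=64)
    assert h.counts.sum() == 64  # all pixels counted
    nz = np.nonzero(h.counts)[0]
    assert len(nz) == 1
    left, right = h.bin_edges[nz[0]], h.bin_edges[nz[0] + 1]
    assert left <= 0.25 <= right


def test_fdh_conservation_and_range():
    rng = np.random.default_rng(4)
    el = np.clip(rng.normal(0.3, 0.4, (16, 8, 8)), -2, 2)
    el[0] = 1.0
    img = MuellerImage(sample_id="S0", elements=el, normalized=True, label="x")
    h = fdh([img, img], "m32", bins=32)
    assert h.counts.sum() == 2 * 64  # out-of-range pixels clipped, not lost
    assert h.frequencies.sum() == pytest.approx(1.0)


def test_overlap_coefficient_limits():
    a = fdh([_const_image(-0.5, "a")], "m23")
    b = fdh([_const_image(0.5, "b")], "m23")
    assert overlap_coefficient(a, a) == pytest.approx(1.0)
    assert overlap_coefficient(a, b) == 0.0


def test_separation_report_limits_and_tiebreak():
    same = {
        "m23": {"a": fdh([_const_image(0.1, "a")], "m23"),
                "b": fdh([_const_image(0.1, "b")], "m23")},
        "m32": {"a": fdh([_const_image(-0.4, "a")], "m32"),
                "b": fdh([_const_image(0.4, "b")], "m32")},
    }
    rep = separation_report(same)
    assert rep.iloc[0]["element"] == "m32" and rep.iloc[0]["separation"] == 1.0
    assert rep.iloc[1]["element"] == "m23" and rep.iloc[1]["separation"] == 0.0


def test_fdh_class_overlap_follows_reported_effect_sizes(profiles):
    """Pooled FDHs from the phantom generator: healthy and grade-3 m32
    distributions are nearly disjoint (overlap < 0.1) while their m22
    distributions nearly coincide (asymptotic binned overlap 0.84 at the
    reported means/stds; two-stage seeded check against the 0.8 bound)."""
    from mmbreast import PhantomSpec, generate_sample

    def check(seed):
        spec = PhantomSpec(height=16, width=16, seed=seed)
        imgs = {"healthy": [], "grade3": []}
        for label in imgs:
            for i in range(400):
                t = generate_sample(profiles[label], spec, i, 0)
                imgs[label].append(
                    MuellerImage(sample_id=t.sample_id, elements=t.elements,
                                 normalized=True, label=label)
                )
        m32 = {c: fdh(ims, "m32", label=c) for c, ims in imgs.items()}
        m22 = {c: fdh(ims, "m22", label=c) for c, ims in imgs.items()}
        assert overlap_coefficient(m32["healthy"], m32["grade3"]) < 0.1
        assert overlap_coefficient(m22["healthy"], m22["grade3"]) > 0.8

    run_with_retry(check, (21, 22))
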