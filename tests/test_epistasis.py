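"""Global-epistasis fits, microscopic slope decomposition, classification."""

import numpy as np
import pytest
from sklearn.base import clone

from epiland import (
    AdditiveSpec,
    GlobalEpistasisRegression,
    HoCSpec,
    LandscapeError,
    LatentSpec,
    PairwiseSpec,
    SlopeDecomposer,
    avg_background_effect,
    avg_pairwise_epistasis,
    classify_pattern,
    decompose_report,
    fit_all,
    house_of_cards_summary,
    ols_fit,
    predicted_slope,
    scatter,
    simulate_additive,
    simulate_hoc,
    simulate_latent,
    simulate_pairwise,
    to_walsh,
)

from conftest import random_pairwise_landscape


def brute_force_ols(points: np.ndarray) -> tuple[float, float]:
    """Independent closed-form OLS oracle (normal equations via polyfit)."""
    slope, intercept = np.polyfit(points[:, 0], points[:, 1], 1)
    return float(slope), float(intercept)


# -- scatter ---------------------------------------------------------------


def test_scatter_toy_points(toy):
    pts = scatter(toy, "m1")
    assert sorted(map(tuple, pts.round(12))) == [(1.0, 0.2), (1.1, 0.3)]


def test_scatter_counts_and_flatness():
    ls = simulate_hoc(HoCSpec(tuple("abcdef"), seed=2))
    assert all(scatter(ls, n).shape == (32, 2) for n in ls.locus_names)
    effects = (0.3, 0.2, 0.1, -0.1, -0.2, -0.3)
    add = simulate_additive(AdditiveSpec(tuple("abcdef"), 1.0, effects))
    for k, name in enumerate(add.locus_names):
        np.testing.assert_allclose(scatter(add, name)[:, 1], effects[k])


# -- OLS -------------------------------------------------------------------


def test_ols_exact_line():
    x = np.linspace(0.5, 2.0, 8)
    fit = ols_fit(np.column_stack([x, 0.35 * x]))
    assert fit.slope == pytest.approx(0.35)
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.p_value < 1e-9


def test_ols_constant_response_degenerate():
    x = np.array([1.0, 1.2, 1.5, 2.0])
    fit = ols_fit(np.column_stack([x, np.full(4, 0.3)]))
    assert fit.slope == 0.0 and fit.r_squared == 0.0 and fit.degenerate
    assert classify_pattern(fit) == "flat"


def test_ols_zero_x_variance_flagged_not_crash():
    pts = np.column_stack([np.ones(5), np.arange(5.0)])
    fit = ols_fit(pts)
    assert fit.degenerate and np.isnan(fit.slope)
    assert classify_pattern(fit) == "flat"


def test_ols_requires_three_points():
    with pytest.raises(ValueError, match="3 points"):
        ols_fit(np.array([[1.0, 0.1], [1.2, 0.2]]))


def test_ols_matches_independent_oracle():
    rng = np.random.default_rng(0)
    pts = np.column_stack([rng.normal(1, 0.4, 30), rng.normal(0, 0.2, 30)])
    fit = ols_fit(pts)
    slope, intercept = brute_force_ols(pts)
    assert fit.slope == pytest.approx(slope, abs=1e-10)
    assert fit.intercept == pytest.approx(intercept, abs=1e-10)
    r = np.corrcoef(pts[:, 0], pts[:, 1])[0, 1]
    assert fit.r_squared == pytest.approx(r**2, abs=1e-12)


# -- background-averaged quantities ---------------------------------------


def test_avg_effect_additive_mutation():
    ls = simulate_pairwise(
        PairwiseSpec(tuple("abcd"), 1.0, (0.2, 0.3, -0.1, 0.4), {("a", "c"): 0.15})
    )
    # b interacts with nothing: its average effect is δ_b for any focal
    for focal in ("a", "c", "d"):
        value, n = avg_background_effect(ls, "b", focal)
        assert value == pytest.approx(0.3)
        assert n == 4


def test_avg_effect_matches_walsh_identity():
    rng = np.random.default_rng(11)
    ls = random_pairwise_landscape(rng, 5)
    e = to_walsh(ls)
    for focal in ls.locus_names:
        for j in ls.locus_names:
            if j == focal:
                continue
            value, n = avg_background_effect(ls, j, focal)
            f_j = e.coefficient(j)
            f_ij = e.coefficient(focal, j)
            assert value == pytest.approx(2 * (f_j - f_ij), abs=1e-10)
            assert n == 2 ** (ls.n_loci - 2)


def test_avg_effect_single_interaction_is_delta2(worked_n3):
    # mutation 2 is purely additive on backgrounds lacking mutation 1
    value, _ = avg_background_effect(worked_n3, "m2", "m1")
    assert value == pytest.approx(0.3, abs=1e-12)


def test_avg_pairwise_epistasis_values(toy, worked_n3):
    assert avg_pairwise_epistasis(toy, "m1", "m2") == (pytest.approx(0.1), 1)
    assert avg_pairwise_epistasis(worked_n3, "m1", "m2")[0] == pytest.approx(0.12)
    add = simulate_additive(AdditiveSpec(tuple("abc"), 1.0, (0.1, 0.2, 0.3)))
    assert avg_pairwise_epistasis(add, "a", "b")[0] == pytest.approx(0.0, abs=1e-12)


def test_avg_pairwise_matches_walsh_identity():
    rng = np.random.default_rng(13)
    ls = random_pairwise_landscape(rng, 6)
    e = to_walsh(ls)
    for i in range(3):
        for j in range(i + 1, 6):
            value, _ = avg_pairwise_epistasis(ls, i, j)
            assert value == pytest.approx(4 * e.coefficient(i, j), abs=1e-10)


# -- predicted slope / decomposition ---------------------------------------


def test_worked_example_prediction_equals_ols(worked_n3):
    """Focal-only interaction: microscopic prediction is exact.

    δ = (0.5, 0.3, 0.2), ε₁₂ = 0.12 → slope = ε₁₂δ₂/(δ₂²+δ₃²) = 0.036/0.13.
    """
    pts = scatter(worked_n3, "m1")
    ols_slope, ols_intercept = brute_force_ols(pts)
    assert ols_slope == pytest.approx(0.036 / 0.13, abs=1e-12)
    d = predicted_slope(worked_n3, "m1")
    assert d.predicted_slope == pytest.approx(ols_slope, abs=1e-12)
    assert d.predicted_intercept == pytest.approx(ols_intercept, abs=1e-12)


def test_focal_only_interactions_exact_at_machine_precision():
    """No background–background epistasis → prediction equals OLS exactly."""
    rng = np.random.default_rng(23)
    for trial in range(10):
        n = int(rng.integers(3, 7))
        names = tuple(f"m{k + 1}" for k in range(n))
        interactions = {
            (names[0], names[j]): float(rng.normal(0, 0.3))
            for j in range(1, n)
        }
        ls = simulate_pairwise(
            PairwiseSpec(names, 1.0, tuple(rng.normal(0, 0.5, n)), interactions)
        )
        d = predicted_slope(ls, names[0])
        fit = ols_fit(scatter(ls, names[0]))
        assert d.predicted_slope == pytest.approx(fit.slope, abs=1e-12)
        assert d.predicted_intercept == pytest.approx(fit.intercept, abs=1e-12)


def test_additive_prediction_zero():
    ls = simulate_additive(AdditiveSpec(tuple("abcd"), 1.0, (0.3, 0.2, -0.1, 0.4)))
    for name in ls.locus_names:
        d = predicted_slope(ls, name)
        assert d.predicted_slope == pytest.approx(0.0, abs=1e-12)
        assert all(t.product == pytest.approx(0.0, abs=1e-12) for t in d.partners)


def test_modes_agree_on_pairwise_landscapes():
    rng = np.random.default_rng(31)
    for trial in range(5):
        ls = random_pairwise_landscape(rng, int(rng.integers(4, 7)))
        for name in ls.locus_names:
            da = predicted_slope(ls, name, mode="averages")
            dw = predicted_slope(ls, name, mode="walsh")
            assert da.predicted_slope == pytest.approx(dw.predicted_slope, abs=1e-9)
            for ta, tw in zip(da.partners, tw_sorted(dw.partners)):
                assert ta.avg_epistasis == pytest.approx(tw.avg_epistasis, abs=1e-9)
                assert ta.avg_effect == pytest.approx(tw.avg_effect, abs=1e-9)


def tw_sorted(partners):
    return partners  # both modes enumerate partners in locus order


def test_omega_normalisation():
    rng = np.random.default_rng(41)
    ls = random_pairwise_landscape(rng, 5)
    for name in ls.locus_names:
        d = predicted_slope(ls, name)
        assert sum(t.omega for t in d.partners) == pytest.approx(1.0)


def test_sign_rule_all_positive_products():
    names = tuple("abcd")
    interactions = {("a", j): 0.1 for j in "bcd"}
    ls = simulate_pairwise(PairwiseSpec(names, 1.0, (0.2, 0.3, 0.25, 0.4), interactions))
    d = predicted_slope(ls, "a")
    assert all(t.product > 0 for t in d.partners)
    assert d.predicted_slope > 0


def test_dominant_negative_product_flips_slope():
    names = tuple("abcde")
    interactions = {("a", "b"): -0.4, ("a", "c"): 0.05, ("a", "d"): 0.05, ("a", "e"): 0.05}
    ls = simulate_pairwise(
        PairwiseSpec(names, 1.0, (0.2, 0.5, 0.2, 0.2, 0.2), interactions)
    )
    d = predicted_slope(ls, "a")
    products = sorted(t.product for t in d.partners)
    assert products[0] < 0 < products[-1]
    assert d.predicted_slope < 0
    assert ols_fit(scatter(ls, "a")).slope < 0


def test_partner_with_zero_effect_keeps_sum_defined():
    # mutation b has δ_b = 0 and interacts with nothing except focal a
    ls = simulate_pairwise(
        PairwiseSpec(tuple("abc"), 1.0, (0.2, 0.0, 0.3), {("a", "b"): 0.1})
    )
    d = predicted_slope(ls, "a")
    by_name = {t.partner: t for t in d.partners}
    assert np.isnan(by_name["b"].beta)
    assert by_name["b"].omega == 0.0
    assert by_name["b"].product == pytest.approx(0.0, abs=1e-12)
    assert np.isfinite(d.predicted_slope)


def test_all_effects_zero_is_degenerate():
    ls = simulate_pairwise(
        PairwiseSpec(tuple("abc"), 1.0, (0.3, 0.0, 0.0), {("a", "b"): 0.1})
    )
    d = predicted_slope(ls, "a")
    assert d.degenerate and np.isnan(d.predicted_slope)


def test_prediction_converges_as_interactions_shrink():
    """Background–background epistasis breaks exactness; error → 0 with ε."""
    rng = np.random.default_rng(53)
    names = tuple(f"m{k}" for k in range(5))
    effects = tuple(rng.normal(0, 0.5, 5))
    base_interactions = {
        (names[i], names[j]): float(rng.normal(0, 1.0))
        for i in range(5)
        for j in range(i + 1, 5)
    }
    errors = []
    for scale in (0.3, 0.03, 0.003):
        interactions = {k: scale * v for k, v in base_interactions.items()}
        ls = simulate_pairwise(PairwiseSpec(names, 1.0, effects, interactions))
        rep = decompose_report(ls, names[0])
        errors.append(abs(rep.decomposition.predicted_slope - rep.fit.slope))
    assert errors[0] > errors[1] > errors[2]
    assert errors[2] < 1e-3


def test_decompose_report_joint_record(worked_n3):
    rep = decompose_report(worked_n3, "m1")
    assert rep.fit.slope == pytest.approx(rep.decomposition.predicted_slope, abs=1e-12)
    assert {t.partner for t in rep.decomposition.partners} == {"m2", "m3"}


# -- classification --------------------------------------------------------


@pytest.mark.parametrize(
    "transform, effect, label",
    [
        ("concave", 0.4, "diminishing returns"),
        ("concave", -0.4, "decreasing costs"),
        ("convex", 0.4, "increasing returns"),
        ("convex", -0.4, "increasing costs"),
    ],
)
def test_latent_classifications(transform, effect, label):
    names = tuple("abcd")
    effects = (effect, 0.3, -0.25, 0.2)
    ls = simulate_latent(LatentSpec(names, 0.2, effects, transform=transform))
    fit = ols_fit(scatter(ls, "a"), focal="a")
    assert classify_pattern(fit) == label


def test_additive_classified_flat():
    ls = simulate_additive(AdditiveSpec(tuple("abcd"), 1.0, (0.3, 0.2, -0.1, 0.4)))
    for fit, label in fit_all(ls):
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert label == "flat"


def test_mixed_sign_label():
    # concave latent landscape: mutation with δλ>0 has ΔF>0 everywhere;
    # engineering a mixed-sign ΔF needs sign epistasis — use a HoC draw
    ls = simulate_hoc(HoCSpec(tuple("abcdef"), seed=5))
    labels = {classify_pattern(f, alpha=0.2) for f, _ in
              ((ols_fit(scatter(ls, n), focal=n), n) for n in ls.locus_names)}
    assert labels <= {"mixed-sign", "flat"}
    assert "mixed-sign" in labels


# -- regression to the mean -------------------------------------------------


def test_house_of_cards_summary_small():
    s = house_of_cards_summary(n_replicates=60, seed=123)
    assert s["n_fits"] == 360
    assert s["slope"] == pytest.approx(-1.0, abs=0.1)
    assert s["r_squared"] == pytest.approx(0.5, abs=0.1)
    assert s["intercept"] == pytest.approx(1.0, abs=0.1)


# -- estimator interfaces ---------------------------------------------------


class TestEstimators:
    def test_global_epistasis_regression(self, worked_n3):
        est = GlobalEpistasisRegression(alpha=0.05)
        est.fit(worked_n3.genotypes, worked_n3.fitness)
        assert est.slopes_.shape == (3,)
        assert est.slopes_[0] == pytest.approx(0.036 / 0.13, abs=1e-12)
        assert est.labels_[2] == "flat"  # m3 is purely additive
        assert clone(est).get_params() == {"alpha": 0.05}

    def test_slope_decomposer(self, worked_n3):
        est = SlopeDecomposer(mode="averages").fit(
            worked_n3.genotypes, worked_n3.fitness
        )
        np.testing.assert_allclose(est.predicted_slopes_, est.ols_slopes_, atol=1e-12)
        assert clone(est).get_params() == {"mode": "averages"}
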