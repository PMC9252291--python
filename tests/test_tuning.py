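import numpy as np
import pytest

from numsense import tuning
from numsense.tuning import (
    NUMEROSITIES,
    SCALES,
    fit_gaussian_on_scale,
    fit_unit_curves,
    mean_r_square,
    mean_r_square_by_preference,
    mean_tuning_curves,
    pool_curves,
    preference_distribution,
    preferred_numerosities,
    r_square,
    sigma_slope,
)


def gaussian(x, a, mu, sd):
    return a * np.exp(-((x - mu) ** 2) / (2 * sd**2))


def test_single_repeat_curves_equal_raw_responses(rng):
    responses = rng.random((1, 10, 30))
    curves = mean_tuning_curves(responses, output_shape=(10,))
    for u, c in enumerate(curves):
        assert np.array_equal(c.mean_response, responses[0, u])


def test_opposite_repeats_average_to_zero(rng):
    r = rng.normal(size=(1, 6, 30))
    curves = mean_tuning_curves(np.concatenate([r, -r]), output_shape=(6,))
    for c in curves:
        assert np.allclose(c.mean_response, 0.0)


def test_constant_curve_prefers_smallest_numerosity():
    curves = mean_tuning_curves(np.ones((1, 3, 30)), output_shape=(3,))
    assert all(c.preferred_numerosity == 1 for c in curves)


def test_preference_invariant_under_reversed_numerosity_order(rng):
    responses = rng.random((2, 20, 30))
    mean = responses.mean(axis=0)
    fwd = preferred_numerosities(mean)
    rev = 31 - preferred_numerosities(mean[:, ::-1])
    ties = np.array([(m == m.max()).sum() > 1 for m in mean])
    assert np.array_equal(fwd[~ties], rev[~ties])


def test_missing_numerosities_rejected(rng):
    with pytest.raises(ValueError):
        mean_tuning_curves(rng.random((2, 5, 29)))


def test_distribution_all_units_prefer_one():
    responses = np.zeros((3, 8, 30))
    responses[:, :, 0] = 1.0
    dist = preference_distribution(responses)
    assert dist[0] == 1.0 and np.all(dist[1:] == 0.0)


def test_distribution_uniform_for_uniform_preferences():
    responses = np.zeros((2, 30, 30))
    for u in range(30):
        responses[:, u, u] = 1.0
    dist = preference_distribution(responses)
    assert np.allclose(dist, 1 / 30)


def test_distribution_sums_to_one(rng):
    dist = preference_distribution(rng.random((5, 400, 30)))
    assert dist.sum() == pytest.approx(1.0, abs=1e-12)


def test_pool_single_unit_returns_own_normalized_curve(rng):
    curves = mean_tuning_curves(rng.random((1, 1, 30)), output_shape=(1,))
    pooled = pool_curves(curves, curves[0].preferred_numerosity)
    raw = curves[0].mean_response
    expected = (raw - raw.min()) / (raw.max() - raw.min())
    assert np.allclose(pooled.response, expected)
    assert pooled.unit_count == 1
    assert pooled.response.max() == pytest.approx(1.0)


def test_pool_identical_units_unchanged(rng):
    base = rng.random(30)
    responses = np.stack([base, base])[None]
    curves = mean_tuning_curves(responses, output_shape=(2,))
    pooled = pool_curves(curves, curves[0].preferred_numerosity)
    assert pooled.unit_count == 2
    expected = (base - base.min()) / (base.max() - base.min())
    assert np.allclose(pooled.response, expected)


def test_empty_pool_is_flagged_absent(rng):
    curves = mean_tuning_curves(np.ones((1, 2, 30)), output_shape=(2,))
    pooled = pool_curves(curves, 17)
    assert pooled.absent and pooled.response is None
    fit = fit_gaussian_on_scale(pooled, "linear")
    assert not fit.converged


@pytest.mark.parametrize("scale_id", ["linear", "sqrt", "cuberoot", "log2"])
def test_exact_gaussian_is_recovered(scale_id):
    x = SCALES[scale_id](NUMEROSITIES)
    true = (0.9, float(x[12]), 0.35 * (x[-1] - x[0]))
    fit = fit_gaussian_on_scale(gaussian(x, *true), scale_id, 13)
    assert fit.converged
    assert fit.amplitude == pytest.approx(true[0], abs=1e-6)
    assert fit.center == pytest.approx(true[1], abs=1e-6)
    assert fit.sigma == pytest.approx(true[2], abs=1e-6)
    assert fit.r_square == pytest.approx(1.0, abs=1e-9)


def test_constant_curve_has_zero_r_square():
    fit = fit_gaussian_on_scale(np.full(30, 0.4), "linear", 1)
    assert fit.r_square == pytest.approx(0.0, abs=1e-6)


@pytest.mark.parametrize("scale_id", ["linear", "log2"])
def test_gaussian_center_recovery_under_noise(scale_id):
    """Center recovered within 0.5 transformed units at noise sd 0.05."""
    x = SCALES[scale_id](NUMEROSITIES)
    rng = np.random.default_rng(2024)
    span = x[-1] - x[0]
    errors = []
    for _ in range(100):
        mu = rng.uniform(x[3], x[-4])
        sd = rng.uniform(0.05, 0.2) * span
        y = gaussian(x, 1.0, mu, sd) + rng.normal(0, 0.05, size=30)
        pref = int(NUMEROSITIES[np.argmax(y)])
        fit = fit_gaussian_on_scale(y, scale_id, pref)
        assert fit.converged
        errors.append(abs(fit.center - mu))
    assert max(errors) <= 0.5


def test_sigma_slope_flat_and_exact_line():
    fits = [
        tuning.GaussianFitResult("linear", p, 1.0, p, 2.0, 0.9, True)
        for p in (1, 5, 9, 20)
    ]
    assert sigma_slope(fits) == pytest.approx(0.0)
    fits = [
        tuning.GaussianFitResult("linear", p, 1.0, p, 0.5 * p, 0.9, True)
        for p in (1, 4, 8, 30)
    ]
    assert sigma_slope(fits) == pytest.approx(0.5)


def test_sigma_slope_needs_two_converged_fits():
    fit = tuning.GaussianFitResult("linear", 3, 1.0, 3.0, 1.0, 0.8, True)
    with pytest.raises(ValueError):
        sigma_slope([fit, tuning.GaussianFitResult("linear", 5)])


def test_r_square_definition_and_clipping():
    y = np.array([0.0, 1.0, 0.0])
    assert r_square(y, np.full(3, y.mean())) == 0.0
    assert r_square(y, y) == pytest.approx(1.0)
    assert r_square(np.full(3, 0.5), np.full(3, 0.5)) == 0.0  # flat target
    wild = np.array([5.0, -5.0, 5.0])
    assert r_square(y, wild) == 1.0  # over-dispersed fit clipped


def test_unit_fit_helpers_skip_flat_units(rng):
    flat = np.zeros((1, 1, 30))
    bumpy = rng.random((1, 1, 30))
    curves = mean_tuning_curves(np.concatenate([flat, bumpy], axis=1),
                                output_shape=(2,))
    fits = fit_unit_curves(curves, "linear")
    assert len(fits) == 1
    assert np.isfinite(mean_r_square(fits))
    assert np.isfinite(mean_r_square_by_preference(fits))
    assert np.isnan(mean_r_square_by_preference([]))
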