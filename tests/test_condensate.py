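"""Clustering-statistic oracles: SCI, signal variance, classification,
and the variance-mixture EM fitter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cophase.condensate import (
    ASSEMBLY_CLASSES,
    LineProfile,
    NucleusImage,
    classify_assembly,
    extract_line_profile,
    fit_variance_mixture,
    max_project,
    nucleus_signal_variance,
    population_fractions,
    spatial_clustering_index,
)


# ---------------------------------------------------------------------------
# max projection


def test_max_project_single_plane_is_identity():
    img = NucleusImage(np.arange(16.0).reshape(4, 4))
    out = max_project([img])
    np.testing.assert_array_equal(out.intensities, img.intensities)


def test_max_project_takes_pixelwise_maximum():
    a = np.zeros((4, 4))
    b = np.zeros((4, 4))
    a[0, 0] = 5.0
    b[3, 3] = 7.0
    out = max_project([a, b, np.zeros((4, 4))])
    assert out.intensities[0, 0] == 5.0
    assert out.intensities[3, 3] == 7.0
    assert out.intensities.sum() == 12.0


def test_max_project_shape_mismatch_errors():
    with pytest.raises(ValueError):
        max_project([np.zeros((4, 4)), np.zeros((5, 5))])


# ---------------------------------------------------------------------------
# spatial clustering index


@pytest.mark.parametrize(
    "values, expected",
    [
        # constant profile: top and bottom tails identical
        (np.full(40, 7.0), 1.0),
        # 100 values: five at 50, five at 10, rest 20 -> 50/10
        (np.r_[np.full(5, 50.0), np.full(5, 10.0), np.full(90, 20.0)], 5.0),
        # 20 values: single-element tails, max 40 / min 4
        (np.r_[40.0, 4.0, np.full(18, 20.0)], 10.0),
    ],
)
def test_sci_matches_sort_and_average_oracle(values, expected):
    assert spatial_clustering_index(LineProfile(values)) == pytest.approx(expected)


def test_sci_brute_force_oracle_random_profile():
    rng = np.random.default_rng(42)
    values = rng.uniform(1, 100, 200)
    k = int(np.floor(0.05 * 200))
    srt = np.sort(values)
    expected = srt[-k:].mean() / srt[:k].mean()
    assert spatial_clustering_index(LineProfile(values)) == pytest.approx(expected)


def test_sci_zero_background_errors():
    vals = np.r_[np.zeros(2), np.full(38, 5.0)]
    with pytest.raises(ValueError, match="degenerate background"):
        spatial_clustering_index(LineProfile(vals))


def test_sci_too_short_profile_errors():
    with pytest.raises(ValueError):
        spatial_clustering_index(np.ones(10), tail_fraction=0.05)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(min_value=1.0, max_value=1e3), min_size=25, max_size=200),
    st.floats(min_value=0.1, max_value=1e3),
)
def test_sci_scale_invariant_and_shift_toward_one(values, c):
    profile = np.asarray(values)
    sci = spatial_clustering_index(LineProfile(profile))
    assert sci >= 1.0
    scaled = spatial_clustering_index(LineProfile(c * profile))
    assert scaled == pytest.approx(sci, rel=1e-9)
    shifted = spatial_clustering_index(LineProfile(profile + c))
    assert 1.0 - 1e-12 <= shifted <= sci + 1e-12


def test_extract_line_profile_reads_constant_stripe():
    img = NucleusImage(np.full((40, 40), 3.0), pixel_size=0.1)
    prof = extract_line_profile(img, (5, 20), (34, 20), width_um=0.3)
    assert prof.values.size >= 20
    np.testing.assert_allclose(prof.values, 3.0)


# ---------------------------------------------------------------------------
# signal variance


def _masked_image(values, pad=10):
    """Embed a foreground patch on a dark background for thresholding."""
    patch = np.asarray(values, dtype=float)
    img = np.zeros((patch.shape[0] + 2 * pad, patch.shape[1] + 2 * pad))
    img[pad:-pad, pad:-pad] = patch
    return NucleusImage(img)


def test_variance_zero_for_constant_foreground():
    img = _masked_image(np.full((10, 10), 50.0))
    var, fg = nucleus_signal_variance(img)
    assert var == pytest.approx(0.0, abs=1e-12)
    assert fg.sum() == 100


def test_variance_direct_formula_two_level_foreground():
    # foreground pixels half at 100, half at 300: mean 200, pop SD 100
    patch = np.full((10, 10), 100.0)
    patch[:, 5:] = 300.0
    var, _ = nucleus_signal_variance(_masked_image(patch))
    assert var == pytest.approx((100.0 / 200.0) ** 2, rel=1e-9)


def test_variance_formula_on_small_multiset_whole_mode():
    # foreground multiset {1, 3}: pop SD 1, mean 2 -> (1/2)^2
    img = NucleusImage(
        np.array([[1.0, 3.0], [0.0, 0.0]]),
        mask=np.array([[True, True], [False, False]]),
    )
    var, _ = nucleus_signal_variance(img, mode="whole", min_foreground_px=1)
    assert var == pytest.approx(0.25, rel=1e-12)


def test_variance_scale_invariance():
    rng = np.random.default_rng(0)
    patch = rng.uniform(50, 150, (12, 12))
    v1, _ = nucleus_signal_variance(_masked_image(patch))
    v2, _ = nucleus_signal_variance(_masked_image(3.7 * patch))
    assert v2 == pytest.approx(v1, rel=1e-6)


def test_variance_empty_foreground_errors():
    img = NucleusImage(np.full((20, 20), 5.0))  # constant: no split
    with pytest.raises(ValueError):
        nucleus_signal_variance(img)


# ---------------------------------------------------------------------------
# classification


@pytest.mark.parametrize(
    "variance, expected",
    [
        (0.10, "diffuse"),
        (0.30, "spherical"),
        (0.60, "aggregate"),
        (0.21, "spherical"),  # closed lower boundary of the middle bin
        (0.45, "spherical"),  # closed upper boundary
        (0.209999, "diffuse"),
        (0.450001, "aggregate"),
    ],
)
def test_classification_thresholds_exact(variance, expected):
    assert classify_assembly(variance).assembly_class == expected


def test_classification_rejects_negative_variance():
    with pytest.raises(ValueError):
        classify_assembly(-0.1)


def test_population_fractions_tally():
    cls = [classify_assembly(v) for v in (0.1, 0.3, 0.6)]
    fractions, counts = population_fractions(cls)
    np.testing.assert_allclose(fractions, [1 / 3, 1 / 3, 1 / 3])
    assert counts.tolist() == [1, 1, 1]
    fr_all, _ = population_fractions([classify_assembly(0.05)] * 4)
    np.testing.assert_allclose(fr_all, [1.0, 0.0, 0.0])
    with pytest.raises(ValueError):
        population_fractions([])


# ---------------------------------------------------------------------------
# variance mixture


def test_mixture_k1_closed_form():
    rng = np.random.default_rng(3)
    x = rng.normal(0.3, 0.05, 400)
    fit = fit_variance_mixture(x, k=1)
    assert fit.means[0] == pytest.approx(x.mean(), rel=1e-12)
    assert fit.sds[0] == pytest.approx(x.std(ddof=0), rel=1e-12)
    assert fit.weights[0] == 1.0


def test_mixture_recovers_three_separated_components():
    rng = np.random.default_rng(11)
    weights = (0.2, 0.3, 0.5)
    means = (0.05, 0.35, 0.80)
    sds = (0.02, 0.04, 0.05)
    parts = [
        rng.normal(m, s, int(w * 3000)) for w, m, s in zip(weights, means, sds)
    ]
    x = np.concatenate(parts)
    fit = fit_variance_mixture(x, k=3, seed=5)
    assert fit.converged
    np.testing.assert_allclose(fit.weights, weights, atol=0.03)
    np.testing.assert_allclose(fit.means, means, atol=0.02)
    assert np.all(np.diff(fit.means) > 0)
    assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)
    # boundaries sit between adjacent means
    for b, lo, hi in zip(fit.boundaries, fit.means[:-1], fit.means[1:]):
        assert lo < b < hi


def test_mixture_log_likelihood_nondecreasing():
    rng = np.random.default_rng(7)
    x = np.concatenate([rng.normal(0.1, 0.03, 300), rng.normal(0.6, 0.08, 300)])
    fit = fit_variance_mixture(x, k=2, seed=2)
    diffs = np.diff(fit.ll_trace)
    assert np.all(diffs >= -1e-7 * np.abs(fit.ll_trace[:-1]))


def test_mixture_agrees_with_sklearn_reference():
    sklearn = pytest.importorskip("sklearn.mixture")
    rng = np.random.default_rng(19)
    x = np.concatenate([rng.normal(0.1, 0.03, 500), rng.normal(0.7, 0.1, 500)])
    fit = fit_variance_mixture(x, k=2, seed=0)
    gm = sklearn.GaussianMixture(2, random_state=0, n_init=5).fit(x[:, None])
    order = np.argsort(gm.means_.ravel())
    np.testing.assert_allclose(fit.means, gm.means_.ravel()[order], atol=0.01)
    np.testing.assert_allclose(fit.weights, gm.weights_[order], atol=0.02)


def test_mixture_identical_components_flagged_degenerate():
    rng = np.random.default_rng(23)
    x = rng.normal(0.4, 0.05, 600)  # one true component, fit with two
    fit = fit_variance_mixture(x, k=2, seed=1)
    # both components collapse onto the single mode
    assert fit.degenerate or abs(fit.means[1] - fit.means[0]) < 0.05


def test_mixture_requires_enough_observations():
    with pytest.raises(ValueError):
        fit_variance_mixture(np.ones(10), k=3)
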