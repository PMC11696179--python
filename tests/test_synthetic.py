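"""Generator contracts: determinism, conservation, closed-form traces,
and calibration of the nucleus classes against the variance classifier."""

import numpy as np
import pytest

from cophase.condensate import classify_assembly, nucleus_signal_variance
from cophase.spr import BivalentParams, simulate_series
from cophase.synthetic import (
    SyntheticFrapSpec,
    SyntheticNucleusSpec,
    SyntheticSensorgramSpec,
    make_frap_trace,
    make_nucleus_image,
    make_nucleus_population,
    make_particle_field,
    make_sensorgram_set,
)


# ---------------------------------------------------------------------------
# nuclei


def test_nucleus_image_bit_identical_for_same_seed():
    spec = SyntheticNucleusSpec(assembly_class="spherical", seed=123)
    a, _ = make_nucleus_image(spec)
    b, _ = make_nucleus_image(spec)
    np.testing.assert_array_equal(a.intensities, b.intensities)
    np.testing.assert_array_equal(a.mask, b.mask)


@pytest.mark.parametrize("cls, lo, hi", [
    ("diffuse", 0.0, 0.21),
    ("spherical", 0.21, 0.45),
    ("aggregate", 0.45, np.inf),
])
def test_single_seed_lands_in_class_bin(cls, lo, hi):
    img, _ = make_nucleus_image(SyntheticNucleusSpec(assembly_class=cls, seed=1))
    var, _ = nucleus_signal_variance(img)
    assert lo <= var <= hi or (cls == "diffuse" and var < lo) or (cls == "aggregate" and var > 0.45)
    assert classify_assembly(var).assembly_class == cls


def test_nucleus_spec_validation():
    with pytest.raises(ValueError):
        SyntheticNucleusSpec(assembly_class="diffuse", focus_count=3)
    with pytest.raises(ValueError):
        SyntheticNucleusSpec(assembly_class="blobby")
    with pytest.raises(ValueError):
        SyntheticNucleusSpec(assembly_class="spherical", mean_intensity=0.0)
    # too many foci for a tiny image
    with pytest.raises(ValueError):
        make_nucleus_image(
            SyntheticNucleusSpec(assembly_class="spherical", image_size=24, focus_count=30)
        )


def test_population_counts_and_degenerate_weights():
    pop = make_nucleus_population((1.0, 0.0, 0.0), n=10, seed=0)
    assert len(pop) == 10
    assert all(lab == "diffuse" for _, lab in pop)

    pop = make_nucleus_population((0.16, 0.36, 0.48), n=75, seed=4)
    assert len(pop) == 75

    with pytest.raises(ValueError):
        make_nucleus_population((-0.1, 0.6, 0.5), n=5)
    with pytest.raises(ValueError):
        make_nucleus_population((0.5, 0.5, 0.0), n=0)


def test_population_fractions_converge_to_weights():
    weights = np.array([0.16, 0.36, 0.48])
    rng_labels = [lab for _, lab in make_nucleus_population(weights, n=600, seed=9)]
    fracs = np.array(
        [rng_labels.count(c) / 600 for c in ("diffuse", "spherical", "aggregate")]
    )
    np.testing.assert_allclose(fracs, weights, atol=0.06)


# ---------------------------------------------------------------------------
# FRAP traces


def test_frap_trace_matches_closed_form_noiseless():
    spec = SyntheticFrapSpec(plateau=0.8, rate=0.1, acquisition_bleach_rate=0.0, noise_sd=0.0)
    trace, truth = make_frap_trace(spec)
    t = trace.times
    post = t >= t[trace.bleach_frame_index]
    expected = 0.8 * (1 - np.exp(-0.1 * (t[post] - t[trace.bleach_frame_index])))
    np.testing.assert_allclose(trace.bleach_roi[post], expected, atol=1e-12)
    np.testing.assert_allclose(trace.bleach_roi[: trace.prebleach_frames], 1.0)


def test_frap_trace_no_recovery_stays_at_bleach_depth():
    spec = SyntheticFrapSpec(plateau=0.0, rate=0.1, noise_sd=0.0)
    trace, _ = make_frap_trace(spec)
    post = trace.times >= trace.times[trace.bleach_frame_index]
    np.testing.assert_allclose(trace.bleach_roi[post], 0.0, atol=1e-15)


def test_frap_reference_carries_acquisition_bleaching():
    spec = SyntheticFrapSpec(
        plateau=0.5, rate=0.05, acquisition_bleach_rate=0.01, noise_sd=0.0,
        frame_interval=1.0, duration=100.0,
    )
    trace, _ = make_frap_trace(spec)
    # at t = 100 s the reference has decayed to e^-1 of its initial value
    assert trace.reference_roi[-1] == pytest.approx(np.exp(-1.0), rel=1e-12)


def test_frap_spec_validation():
    with pytest.raises(ValueError):
        SyntheticFrapSpec(plateau=1.2)
    with pytest.raises(ValueError):
        SyntheticFrapSpec(duration=-5)
    with pytest.raises(ValueError):
        SyntheticFrapSpec(prebleach_frames=0)


# ---------------------------------------------------------------------------
# sensorgrams


def _spec(**kw):
    params = BivalentParams(ka1=2e5, kd1=1e-2, ka2=1e-4, kd2=1e-3, rmax=120.0)
    kw.setdefault("params", params)
    return SyntheticSensorgramSpec(**kw)


def test_sensorgram_concentrations_geometric_series():
    spec = _spec(top_concentration=256e-9, dilution_factor=2.0, n_dilutions=6)
    np.testing.assert_allclose(
        spec.concentrations, np.array([256, 128, 64, 32, 16, 8]) * 1e-9
    )
    assert np.all(np.diff(spec.concentrations) < 0)


def test_noiseless_set_equals_forward_simulation():
    spec = _spec(n_dilutions=3)
    grams, truth = make_sensorgram_set(spec)
    sims = simulate_series(truth, spec.concentrations)
    for g, s in zip(grams, sims):
        np.testing.assert_allclose(g.response, s.response, atol=1e-12)


def test_sensorgram_langmuir_limit_equilibrium():
    # no second-site step: association plateau is the 1:1 Langmuir isotherm
    params = BivalentParams(ka1=1e6, kd1=1e-2, ka2=0.0, kd2=0.0, rmax=100.0)
    spec = SyntheticSensorgramSpec(
        params=params, top_concentration=1e-7, n_dilutions=4,
        association_time=2000.0, dissociation_time=10.0,
    )
    grams, _ = make_sensorgram_set(spec)
    kd = 1e-2 / 1e6
    for g in grams:
        c = g.analyte_concentration
        eq = 100.0 * c / (c + kd)
        assoc_end = g.response[g.times <= g.phase_boundary][-1]
        assert assoc_end == pytest.approx(eq, rel=1e-4)


def test_sensorgram_spec_validation():
    with pytest.raises(ValueError):
        _spec(top_concentration=-1e-9)
    with pytest.raises(ValueError):
        _spec(dilution_factor=1.0)
    with pytest.raises(ValueError):
        _spec(n_dilutions=0)


# ---------------------------------------------------------------------------
# particle fields


def test_particle_field_empty_and_deterministic():
    img0, truth0 = make_particle_field(0, seed=3)
    assert truth0.empty
    np.testing.assert_allclose(img0, 10.0)

    a, ta = make_particle_field(12, seed=5)
    b, tb = make_particle_field(12, seed=5)
    np.testing.assert_array_equal(a, b)
    np.testing.assert_array_equal(ta["x"], tb["x"])


def test_particle_field_intensity_conservation():
    img, truth = make_particle_field(
        5, intensity_mean=3000.0, image_size=128, seed=8, background=20.0, noise_sd=0.0
    )
    integrated = img.sum() - 20.0 * 128 * 128
    assert integrated == pytest.approx(truth["total_intensity"].sum(), rel=0.01)


def test_particle_field_crowding_flag():
    _, truth = make_particle_field(60, image_size=64, seed=1, psf_sigma=2.0)
    assert truth["crowded"].any()  # high density must raise the warning flag
    with pytest.raises(ValueError):
        make_particle_field(-1)
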