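"""Contact-point detection and modulus fitting against analytic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fvmap.curve_processing import (
    BundleUnusableError,
    CantileverSpec,
    FitOptions,
    ForceCurve,
    ForceCurveModel,
    contact_model_constant,
    detect_contact_point,
    fit_modulus,
    indentation_depth,
    process_bundle,
)
from fvmap.synthetic_data import (
    AcquisitionSpec,
    PhantomSpec,
    make_phantom,
    simulate_curve,
    simulate_fv_bundle,
)


def _synthetic_curve(e_pa, cantilever, contact_index=40, n=120, baseline=0.0, noise=0.0, rng=None):
    """Curve with the contact point exactly at a chosen sample index."""
    k = cantilever.spring_constant_n_per_m
    C = contact_model_constant(cantilever)
    cprime = C * e_pa * 1e-9
    z = np.arange(n, dtype=float) * 10.0
    zc = z[contact_index]
    s = np.maximum(z - zc, 0.0)
    a = cprime / k**2
    b = 2 * cprime * s / k + 1.0
    c = cprime * s * s
    f = 2 * c / (b + np.sqrt(np.maximum(b * b - 4 * a * c, 0.0))) + baseline
    if noise:
        f = f + rng.normal(0, noise, n)
    return ForceCurve(piezo_nm=z, force_nN=f)


class TestDetectContactPoint:
    def test_noiseless_contact_found_exactly(self, cantilever):
        curve = _synthetic_curve(10_000.0, cantilever, contact_index=40)
        res = detect_contact_point(curve, cantilever)
        assert res.contact_index == 40
        assert res.baseline_nN == pytest.approx(0.0, abs=1e-12)

    def test_nonzero_baseline_recovered(self, cantilever):
        curve = _synthetic_curve(10_000.0, cantilever, contact_index=55, baseline=0.37)
        res = detect_contact_point(curve, cantilever)
        assert res.contact_index == 55
        assert res.baseline_nN == pytest.approx(0.37, abs=1e-9)

    def test_flat_curve_never_contacts(self, cantilever, rng):
        z = np.arange(64, dtype=float)
        f = rng.normal(0.0, 1e-4, 64)
        res = detect_contact_point(ForceCurve(piezo_nm=z, force_nN=f), cantilever)
        assert not res.valid
        assert res.reject_reason == "no_contact"

    def test_too_short_for_baseline(self, cantilever):
        curve = _synthetic_curve(10_000.0, cantilever, contact_index=8, n=16)
        opts = FitOptions(min_baseline_samples=12, min_contact_samples=12)
        res = detect_contact_point(curve, cantilever, opts)
        assert res.reject_reason == "no_baseline"

    def test_noisy_median_error_within_two_samples(self, cantilever, rng):
        """Force noise at 2% of the 2.5 nN trigger: median |error| <= 2 samples."""
        acq = AcquisitionSpec(noise_sd_nN=0.05)
        errs = []
        for _ in range(200):
            curve = simulate_curve(5_000.0, cantilever, acq, rng=rng)
            res = detect_contact_point(curve, cantilever)
            errs.append(abs(res.contact_index - curve.true_contact_index))
        assert np.median(errs) <= 2


class TestIndentationDepth:
    def test_rigid_sample_limit(self, cantilever):
        """Very stiff sample: deflection tracks piezo, depth stays ~0."""
        curve = _synthetic_curve(5e8, cantilever, contact_index=30, n=64)
        delta = indentation_depth(curve, 30, 0.0, cantilever)
        # piezo travels hundreds of nm past contact; depth stays tiny
        assert delta.max() < 0.05 * (curve.piezo_nm[-1] - curve.piezo_nm[30])

    def test_stiff_cantilever_limit(self):
        """k -> infinity: deflection term vanishes, depth equals piezo travel."""
        soft = CantileverSpec()
        stiff = CantileverSpec(spring_constant_n_per_m=1e9)
        curve = _synthetic_curve(10_000.0, soft, contact_index=30, n=64)
        delta = indentation_depth(curve, 30, 0.0, stiff)
        np.testing.assert_allclose(delta, curve.piezo_nm[30:] - curve.piezo_nm[30], rtol=1e-6)

    def test_depth_at_trigger_matches_forward_inversion(self, cantilever, noiseless_acq):
        curve = simulate_curve(10_000.0, cantilever, noiseless_acq, seed=5)
        c0 = curve.true_contact_index
        delta = indentation_depth(curve, c0, 0.0, cantilever)
        C = contact_model_constant(cantilever)
        expected = np.sqrt(curve.force_nN[-1] / (C * 10_000.0 * 1e-9))
        assert delta[-1] == pytest.approx(expected, rel=1e-9)

    def test_nonmonotone_depth_rejected(self, cantilever):
        z = np.arange(64, dtype=float) * 10
        f = np.concatenate([np.zeros(32), np.linspace(0, 50, 32)])  # deflection > travel
        with pytest.raises(ValueError, match="nonmonotone_indentation"):
            indentation_depth(ForceCurve(piezo_nm=z, force_nN=f), 32, 0.0, cantilever)


class TestFitModulus:
    @pytest.mark.parametrize("e_true", [1e3, 5e3, 1e4, 5e4])
    def test_noiseless_roundtrip_exact(self, cantilever, noiseless_acq, e_true):
        curve = simulate_curve(e_true, cantilever, noiseless_acq, seed=2)
        res = fit_modulus(curve, cantilever)
        assert res.valid
        assert res.youngs_modulus_pa == pytest.approx(e_true, rel=1e-6)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_pure_noise_invalid(self, cantilever, rng):
        z = np.arange(64, dtype=float)
        f = rng.normal(0.0, 0.05, 64)
        res = fit_modulus(ForceCurve(piezo_nm=z, force_nN=f), cantilever)
        assert not res.valid

    def test_short_contact_rejected(self, cantilever):
        curve = _synthetic_curve(10_000.0, cantilever, contact_index=40, n=120)
        res = fit_modulus(
            curve, cantilever, FitOptions(min_contact_samples=500), contact=detect_contact_point(curve, cantilever)
        )
        assert res.reject_reason == "short_contact"

    def test_modulus_bounds_enforced(self, cantilever, noiseless_acq):
        curve = simulate_curve(10_000.0, cantilever, noiseless_acq, seed=2)
        res = fit_modulus(curve, cantilever, FitOptions(modulus_bounds_pa=(50.0, 5_000.0)))
        assert not res.valid
        assert res.reject_reason == "modulus_out_of_range"

    def test_closed_form_at_trigger_agrees_with_least_squares(self, cantilever, noiseless_acq):
        """Independent oracle: E from the trigger point alone matches the fit."""
        curve = simulate_curve(8_000.0, cantilever, noiseless_acq, seed=3)
        res = fit_modulus(curve, cantilever)
        c0 = res.contact_index
        k = cantilever.spring_constant_n_per_m
        z, f = curve.piezo_nm, curve.force_nN
        delta_trig = (z[-1] - z[c0]) - (f[-1] - res.baseline_nN) / k
        C = contact_model_constant(cantilever)
        e_closed = (f[-1] - res.baseline_nN) / (C * delta_trig**2 * 1e-9)
        assert res.youngs_modulus_pa == pytest.approx(e_closed, rel=1e-9)

    @given(scale=st.floats(0.2, 5.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_equivariance(self, scale):
        """Scaling forces and spring constant by c leaves the indentation
        unchanged and multiplies the fitted E by c (zero baseline)."""
        cantilever = CantileverSpec()
        curve = _synthetic_curve(10_000.0, cantilever, contact_index=40)
        res1 = fit_modulus(curve, cantilever, contact=detect_contact_point(curve, cantilever))
        scaled = ForceCurve(piezo_nm=curve.piezo_nm, force_nN=curve.force_nN * scale)
        scaled_cant = CantileverSpec(
            spring_constant_n_per_m=cantilever.spring_constant_n_per_m * scale
        )
        # fixed contact and baseline, per the equivariance statement
        from fvmap.curve_processing import FitResult

        fixed = FitResult(contact_index=res1.contact_index, baseline_nN=0.0)
        res2 = fit_modulus(
            scaled, scaled_cant, FitOptions(modulus_bounds_pa=(1.0, 1e9)), contact=fixed
        )
        assert res2.youngs_modulus_pa == pytest.approx(scale * res1.youngs_modulus_pa, rel=1e-6)

    def test_monotonicity_in_modulus(self, cantilever, noiseless_acq):
        fits = []
        for e_true in (2e3, 8e3, 3e4):
            curve = simulate_curve(e_true, cantilever, noiseless_acq, seed=6)
            fits.append(fit_modulus(curve, cantilever).youngs_modulus_pa)
        assert fits[0] < fits[1] < fits[2]

    def test_model_object_interface(self, cantilever, noiseless_acq):
        curve = simulate_curve(5e3, cantilever, noiseless_acq, seed=1)
        res = ForceCurveModel(curve, cantilever).fit()
        assert res.valid
        assert "E [Pa]" in res.summary()


class TestProcessBundle:
    def test_noiseless_bundle_recovers_truth(self, cantilever):
        spec = PhantomSpec(grid_n=8, roi_size_um=4.0, modulus_cv=0.1, seed=7)
        ph = make_phantom(spec)
        acq = AcquisitionSpec(grid_n=8, roi_size_um=4.0, noise_sd_nN=0.0)
        bundle = simulate_fv_bundle(ph, cantilever, acq, seed=1)
        mmap, qc = process_bundle(bundle, cantilever)
        assert qc["valid"].all()
        np.testing.assert_allclose(mmap.values_pa, ph.modulus_field, rtol=1e-6)

    def test_corrupted_curve_counts_one_invalid_pixel(self, cantilever, rng):
        spec = PhantomSpec(grid_n=8, roi_size_um=4.0, modulus_cv=0.0, seed=7)
        ph = make_phantom(spec)
        acq = AcquisitionSpec(grid_n=8, roi_size_um=4.0, noise_sd_nN=0.0)
        bundle = simulate_fv_bundle(ph, cantilever, acq, seed=1)
        n = len(bundle.curves[5])
        bundle.curves[5] = ForceCurve(
            piezo_nm=bundle.curves[5].piezo_nm, force_nN=rng.normal(0, 0.01, n)
        )
        mmap, qc = process_bundle(bundle, cantilever)
        assert int((~qc["valid"]).sum()) == 1
        assert int(mmap.valid_mask.sum()) == 63

    def test_unusable_bundle_raises(self, cantilever, rng):
        spec = PhantomSpec(grid_n=8, roi_size_um=4.0, modulus_cv=0.0, seed=7)
        ph = make_phantom(spec)
        acq = AcquisitionSpec(grid_n=8, roi_size_um=4.0, noise_sd_nN=0.0)
        bundle = simulate_fv_bundle(ph, cantilever, acq, seed=1)
        for i in range(33):
            n = len(bundle.curves[i])
            bundle.curves[i] = ForceCurve(
                piezo_nm=bundle.curves[i].piezo_nm, force_nN=rng.normal(0, 0.01, n)
            )
        with pytest.raises(BundleUnusableError, match="bundle_unusable"):
            process_bundle(bundle, cantilever)
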