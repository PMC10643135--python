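"""Mössbauer doublet and powder EPR models: simulation and fitting."""

import numpy as np
import pytest

from redoxmap.fixtures import make_noisy_spectrum
from redoxmap.spectra import (
    FIELD_MT_PER_GHZ,
    EprComponent,
    MossbauerDoublet,
    Spectrum1D,
    fit_epr_weights,
    fit_mossbauer,
    simulate_epr_powder,
    simulate_mossbauer,
)

VEL = np.linspace(-2.0, 2.0, 801)
NQRDE_DOUBLET = MossbauerDoublet(isomer_shift=0.3, quadrupole_splitting=0.51,
                                 linewidth=0.24)
FIELD = np.linspace(300.0, 370.0, 1401)
FES_COMPONENT = EprComponent("axial", g_parallel=2.02, g_perp=1.94,
                             linewidth_g=50.0, weight=0.96)
RADICAL = EprComponent("isotropic", g_iso=2.01, linewidth_g=20.0, weight=0.04)


class TestMossbauerSimulation:
    def test_degenerate_doublet_is_single_line(self):
        d = MossbauerDoublet(0.3, 0.0, 0.24)
        spec = simulate_mossbauer(d, VEL)
        assert VEL[np.argmin(spec.ordinate)] == pytest.approx(0.3, abs=0.01)
        # symmetric about the isomer shift
        left = np.interp(0.3 - 0.4, VEL, spec.ordinate)
        right = np.interp(0.3 + 0.4, VEL, spec.ordinate)
        assert left == pytest.approx(right, rel=1e-6)

    def test_absorption_minima_at_doublet_line_centers(self):
        spec = simulate_mossbauer(NQRDE_DOUBLET, VEL)
        order = np.argsort(spec.ordinate)
        minima = sorted(VEL[order[:2]])
        assert minima[0] == pytest.approx(0.045, abs=0.01)
        assert minima[1] == pytest.approx(0.555, abs=0.01)

    def test_total_area_equals_amplitude(self):
        d = MossbauerDoublet(0.0, 0.5, 0.05, amplitude=2.5)
        grid = np.linspace(-3.0, 3.0, 20001)   # +-10 linewidths around the lines
        spec = simulate_mossbauer(d, grid)
        area = -np.trapezoid(spec.ordinate, grid)
        assert area == pytest.approx(2.5, rel=0.01)

    def test_area_linear_in_amplitude(self):
        s1 = simulate_mossbauer(MossbauerDoublet(0.3, 0.51, 0.24, amplitude=1.0), VEL)
        s3 = simulate_mossbauer(MossbauerDoublet(0.3, 0.51, 0.24, amplitude=3.0), VEL)
        assert np.allclose(3.0 * s1.ordinate, s3.ordinate)

    def test_symmetric_about_isomer_shift_when_asymmetry_one(self):
        spec = simulate_mossbauer(NQRDE_DOUBLET, VEL)
        probe = np.linspace(0.0, 0.8, 50)
        left = np.interp(0.3 - probe, VEL, spec.ordinate)
        right = np.interp(0.3 + probe, VEL, spec.ordinate)
        assert np.allclose(left, right, rtol=1e-6, atol=1e-9)

    def test_grid_missing_lines_warns(self):
        with pytest.warns(UserWarning, match="grid"):
            simulate_mossbauer(MossbauerDoublet(5.0, 0.5), VEL)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MossbauerDoublet(0.3, -0.1)
        with pytest.raises(ValueError):
            MossbauerDoublet(0.3, 0.5, linewidth=0.0)


class TestMossbauerFit:
    def test_noiseless_self_fit_is_exact(self):
        spec = simulate_mossbauer(NQRDE_DOUBLET, VEL)
        fit = fit_mossbauer(spec, MossbauerDoublet(0.2, 0.4, 0.3))
        assert fit.converged
        assert fit.params.isomer_shift == pytest.approx(0.3, abs=1e-6)
        assert fit.params.quadrupole_splitting == pytest.approx(0.51, abs=1e-6)
        assert fit.params.linewidth == pytest.approx(0.24, abs=1e-6)

    def test_seeded_noisy_fit_recovers_splitting(self):
        clean = simulate_mossbauer(NQRDE_DOUBLET, VEL)
        sigma = 0.01 * np.max(np.abs(clean.ordinate))
        spec = make_noisy_spectrum(
            "mossbauer",
            dict(isomer_shift=0.3, quadrupole_splitting=0.51, linewidth=0.24),
            noise_sigma=sigma, seed=2024, axis=VEL)
        fit = fit_mossbauer(spec, MossbauerDoublet(0.25, 0.40, 0.30))
        assert abs(fit.params.quadrupole_splitting - 0.51) < 0.02
        assert fit.stderr["quadrupole_splitting"] is not None

    def test_monte_carlo_bias_is_small(self):
        """Mean ΔE_Q bias over 100 seeded 1%-noise replicates < 0.005 mm/s."""
        clean = simulate_mossbauer(NQRDE_DOUBLET, VEL)
        sigma = 0.01 * np.max(np.abs(clean.ordinate))
        init = MossbauerDoublet(0.25, 0.40, 0.30)
        ests = []
        for seed in range(100):
            spec = make_noisy_spectrum(
                "mossbauer",
                dict(isomer_shift=0.3, quadrupole_splitting=0.51, linewidth=0.24),
                noise_sigma=sigma, seed=seed, axis=VEL)
            ests.append(fit_mossbauer(spec, init).params.quadrupole_splitting)
        assert abs(np.mean(ests) - 0.51) < 0.005

    def test_nonconvergence_flagged_not_raised(self):
        flat = Spectrum1D(VEL, np.zeros_like(VEL))
        fit = fit_mossbauer(flat, MossbauerDoublet(0.3, 0.5, 0.2))
        assert fit.residual_norm >= 0.0   # returns a result either way


class TestEprSimulation:
    def test_isotropic_zero_crossing_at_resonance_field(self):
        iso = EprComponent("isotropic", g_iso=2.0023, linewidth_g=10.0, weight=1.0)
        spec = simulate_epr_powder([iso], 9.40, np.linspace(320, 350, 3001))
        b0 = FIELD_MT_PER_GHZ * 9.40 / 2.0023
        assert b0 == pytest.approx(335.4, abs=0.1)
        sign = np.sign(spec.ordinate)
        crossings = spec.axis[np.where(np.diff(sign) != 0)[0]]
        assert np.min(np.abs(crossings - b0)) < 0.2

    def test_axial_powder_edges_at_g_parallel_and_g_perp(self):
        spec = simulate_epr_powder([EprComponent("axial", g_parallel=2.02,
                                                 g_perp=1.94, linewidth_g=10.0,
                                                 weight=1.0)], 9.40, FIELD)
        b_par = FIELD_MT_PER_GHZ * 9.40 / 2.02
        b_perp = FIELD_MT_PER_GHZ * 9.40 / 1.94
        peak = np.max(np.abs(spec.ordinate))
        # dominant derivative swing at the g_perp edge singularity
        assert abs(spec.axis[np.argmin(spec.ordinate)] - b_perp) < 2.0
        assert abs(spec.axis[np.argmax(spec.ordinate)] - b_perp) < 2.0
        # a distinct (weaker) feature marks the g_par shoulder
        par_window = np.abs(spec.axis - b_par) < 3.0
        assert np.max(np.abs(spec.ordinate[par_window])) > 0.02 * peak
        assert np.max(np.abs(spec.ordinate[par_window])) < 0.5 * peak

    def test_two_component_mixture_shows_radical_feature(self):
        mix = simulate_epr_powder([FES_COMPONENT, RADICAL], 9.40, FIELD)
        fes_only = simulate_epr_powder(
            [EprComponent("axial", g_parallel=2.02, g_perp=1.94,
                          linewidth_g=50.0, weight=1.0)], 9.40, FIELD)
        b_rad = FIELD_MT_PER_GHZ * 9.40 / 2.01
        window = np.abs(mix.axis - b_rad) < 2.5
        # the sharp g=2.01 radical adds a distinct derivative excursion
        assert np.max(np.abs(mix.ordinate[window] - 0.96 * fes_only.ordinate[window])) > \
            0.2 * np.max(np.abs(mix.ordinate))

    def test_derivative_integrates_to_zero(self):
        spec = simulate_epr_powder([FES_COMPONENT, RADICAL], 9.40, FIELD)
        total = np.trapezoid(spec.ordinate, spec.axis)
        scale = np.trapezoid(np.abs(spec.ordinate), spec.axis)
        assert abs(total) < 0.02 * scale

    def test_double_integral_proportional_to_weight(self):
        from scipy.integrate import cumulative_trapezoid
        for w in (0.3, 0.7):
            comp = EprComponent("isotropic", g_iso=2.0, linewidth_g=15.0, weight=w)
            other = EprComponent("isotropic", g_iso=1.8, linewidth_g=15.0, weight=1 - w)
            spec = simulate_epr_powder([comp, other], 9.40, np.linspace(310, 400, 4001))
            absorb = cumulative_trapezoid(spec.ordinate, spec.axis, initial=0.0)
            b_split = (FIELD_MT_PER_GHZ * 9.40 / 1.9)
            mask = spec.axis < b_split
            area_first = np.trapezoid(absorb[mask], spec.axis[mask])
            area_total = np.trapezoid(absorb, spec.axis)
            assert area_first / area_total == pytest.approx(w, abs=0.02)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            simulate_epr_powder([EprComponent("isotropic", g_iso=2.0, weight=0.5)],
                                9.40, FIELD)

    def test_orientation_grid_converged(self):
        a = simulate_epr_powder([FES_COMPONENT, RADICAL], 9.40, FIELD, n_theta=1800)
        b = simulate_epr_powder([FES_COMPONENT, RADICAL], 9.40, FIELD, n_theta=3600)
        assert np.max(np.abs(a.ordinate - b.ordinate)) < 0.005 * np.max(np.abs(a.ordinate))


class TestEprWeightFit:
    def test_single_component_weight_is_one(self):
        spec = simulate_epr_powder(
            [EprComponent("isotropic", g_iso=2.0, linewidth_g=20.0, weight=1.0)],
            9.40, FIELD)
        w = fit_epr_weights(spec, [EprComponent("isotropic", g_iso=2.0,
                                                linewidth_g=20.0, weight=1.0)], 9.40)
        assert w == pytest.approx([1.0])

    def test_recovers_four_percent_radical_weight(self):
        clean = simulate_epr_powder([FES_COMPONENT, RADICAL], 9.40, FIELD)
        rng = np.random.default_rng(77)
        noisy = Spectrum1D(FIELD, clean.ordinate +
                           rng.normal(0, 0.01 * np.max(np.abs(clean.ordinate)),
                                      FIELD.shape),
                           frequency_ghz=9.40)
        w = fit_epr_weights(noisy, [FES_COMPONENT, RADICAL])
        assert abs(w[1] - 0.04) < 0.01

    def test_null_component_recovered_as_near_zero(self):
        only = simulate_epr_powder(
            [EprComponent("axial", g_parallel=2.02, g_perp=1.94,
                          linewidth_g=50.0, weight=1.0)], 9.40, FIELD)
        w = fit_epr_weights(only, [FES_COMPONENT, RADICAL], 9.40)
        assert w[1] <= 0.005

    def test_identical_components_rejected(self):
        spec = simulate_epr_powder([FES_COMPONENT, RADICAL], 9.40, FIELD)
        with pytest.raises(ValueError, match="degenerate"):
            fit_epr_weights(spec, [RADICAL, RADICAL], 9.40)

    def test_g_outside_plausible_window_rejected(self):
        with pytest.raises(ValueError, match="g value"):
            EprComponent("isotropic", g_iso=3.0)
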