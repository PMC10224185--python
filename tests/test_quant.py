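"""Quantification triad, calibration, and agreement/group statistics."""

import numpy as np
import pytest
from scipy import stats

from benchnmr.library import load_library
from benchnmr.processing import reference_and_normalize
from benchnmr.quant import (GLPeak, acetate_window, build_calibration,
                            compare_groups, determine_tsp_shape,
                            fit_gl_peak, integrate_region, library_fit,
                            make_templates, method_agreement,
                            normalize_by_tsp_fit,
                            simulate_calibration_series, welch_df)
from benchnmr.spectrum import Spectrum
from benchnmr.spin import (LineshapeParams, PeakList, default_axis,
                           first_order_peaks, render_spectrum)


def _acetate_tsp(conc_mM, noise=0.0, seed=0, field=60.0, n=8192,
                 extra_peaks=None):
    lib = load_library()
    parts = [first_order_peaks(lib["acetate"], field).scaled(conc_mM),
             first_order_peaks(lib["tsp"], field).scaled(0.5)]
    if extra_peaks is not None:
        parts.append(extra_peaks)
    peaks = PeakList.concatenate(parts)
    ax = default_axis(field, n_points=n)
    spec = render_spectrum(peaks, ax,
                           LineshapeParams(width_hz=1.4, noise_sd=noise,
                                           seed=seed))
    return reference_and_normalize(spec)


def test_region_integral_follows_proton_stoichiometry():
    """Acetate (3H) vs TSP (9H at 0.5 mM): window-ratio arithmetic."""
    spec = _acetate_tsp(10.0)
    area = integrate_region(spec, 1.80, 2.04)
    # spectrum is normalized to the TSP window area; both windows catch
    # the same fraction of their Lorentzian, so the ratio is the proton
    # ratio up to the wider acetate window's extra tail coverage
    expected = (10.0 * 3) / (0.5 * 9)
    assert area == pytest.approx(expected, rel=0.12)
    # linear in concentration up to the tiny acetate-tail leakage into
    # the TSP normalization window
    area2 = integrate_region(_acetate_tsp(20.0), 1.80, 2.04)
    assert area2 == pytest.approx(2 * area, rel=2e-3)


def test_region_outside_axis_is_an_error():
    spec = _acetate_tsp(10.0)
    with pytest.raises(ValueError):
        integrate_region(spec, 10.5, 11.0)


def test_empty_region_integrates_to_noise_level():
    clean = _acetate_tsp(10.0)
    noisy = _acetate_tsp(10.0, noise=1e-3, seed=4)
    # noise adds at most 3x its propagated sd to the signal-free window
    val = integrate_region(noisy, 8.5, 8.7) - integrate_region(clean, 8.5, 8.7)
    dx = noisy.ppm[1] - noisy.ppm[0]
    sd = 1e-3 / noisy.metadata["tsp_area"] * dx * np.sqrt(0.2 / dx)
    assert abs(val) < 3 * sd


def test_gl_selffit_recovers_area_to_per_mille():
    spec = _acetate_tsp(10.0)
    pk = fit_gl_peak(spec, (1.80, 2.04), n_nuisance=0)
    direct = integrate_region(spec, 1.80, 2.04)
    assert pk.center_ppm == pytest.approx(1.92, abs=1e-4)
    assert pk.fwhm_hz == pytest.approx(1.4, rel=0.01)
    # analytic area exceeds the window integral by the tail fraction
    assert pk.area > direct
    assert pk.area == pytest.approx(
        10.0 * 3 / spec.metadata["tsp_area"], rel=1e-3)


def test_gl_beats_region_under_multiplet_overlap():
    """A neighboring multiplet inflates the window integral; the GL
    deconvolution assigns it to nuisance components instead."""
    lib = load_library()
    neighbor = first_order_peaks(lib["glutamate"], 60.0).scaled(4.0)
    clean = _acetate_tsp(10.0)
    truth = fit_gl_peak(clean, (1.80, 2.04), n_nuisance=0).area
    messy = _acetate_tsp(10.0, extra_peaks=neighbor)
    gl = fit_gl_peak(messy, (1.80, 2.04), n_nuisance=2).area
    region = integrate_region(messy, 1.80, 2.04)
    region_clean = integrate_region(clean, 1.80, 2.04)
    assert abs(gl - truth) < abs(region - region_clean)
    assert abs(gl - truth) / truth < 0.05


def test_free_eta_nests_the_gaussian_case():
    lib = load_library()
    peaks = PeakList.concatenate([
        first_order_peaks(lib["acetate"], 60.0).scaled(10.0),
        first_order_peaks(lib["tsp"], 60.0).scaled(0.5)])
    ax = default_axis(60.0, n_points=8192)
    spec = reference_and_normalize(render_spectrum(
        peaks, ax, LineshapeParams(width_hz=1.4, eta=1.0)))  # pure Gaussian
    free = fit_gl_peak(spec, (1.80, 2.04), n_nuisance=0)
    assert free.eta > 0.9
    # freezing eta at 0 (Lorentzian) must fit worse
    init = GLPeak(center_ppm=1.92, fwhm_hz=1.4, eta=0.0, area=free.area)
    x = spec.ppm[(spec.ppm >= 1.80) & (spec.ppm <= 2.04)]
    from benchnmr.quant import _gl_profile
    y = spec.real[(spec.ppm >= 1.80) & (spec.ppm <= 2.04)]
    resid_lor = np.linalg.norm(
        y - free.area * _gl_profile(x, free.center_ppm,
                                    free.fwhm_hz / 60.0, 0.0))
    assert free.residual_norm < resid_lor


def test_library_selffit_is_exact():
    spec = _acetate_tsp(7.5)
    shape = determine_tsp_shape([spec])
    tmpl = make_templates(["acetate"], 60.0, spec.ppm, *shape)
    # renormalize the sample the same way the templates are scaled
    norm = normalize_by_tsp_fit(spec, shape=shape)
    conc, resid = library_fit(norm, tmpl, window=(1.80, 2.04))
    assert conc["acetate"] == pytest.approx(7.5, rel=1e-3)
    assert np.max(np.abs(resid)) < 1e-2 * np.max(norm.real)


def test_two_template_mixture_recovered():
    lib = load_library()
    succ = first_order_peaks(lib["succinate"], 60.0).scaled(5.0)
    spec = _acetate_tsp(10.0, extra_peaks=succ)
    # SNR 100 relative to the spectrum maximum
    rng = np.random.default_rng(8)
    noisy = Spectrum(spec.ppm,
                     spec.real + rng.normal(0, spec.real.max() / 100,
                                            spec.ppm.size),
                     60.0, dict(spec.metadata))
    shape = determine_tsp_shape([noisy])
    tmpl = make_templates(["acetate", "succinate"], 60.0, noisy.ppm, *shape)
    norm = normalize_by_tsp_fit(noisy, shape=shape)
    conc, _ = library_fit(norm, tmpl, window=(1.7, 2.6))
    assert conc["acetate"] == pytest.approx(10.0, rel=0.05)
    assert conc["succinate"] == pytest.approx(5.0, rel=0.05)


def test_absent_template_stays_near_zero():
    spec = _acetate_tsp(10.0, noise=2e-4, seed=3)
    shape = determine_tsp_shape([spec])
    tmpl = make_templates(["acetate", "succinate"], 60.0, spec.ppm, *shape)
    norm = normalize_by_tsp_fit(spec, shape=shape)
    conc, _ = library_fit(norm, tmpl, window=(1.7, 2.6))
    assert conc["succinate"] < 0.02 * conc["acetate"]


def test_quantification_is_homogeneous_in_concentration():
    """All three responses double when the true concentration doubles."""
    s1, s2 = _acetate_tsp(5.0), _acetate_tsp(10.0)
    shape = determine_tsp_shape([s1])
    tmpl = make_templates(["acetate"], 60.0, s1.ppm, *shape)
    r1 = integrate_region(s1, 1.80, 2.04)
    r2 = integrate_region(s2, 1.80, 2.04)
    assert r2 == pytest.approx(2 * r1, rel=2e-3)
    g1 = fit_gl_peak(s1, (1.80, 2.04), n_nuisance=0).area
    g2 = fit_gl_peak(s2, (1.80, 2.04), n_nuisance=0).area
    assert g2 == pytest.approx(2 * g1, rel=1e-3)
    l1, _ = library_fit(normalize_by_tsp_fit(s1, shape=shape), tmpl)
    l2, _ = library_fit(normalize_by_tsp_fit(s2, shape=shape), tmpl)
    assert l2["acetate"] == pytest.approx(2 * l1["acetate"], rel=1e-3)


def test_calibration_on_exact_line_is_perfect():
    levels = [2, 5, 8, 11]
    responses = [0.1 + 0.7 * lv for lv in levels]
    cal = build_calibration(levels, responses)
    assert cal.slope == pytest.approx(0.7)
    assert cal.intercept == pytest.approx(0.1)
    assert cal.r_squared == pytest.approx(1.0)
    assert cal.to_mM(0.1 + 0.7 * 6.5) == pytest.approx(6.5)


def test_calibration_requires_three_levels_and_variance():
    with pytest.raises(ValueError):
        build_calibration([2, 2, 4], [1, 1, 2])
    with pytest.raises(ValueError):
        build_calibration([2, 4, 6], [3, 3, 3])


def test_simulated_series_covers_2_to_20_mM():
    series = simulate_calibration_series(60.0, n_points=4096, replicates=1,
                                         seed=0)
    levels = sorted({lv for lv, _ in series})
    assert levels[0] == 2.0 and levels[-1] == 20.0
    assert all(s.is_normalized for _, s in series)


def test_acetate_window_is_field_dependent():
    assert acetate_window(60.0) == (1.80, 2.04)
    assert acetate_window(800.0) == (1.90, 1.94)


def test_agreement_identical_vectors():
    a = np.array([1.0, 2.0, 3.0])
    ag = method_agreement(a, a)
    assert ag.mae == 0.0
    assert ag.ci95 == (0.0, 0.0)


def test_agreement_constant_offset():
    ref = np.array([1.0, 2.0, 3.0, 4.0])
    ag = method_agreement(ref + 0.5, ref)
    assert ag.mean == pytest.approx(0.5)
    assert ag.sd == pytest.approx(0.0)
    assert ag.mae == pytest.approx(0.5)


def test_agreement_t_interval_hand_computed():
    """diffs [0.1, -0.3, 0.2]: MAE 0.2, CI uses t(0.975, 2) = 4.303."""
    ref = np.array([1.0, 1.0, 1.0])
    est = ref + np.array([0.1, -0.3, 0.2])
    ag = method_agreement(est, ref)
    assert ag.mae == pytest.approx(0.2)
    assert ag.mean == pytest.approx(0.0)
    sd = np.std([0.1, -0.3, 0.2], ddof=1)
    half = 4.302653 * sd / np.sqrt(3)
    assert ag.ci95[0] == pytest.approx(-half, rel=1e-5)
    assert ag.ci95[1] == pytest.approx(half, rel=1e-5)
    assert ag.absolute_percentage_errors == pytest.approx([10.0, 30.0, 20.0])


def test_agreement_needs_pairs():
    with pytest.raises(ValueError):
        method_agreement([1.0], [1.0])
    with pytest.raises(ValueError):
        method_agreement([1.0, 2.0], [1.0])


def test_welch_matches_satterthwaite_oracle():
    rng = np.random.default_rng(21)
    a = rng.normal(0.0, 1.0, 12)
    b = rng.normal(0.8, 2.5, 7)
    res = compare_groups([a, b], test="welch")
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    df_oracle = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    t_oracle = (a.mean() - b.mean()) / np.sqrt(va + vb)
    p_oracle = 2 * stats.t.sf(abs(t_oracle), df_oracle)
    assert res.df == pytest.approx(df_oracle, abs=1e-6)
    assert res.statistic == pytest.approx(t_oracle, abs=1e-6)
    assert res.p_value == pytest.approx(p_oracle, abs=1e-6)
    assert welch_df(a, b) == pytest.approx(df_oracle, abs=1e-9)


def test_identical_groups_are_not_significant():
    a = np.array([1.0, 2.0, 3.0])
    res = compare_groups([a, a.copy()], test="welch")
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_anova_null_tukey_intervals_cover_zero():
    rng = np.random.default_rng(5)
    groups = [rng.normal(5.0, 1.0, 60) for _ in range(3)]
    res = compare_groups(groups, test="anova")
    assert res.p_value > 0.01
    ci = res.tukey.confidence_interval()
    for i in range(3):
        for j in range(3):
            if i != j:
                assert ci.low[i, j] < 0 < ci.high[i, j]


def test_degenerate_groups_rejected():
    with pytest.raises(ValueError):
        compare_groups([[1.0], [1.0, 2.0]], test="welch")
    with pytest.raises(ValueError):
        compare_groups([[1.0, 2.0]], test="welch")
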