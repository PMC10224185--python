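"""Spin simulation: envelope arithmetic, multiplets, Hamiltonian physics."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from benchnmr.spin import (LineshapeParams, PeakList, SpinCountError,
                           SpinGroup, SpinSystem, default_axis,
                           first_order_peaks, full_hamiltonian_peaks,
                           multiplet_envelope_ppm, peaks_auto,
                           render_spectrum)


@pytest.mark.parametrize("J, n, field, expected", [
    (7.70, 3, 60.0, 0.385),      # propionate triplet footprint, benchtop
    (7.05, 2, 60.0, 0.235),      # valine/isoleucine doublet footprint
    (0.0, 1, 60.0, 0.0),         # singlet has no J spread
])
def test_envelope_width_exact(J, n, field, expected):
    assert multiplet_envelope_ppm(J, n, field) == pytest.approx(
        expected, abs=1e-12)


def test_envelope_width_highfield_rounds_to_printed_value():
    assert round(multiplet_envelope_ppm(7.70, 3, 800.0), 3) == 0.029


def test_envelope_rejects_nonpositive_field():
    with pytest.raises(ValueError):
        multiplet_envelope_ppm(7.7, 3, 0.0)
    with pytest.raises(ValueError):
        multiplet_envelope_ppm(7.7, 3, -60.0)


def test_acetate_is_a_singlet_with_three_protons(library):
    p = first_order_peaks(library["acetate"], 60.0)
    assert len(p.lines) == 1
    assert p.ppm[0] == pytest.approx(1.92)
    assert p.intensity[0] == pytest.approx(3.0)


@pytest.mark.parametrize("field", [60.0, 800.0])
def test_alanine_doublet_positions_scale_with_field(library, field):
    """Splitting is J Hz at every field, i.e. J/field ppm."""
    p = first_order_peaks(library["alanine"], field)
    ch3 = p.lines[np.abs(p.ppm - 1.48) < 0.5]
    assert len(ch3) == 2
    lo, hi = sorted(ch3[:, 0])
    assert hi - lo == pytest.approx(7.2 / field, rel=1e-9)
    assert ch3[:, 1] == pytest.approx([1.5, 1.5])


def test_triplet_has_binomial_intensities():
    sys = SpinSystem("x", [SpinGroup(1.0, 3), SpinGroup(2.5, 2)],
                     [[0, 7.0], [7.0, 0]])
    p = first_order_peaks(sys, 60.0)
    ch3 = p.lines[np.abs(p.ppm - 1.0) < 0.5]
    assert sorted(ch3[:, 1]) == pytest.approx([0.75, 0.75, 1.5])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(1, 3), st.integers(1, 3),
       st.floats(0.0, 15.0), st.floats(0.5, 9.0), st.floats(0.5, 9.0))
def test_first_order_conserves_total_intensity(na, nb, J, da, db):
    sys = SpinSystem("x", [SpinGroup(da, na), SpinGroup(db, nb)],
                     [[0, J], [J, 0]])
    for field in (60.0, 800.0):
        p = first_order_peaks(sys, field)
        assert p.total_intensity == pytest.approx(na + nb, rel=1e-9)


def test_hamiltonian_conserves_intensity_for_whole_library(library):
    for name, sys in library.items():
        if sys.n_spins > 8:
            continue
        for field in (60.0, 800.0):
            p = full_hamiltonian_peaks(sys, field)
            assert p.total_intensity == pytest.approx(
                sys.n_protons, rel=1e-6), name


def test_two_uncoupled_spins_give_two_unit_lines():
    sys = SpinSystem("x", [SpinGroup(1.0, 1), SpinGroup(3.0, 1)])
    p = full_hamiltonian_peaks(sys, 60.0)
    assert sorted(p.ppm) == pytest.approx([1.0, 3.0])
    assert p.intensity == pytest.approx([1.0, 1.0])


def _ab_quartet_oracle(da, db, J, field):
    """Closed-form AB spectrum: line positions (ppm) and intensities."""
    va, vb = da * field, db * field
    mid, dnu = (va + vb) / 2.0, va - vb
    C = math.sqrt(dnu**2 + J**2)
    pos = [mid + (C + J) / 2, mid + (C - J) / 2,
           mid - (C - J) / 2, mid - (C + J) / 2]
    inten = [(1 - J / C) / 2, (1 + J / C) / 2,
             (1 + J / C) / 2, (1 - J / C) / 2]
    order = np.argsort(pos)
    return (np.array(pos)[order] / field, np.array(inten)[order])


@pytest.mark.parametrize("da, db, J, field", [
    (3.00, 3.10, 7.0, 60.0),     # strong coupling: dv ~ 0.86 J
    (1.00, 1.05, 7.05, 60.0),
    (6.90, 7.19, 8.5, 60.0),     # tyrosine ring conditions, benchtop
])
def test_hamiltonian_matches_ab_quartet_closed_form(da, db, J, field):
    sys = SpinSystem("ab", [SpinGroup(da, 1), SpinGroup(db, 1)],
                     [[0, J], [J, 0]])
    p = full_hamiltonian_peaks(sys, field)
    order = np.argsort(p.ppm)
    pos_o, int_o = _ab_quartet_oracle(da, db, J, field)
    assert np.max(np.abs(p.ppm[order] - pos_o)) * field < 1e-9  # Hz
    assert np.max(np.abs(p.intensity[order] - int_o)) < 1e-9
    # roof effect: inner lines stronger
    assert p.intensity[order][1] > p.intensity[order][0]


def test_hamiltonian_reduces_to_first_order_in_weak_coupling_limit():
    """At dv = 500 J the exact positions match first order to 0.1% of J."""
    J, field = 1.0, 800.0
    sys = SpinSystem("ax", [SpinGroup(1.0, 1),
                            SpinGroup(1.0 + 500 * J / field, 1)],
                     [[0, J], [J, 0]])
    fo = first_order_peaks(sys, field)
    ha = full_hamiltonian_peaks(sys, field)
    fo_pos = np.sort(fo.ppm)
    ha_pos = np.sort(ha.ppm)
    assert np.max(np.abs(fo_pos - ha_pos)) * field < 1e-3 * J


def test_spin_cap_directs_to_first_order(library):
    with pytest.raises(SpinCountError):
        full_hamiltonian_peaks(library["isoleucine"], 60.0)  # 10 protons
    # auto mode falls back silently
    p = peaks_auto(library["isoleucine"], 60.0)
    assert p.total_intensity == pytest.approx(10.0, rel=1e-9)


def test_lorentzian_render_is_area_normalized(axis60):
    peaks = PeakList(np.array([[5.0, 1.0]]), 60.0)
    spec = render_spectrum(peaks, axis60,
                           LineshapeParams(width_hz=1.4, eta=0.0))
    assert spec.ppm[np.argmax(spec.real)] == pytest.approx(5.0, abs=0.01)
    assert np.trapezoid(spec.real, spec.ppm) == pytest.approx(1.0, abs=0.01)


def test_multiplet_integrals_are_field_invariant(library):
    """The same peak list rendered at 60 and 800 MHz integrates equally."""
    for name in ("alanine", "propionate", "valine"):
        sys = library[name]
        for mode in (first_order_peaks, peaks_auto):
            areas = []
            for field in (60.0, 800.0):
                p = mode(sys, field)
                ax = default_axis(field, n_points=16384)
                s = render_spectrum(p, ax, LineshapeParams(width_hz=1.0))
                areas.append(np.trapezoid(s.real, s.ppm))
            assert areas[0] == pytest.approx(areas[1], rel=0.01)


def test_render_is_deterministic_given_seed(axis60):
    peaks = PeakList(np.array([[5.0, 1.0]]), 60.0)
    shape = LineshapeParams(width_hz=1.4, noise_sd=0.1, seed=42)
    a = render_spectrum(peaks, axis60, shape)
    b = render_spectrum(peaks, axis60, shape)
    assert np.array_equal(a.intensity, b.intensity)


def test_render_warns_on_truncating_axis():
    peaks = PeakList(np.array([[5.0, 1.0]]), 60.0)
    narrow = np.linspace(4.99, 5.01, 200)
    with pytest.warns(UserWarning, match="truncated"):
        spec = render_spectrum(peaks, narrow, LineshapeParams(width_hz=1.4))
    assert spec.metadata.get("truncated") is True


def test_spin_system_validation():
    with pytest.raises(ValueError):
        SpinGroup(15.0, 1)                       # shift out of range
    with pytest.raises(ValueError):
        SpinGroup(1.0, 0)                        # no protons
    with pytest.raises(ValueError):
        SpinSystem("x", [SpinGroup(1.0, 1), SpinGroup(2.0, 1)],
                   [[0, 7], [5, 0]])             # asymmetric J
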