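import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinfit import (
    AcquisitionGrid,
    FID,
    SequenceKind,
    Spectrum,
    fid_to_spectrum,
    make_timing,
    simulate_basis,
    simulate_echo,
)
from spinfit.spin_library import SpinSystem

GLY_PPM = 3.548


# ------------------------------------------------------------------ timing


@pytest.mark.parametrize(
    "kind,te,n_seg",
    [("press", 280.0, 3), ("press", 35.0, 3), ("slaser", 135.0, 5), ("slaser", 40.0, 5)],
)
def test_timing_segments_sum_to_te(kind, te, n_seg):
    tm = make_timing(kind, te)
    assert len(tm.segment_durations) == n_seg
    assert sum(tm.segment_durations) == pytest.approx(te, rel=1e-12)


@given(te=st.floats(1.0, 400.0), kind=st.sampled_from(["press", "slaser"]))
@settings(max_examples=40, deadline=None)
def test_timing_echo_condition_holds_for_any_te(te, kind):
    """Alternating-sign segment sum vanishes: chemical shift refocuses."""
    tm = make_timing(kind, te)
    signs = [(-1) ** k for k in range(len(tm.segment_durations))]
    assert sum(s * d for s, d in zip(signs, tm.segment_durations)) == pytest.approx(
        0.0, abs=1e-9 * te
    )
    assert all(d >= 0 for d in tm.segment_durations)


def test_nonpositive_te_rejected():
    with pytest.raises(ValueError):
        make_timing("press", 0.0)
    with pytest.raises(ValueError):
        make_timing("slaser", -5.0)


def test_grid_validation():
    with pytest.raises(ValueError):
        AcquisitionGrid(n_points=3000)  # not a power of two
    with pytest.raises(ValueError):
        AcquisitionGrid(n_points=512)  # too small
    with pytest.raises(ValueError):
        AcquisitionGrid(sweep_width_hz=800.0)  # cannot cover 0-10 ppm


# ------------------------------------------------------------------ echoes


def test_singlet_fid_invariant_across_te(lib, grid):
    gly = lib["Gly"]
    f35 = simulate_echo(gly, make_timing("press", 35.0), grid)
    f280 = simulate_echo(gly, make_timing("press", 280.0), grid)
    assert abs(f35.samples[0]) == pytest.approx(abs(f280.samples[0]), rel=1e-9)
    s35 = fid_to_spectrum(f35, 8.0)
    s280 = fid_to_spectrum(f280, 8.0)
    i35 = np.trapezoid(s35.values.real, s35.ppm)
    i280 = np.trapezoid(s280.values.real, s280.ppm)
    assert i35 == pytest.approx(i280, rel=1e-9)


def test_density_operator_stays_hermitian_under_propagation(lib, grid):
    simulate_echo(lib["mI"], make_timing("press", 135.0), grid, check_hermiticity=True)
    simulate_echo(lib["Lac"], make_timing("slaser", 135.0), grid, check_hermiticity=True)


def test_first_point_equals_weighted_proton_count(lib, grid):
    """At negligible TE, FID(0) magnitude is the weighted proton sum."""
    tm = make_timing("press", 0.01)
    for name, protons in [("Gly", 2), ("Cr", 5), ("NAA", 6), ("Lac", 4), ("mI", 6)]:
        fid = simulate_echo(lib[name], tm, grid)
        assert abs(fid.samples[0]) == pytest.approx(protons, rel=1e-4)


@pytest.mark.parametrize("kind", ["press", "slaser"])
def test_lactate_doublet_inverts_at_te_135_upright_at_35(lib, grid, kind):
    for te, sign in [(35.0, 1.0), (135.0, -1.0)]:
        spec = fid_to_spectrum(simulate_echo(lib["Lac"], make_timing(kind, te), grid), 8.0)
        win = spec.window(1.2, 1.45)
        extremum = win.values.real[np.argmax(np.abs(win.values.real))]
        assert np.sign(extremum) == sign, (kind, te)


def test_too_many_spins_raises_capability_error(grid):
    n = 9
    sys = SpinSystem("big", [3.0] * n, np.zeros((n, n)), [1] * n)
    with pytest.raises(ValueError, match="spin"):
        simulate_echo(sys, make_timing("press", 35.0), grid)


# ------------------------------------------------------------- spectra


def test_zero_fid_gives_zero_spectrum(grid):
    fid = FID(np.zeros(grid.n_points, dtype=complex), grid)
    spec = fid_to_spectrum(fid, 8.0)
    assert np.all(spec.values == 0)


def test_lorentzian_apodization_sets_fwhm(lib, grid):
    """The absorption (real) lineshape of an undamped singlet has FWHM equal
    to the requested apodization linewidth."""
    spec = fid_to_spectrum(simulate_echo(lib["Gly"], make_timing("press", 35.0), grid), 8.0)
    absn = spec.values.real
    peak = absn.argmax()
    half = absn[peak] / 2
    above = np.where(absn >= half)[0]
    lo = np.interp(half, absn[above[0] - 1 : above[0] + 1], spec.ppm[above[0] - 1 : above[0] + 1])
    hi = np.interp(
        half, absn[above[-1] + 1 : above[-1] - 1 : -1], spec.ppm[above[-1] + 1 : above[-1] - 1 : -1]
    )
    fwhm_hz = (hi - lo) * grid.f0_mhz
    bin_hz = grid.sweep_width_hz / grid.n_points
    assert abs(fwhm_hz - 8.0) <= bin_hz


def test_parseval_energy_preserved(lib, grid):
    fid = simulate_echo(lib["NAA"], make_timing("press", 35.0), grid)
    spec = fid_to_spectrum(fid, 8.0)
    t = grid.time_axis_s
    apod = np.exp(-np.pi * 8.0 * t)
    e_time = np.sum(np.abs(fid.samples * apod) ** 2)
    e_freq = np.sum(np.abs(spec.values) ** 2) / grid.n_points
    assert e_freq == pytest.approx(e_time, rel=1e-9)


def test_invalid_linewidth_and_lineshape_rejected(lib, grid):
    fid = simulate_echo(lib["Gly"], make_timing("press", 35.0), grid)
    with pytest.raises(ValueError):
        fid_to_spectrum(fid, 0.0)
    with pytest.raises(ValueError):
        fid_to_spectrum(fid, 8.0, lineshape="sinc")


def test_spectrum_axis_must_be_monotone():
    with pytest.raises(ValueError):
        Spectrum(np.array([1.0, 3.0, 2.0]), np.zeros(3, dtype=complex))


# ------------------------------------------------------------- basis sets


def test_gly_position_invariant_and_mi_pseudo_singlet(mi_gly_basis_factory):
    """Gly sits at 3.55 ppm at every TE; mI mimics it only at TE 135."""
    positions = []
    for te in (35.0, 135.0, 280.0):
        basis = mi_gly_basis_factory(te)
        gly = basis["Gly"]
        positions.append(float(gly.ppm[np.argmax(gly.values.real)]))
    assert max(positions) - min(positions) < 1e-9
    assert abs(positions[0] - GLY_PPM) < 0.01

    b135 = mi_gly_basis_factory(135.0)
    win = b135["mI"].window(3.4, 3.7)
    k = np.argmax(np.abs(win.values.real))
    assert win.values.real[k] > 0  # same polarity as Gly
    assert abs(win.ppm[k] - GLY_PPM) <= 0.03  # pseudo-singlet at the Gly position


def test_mi_polarity_opposite_to_gly_at_long_te(mi_gly_basis_factory):
    basis = mi_gly_basis_factory(280.0)
    mi = basis["mI"].window(3.45, 3.65).values.real
    gly = basis["Gly"].window(3.45, 3.65).values.real
    assert gly[np.argmax(np.abs(gly))] > 0
    assert mi[np.argmax(np.abs(mi))] < 0


def test_press_and_slaser_agree_for_singlets_but_not_for_mi(lib, grid):
    te = 135.0
    press = simulate_basis(lib, ["Gly", "mI"], make_timing("press", te), grid, 8.0)
    slaser = simulate_basis(lib, ["Gly", "mI"], make_timing("slaser", te), grid, 8.0)
    np.testing.assert_allclose(
        press["Gly"].values, slaser["Gly"].values, rtol=1e-8, atol=1e-9
    )
    a = press["mI"].window(3.0, 4.2).values.real
    b = slaser["mI"].window(3.0, 4.2).values.real
    rel_diff = np.linalg.norm(a - b) / np.linalg.norm(a)
    assert rel_diff > 1e-3  # strongly coupled evolution differs in detail
    assert np.corrcoef(a, b)[0, 1] > 0.5  # but the overall pattern is similar


def test_basis_members_share_axis_and_record_metadata(lib, grid):
    basis = simulate_basis(lib, ["mI", "Gly", "Cr"], make_timing("press", 135.0), grid, 8.0)
    assert basis.meta["te_ms"] == 135.0
    assert basis.meta["linewidth_hz"] == 8.0
    assert set(basis.names) == {"mI", "Gly", "Cr"}
    with pytest.raises(KeyError):
        simulate_basis(lib, ["Foo"], make_timing("press", 135.0), grid, 8.0)
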