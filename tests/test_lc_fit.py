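import numpy as np
import pytest

from spinfit import (
    AcquisitionGrid,
    BasisSet,
    FitModel,
    FitOptions,
    FitResult,
    Spectrum,
    fisher_uncertainty,
    fit_spectrum,
    make_timing,
    ratios_to_tcr,
    simulate_basis,
)

AMP_ONLY = FitOptions(
    baseline_order=None, fit_shift=False, fit_phase=False, fit_broadening=False
)


def _combine(basis, amplitudes):
    vals = sum(amplitudes[m] * basis[m].values for m in amplitudes)
    return Spectrum(basis.ppm, vals, {"f0_mhz": basis.meta["f0_mhz"]})


def test_noiseless_fit_recovers_amplitudes_exactly(small_basis_te35):
    truth = {"NAA": 1.0, "Cr": 1.0, "mI": 0.74, "Gly": 0.09, "Lac": 0.3}
    data = _combine(small_basis_te35, truth)
    fit = fit_spectrum(data, small_basis_te35)
    for name, c in truth.items():
        assert fit.model.amplitudes[name] == pytest.approx(c, rel=1e-6)
    assert abs(fit.model.global_shift_hz) < 1e-6
    assert abs(fit.model.extra_broadening_hz) < 1e-6


def test_crlb_scales_linearly_with_noise(small_basis_te35):
    truth = {"NAA": 1.0, "Cr": 1.0, "mI": 0.74, "Gly": 0.09, "Lac": 0.3}
    data = _combine(small_basis_te35, truth)
    fit = fit_spectrum(data, small_basis_te35)
    u1 = fisher_uncertainty(fit, data, sigma=1.0)
    u2 = fisher_uncertainty(fit, data, sigma=2.0)
    for name in truth:
        assert u2.crlb_percent[name] == pytest.approx(
            2.0 * u1.crlb_percent[name], rel=1e-9
        )


def test_disjoint_basis_members_have_zero_cmc(grid):
    """Two compact-support peaks that never overlap are uncorrelated."""
    ppm = grid.ppm_axis
    a = np.where(np.abs(ppm - 2.0) < 0.15, np.exp(-((ppm - 2.0) / 0.02) ** 2), 0.0)
    b = np.where(np.abs(ppm - 3.5) < 0.15, np.exp(-((ppm - 3.5) / 0.02) ** 2), 0.0)
    basis = BasisSet(
        spectra={
            "A": Spectrum(ppm, a.astype(complex), {"f0_mhz": grid.f0_mhz}),
            "B": Spectrum(ppm, b.astype(complex), {"f0_mhz": grid.f0_mhz}),
        },
        meta={"f0_mhz": grid.f0_mhz},
    )
    data = Spectrum(ppm, (2.0 * a + 0.5 * b).astype(complex), {"f0_mhz": grid.f0_mhz})
    fit = fit_spectrum(data, basis, AMP_ONLY)
    assert abs(fit.uncertainty.cmc_between("A", "B")) < 1e-6
    assert fit.model.amplitudes["A"] == pytest.approx(2.0, rel=1e-9)
    assert fit.model.amplitudes["B"] == pytest.approx(0.5, rel=1e-9)


def test_analytic_jacobian_matches_finite_differences(mi_gly_basis_factory):
    basis = mi_gly_basis_factory(135.0)
    data = _combine(basis, {"mI": 1.0, "Gly": 0.2})
    fit = fit_spectrum(data, basis, FitOptions(baseline_order=2))
    ctx = fit._ctx
    model = fit.model
    j, labels = ctx.jacobian(model)
    coef = np.concatenate(
        [[model.amplitudes[m] for m in ctx.names], model.baseline_coeffs]
    )

    def predict(df, phi, gam):
        return ctx.design(df, phi, gam) @ coef

    p0 = (model.global_shift_hz, model.phase0_rad, model.extra_broadening_hz)
    eps = 1e-5
    for label, k in [("shift", 0), ("phase", 1), ("broadening", 2)]:
        hi = list(p0)
        lo = list(p0)
        hi[k] += eps
        lo[k] -= eps
        fd = (predict(*hi) - predict(*lo)) / (2 * eps)
        col = j[:, labels.index(label)]
        assert np.abs(fd - col).max() <= 1e-5 * max(np.abs(col).max(), 1.0), label


def test_cmc_is_a_valid_correlation_matrix(lib, grid, small_basis_te35):
    from spinfit.synthetic import SpectrumSampler

    sampler = SpectrumSampler(
        {"NAA": 1.0, "Cr": 1.0, "mI": 0.74, "Gly": 0.09, "Lac": 0.3},
        make_timing("press", 35.0),
        grid,
        noise_sigma=0.05,
        lib=lib,
    )
    spec, _ = sampler.draw(42)
    fit = fit_spectrum(spec, small_basis_te35)
    cmc = fit.uncertainty.cmc
    assert np.allclose(cmc, cmc.T, atol=1e-12)
    assert np.allclose(np.diag(cmc), 1.0, atol=1e-12)
    assert np.linalg.eigvalsh(cmc).min() >= -1e-10
    assert np.all(np.abs(cmc) <= 1 + 1e-12)


@pytest.mark.parametrize("te,sign", [(35.0, -1.0), (280.0, 1.0)])
def test_mi_gly_cmc_sign_flips_with_te(mi_gly_basis_factory, te, sign):
    """Negative amplitude covariance at short TE (near-collinear bases),
    positive at long TE (opposite-polarity overlap). Cross-checked against a
    covariance computed directly from the basis design matrix."""
    basis = mi_gly_basis_factory(te)
    data = _combine(basis, {"mI": 1.0, "Gly": 0.2})
    fit = fit_spectrum(data, basis, AMP_ONLY)
    cmc = fit.uncertainty.cmc_between("mI", "Gly")
    assert np.sign(cmc) == sign

    # independent oracle: window the raw basis real parts, invert B^T B
    lo, hi = AMP_ONLY.window_ppm
    mask = (basis.ppm >= lo) & (basis.ppm <= hi)
    b = np.column_stack(
        [basis["mI"].values.real[mask], basis["Gly"].values.real[mask]]
    )
    cov = np.linalg.inv(b.T @ b)
    oracle = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
    assert cmc == pytest.approx(oracle, abs=1e-6)


def test_crlb_grows_with_linewidth_overlap(lib, grid):
    """Broader lines overlap more; Gly precision strictly degrades."""
    crlbs = []
    for lw in (4.0, 8.0, 16.0):
        basis = simulate_basis(lib, ["mI", "Gly"], make_timing("press", 35.0), grid, lw)
        data = _combine(basis, {"mI": 1.0, "Gly": 0.2})
        fit = fit_spectrum(data, basis, AMP_ONLY)
        crlbs.append(fisher_uncertainty(fit, data, sigma=1.0).crlb_percent["Gly"])
    assert crlbs[0] < crlbs[1] < crlbs[2]


def test_amplitude_recovery_bias_and_crlb_calibration(lib, grid, small_basis_te35):
    """On repeated noisy replicates the fitted singlet amplitudes are unbiased
    (<2%) and their empirical spread is within a factor 2 of the CRLB."""
    from spinfit.synthetic import SpectrumSampler

    truth = {"NAA": 1.0, "Cr": 1.0, "mI": 0.74, "Gly": 0.09, "Lac": 0.3}
    sampler = SpectrumSampler(
        truth, make_timing("press", 35.0), grid, noise_sigma=0.02, lib=lib
    )
    est = {"NAA": [], "Cr": []}
    crlb_pred = {"NAA": [], "Cr": []}
    for k in range(100):
        spec, _ = sampler.draw(10_000 + k)
        fit = fit_spectrum(spec, small_basis_te35)
        for m in est:
            est[m].append(fit.model.amplitudes[m])
            crlb_pred[m].append(fit.uncertainty.crlb_percent[m])
    for m in est:
        vals = np.asarray(est[m])
        bias = abs(vals.mean() - truth[m]) / truth[m]
        assert bias < 0.02, m
        predicted_sd = np.mean(crlb_pred[m]) / 100.0 * truth[m]
        ratio = vals.std() / predicted_sd
        assert 0.5 < ratio < 2.0, (m, ratio)


def test_ratio_table_arithmetic():
    def result_with(amps):
        return FitResult(
            model=FitModel(amplitudes=amps),
            residual=np.zeros(1),
            window_ppm_axis=np.zeros(1),
            uncertainty=None,
            ratios={},
            cost=0.0,
        )

    r = ratios_to_tcr(result_with({"mI": 2.0, "Cr": 1.0, "PCr": 1.0, "Gly": 1.0}))
    assert r["mI/tCr"] == pytest.approx(1.0)
    assert r["mI/Gly"] == pytest.approx(2.0)

    r = ratios_to_tcr(result_with({"mI": 2.0, "Cr": 1.0, "PCr": 1.0, "Gly": 0.0}))
    assert r["mI/Gly"] is None  # undefined, the table's em-dash

    r = ratios_to_tcr(result_with({"mI": 0.0, "Cr": 0.0, "PCr": 0.0, "Gly": 0.0}))
    assert r["mI/tCr"] is None and r["mI/Gly"] is None


def test_window_outside_axis_is_rejected(small_basis_te35):
    data = _combine(small_basis_te35, {"NAA": 1.0, "Cr": 1.0, "mI": 0.5, "Gly": 0.1, "Lac": 0.2})
    with pytest.raises(ValueError, match="window"):
        fit_spectrum(data, small_basis_te35, FitOptions(window_ppm=(-20.0, 4.2)))
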