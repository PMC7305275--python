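"""Analytic timing-kernel properties against quadrature and closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from tofpet import (
    CrystalTimingParams,
    ConvolvedTimingParams,
    CTRKernel,
    ConvolvedKernel,
    GaussianKernel,
    GaussianTimingParams,
    LaplaceKernel,
    bin_probabilities,
    conv_cdf,
    conv_pdf,
    ctr_cdf,
    ctr_pdf,
    kernel_fwhm,
    kernel_from_config,
    kernel_to_config,
    laplace_cdf,
    laplace_pdf,
    truncated_exp_pdf,
)
from tofpet.kernels import conv_pdf_reference, ctr_pdf_oracle
from tofpet.timing_sim import TimingSimConfig, sample_time_differences, truncated_exp_var


def crystal_for_lamT(lamT: float, L: float = 20.0) -> CrystalTimingParams:
    """Crystal with the requested opacity lambda*T at fixed length."""
    c = 0.2998
    return CrystalTimingParams(L=L, beta=lamT / (L / c) / c)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


def test_crystal_params_derived_quantities_exact():
    p = CrystalTimingParams(L=20.0, beta=0.087, c=0.2998)
    assert p.T == 20.0 / 0.2998
    assert p.lam == 0.087 * 0.2998


@pytest.mark.parametrize("bad", [dict(L=0), dict(L=-3), dict(L=10, beta=0), dict(L=10, c=-1)])
def test_crystal_params_reject_nonpositive(bad):
    with pytest.raises(ValueError):
        CrystalTimingParams(**bad)


def test_gaussian_params_fwhm_ratio():
    g = GaussianTimingParams(sigma=10.0)
    assert g.fwhm / g.sigma == pytest.approx(2.35482, abs=1e-5)
    with pytest.raises(ValueError):
        GaussianTimingParams(sigma=0.0)


# ---------------------------------------------------------------------------
# truncated exponential
# ---------------------------------------------------------------------------


def test_truncated_exp_pdf_support_and_mass(crystal20):
    T = crystal20.T
    assert truncated_exp_pdf(-1.0, crystal20) == 0.0
    assert truncated_exp_pdf(T + 1.0, crystal20) == 0.0
    mass, _ = integrate.quad(lambda t: truncated_exp_pdf(t, crystal20), 0, T, limit=200)
    assert mass == pytest.approx(1.0, abs=1e-9)


def test_truncated_exp_pdf_long_crystal_limit():
    p = crystal_for_lamT(60.0)  # lam*T > 50: truncation factor ~ exp(-60)
    lam = p.lam
    for t in (0.1 * p.T, 0.5 * p.T):
        assert truncated_exp_pdf(t, p) == pytest.approx(lam * math.exp(-lam * t), rel=1e-12)


def test_truncated_exp_pdf_rejects_nonfinite(crystal20):
    with pytest.raises(ValueError):
        truncated_exp_pdf(np.nan, crystal20)


# ---------------------------------------------------------------------------
# CTR kernel
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("lamT", [0.5, 1.0, 2.0, 3.5, 5.3])
def test_ctr_pdf_matches_joint_integration_oracle(lamT):
    """Closed form equals the 2-D joint-density integration on a grid (1e-8)."""
    p = crystal_for_lamT(lamT)
    grid = np.linspace(-p.T, p.T, 50)
    for d in grid:
        assert ctr_pdf(d, p) == pytest.approx(ctr_pdf_oracle(d, p), abs=1e-8)


def test_ctr_pdf_boundary_symmetry_and_mass(crystal20):
    T = crystal20.T
    assert ctr_pdf(T, crystal20) == 0.0
    assert ctr_pdf(-T, crystal20) == 0.0
    d = np.linspace(-T, T, 101)
    np.testing.assert_allclose(ctr_pdf(d, crystal20), ctr_pdf(-d, crystal20), rtol=0, atol=0)
    mass, _ = integrate.quad(lambda x: ctr_pdf(x, crystal20), -T, T, limit=300)
    assert mass == pytest.approx(1.0, abs=1e-9)


def test_ctr_pdf_oracle_normalises_and_is_symmetric(crystal20):
    T = crystal20.T
    mass, _ = integrate.quad(lambda d: ctr_pdf_oracle(d, crystal20), -T, T, limit=100)
    assert mass == pytest.approx(1.0, abs=1e-6)
    assert ctr_pdf_oracle(0.3 * T, crystal20) == pytest.approx(ctr_pdf_oracle(-0.3 * T, crystal20), rel=1e-12)
    assert ctr_pdf_oracle(1.5 * T, crystal20) == 0.0


def test_ctr_cdf_midpoint_boundaries_and_derivative(crystal20):
    T = crystal20.T
    assert ctr_cdf(0.0, crystal20) == 0.5
    assert ctr_cdf(-T, crystal20) == 0.0
    assert ctr_cdf(T, crystal20) == 1.0
    assert ctr_cdf(-T - 5, crystal20) == 0.0
    assert ctr_cdf(T + 5, crystal20) == 1.0
    grid = np.linspace(-0.99 * T, 0.99 * T, 201)
    h = 1e-4
    fd = (ctr_cdf(grid + h, crystal20) - ctr_cdf(grid - h, crystal20)) / (2 * h)
    np.testing.assert_allclose(fd, ctr_pdf(grid, crystal20), atol=1e-6)


def test_ctr_survives_extreme_opacity():
    p = crystal_for_lamT(800.0, L=40.0)
    assert np.isfinite(ctr_pdf(0.0, p))
    assert ctr_pdf(0.0, p) == pytest.approx(laplace_pdf(0.0, p.lam), rel=1e-12)
    assert ctr_cdf(0.3 * p.T, p) == pytest.approx(laplace_cdf(0.3 * p.T, p.lam), abs=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    lamT=st.floats(0.1, 30.0),
    frac=st.floats(-1.2, 1.2),
)
def test_ctr_cdf_is_a_distribution_function(lamT, frac):
    p = crystal_for_lamT(lamT)
    d = frac * p.T
    val = ctr_cdf(d, p)
    assert 0.0 <= val <= 1.0
    assert ctr_cdf(d + 0.01 * p.T, p) >= val
    assert ctr_pdf(d, p) >= 0.0


# ---------------------------------------------------------------------------
# Laplace limit
# ---------------------------------------------------------------------------


def test_laplace_closed_forms():
    lam = 0.03
    assert laplace_pdf(0.0, lam) == lam / 2
    assert laplace_cdf(0.0, lam) == 0.5
    assert laplace_cdf(np.inf, lam) == 1.0
    assert laplace_cdf(-np.inf, lam) == 0.0
    with pytest.raises(ValueError):
        laplace_pdf(0.0, -1.0)


@pytest.mark.parametrize("lamT", [30.0, 40.0])
def test_ctr_converges_to_laplace_for_long_crystals(lamT):
    p = crystal_for_lamT(lamT)
    d = np.linspace(-p.T, p.T, 2001)
    gap = np.max(np.abs(ctr_pdf(d, p) - laplace_pdf(d, p.lam)))
    assert gap < 1e-6 * p.lam


def test_laplace_gap_decays_exponentially_in_lamT():
    lam = 0.026
    gaps = []
    for lamT in (5.0, 10.0, 15.0, 20.0):
        # same absorption rate, increasing crystal length
        p = CrystalTimingParams(L=(lamT / lam) * 0.2998, beta=lam / 0.2998)
        d = np.linspace(-p.T, p.T, 1501)
        gaps.append(np.max(np.abs(ctr_pdf(d, p) - laplace_pdf(d, lam))))
    ratios = np.array(gaps[:-1]) / np.array(gaps[1:])
    expected = math.exp(5.0)  # T grows by 5/lam each step
    assert np.all(ratios > 0.3 * expected)
    assert np.all(ratios < 3.0 * expected)


# ---------------------------------------------------------------------------
# convolution kernel
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("lamT,siglam", [(1.0, 0.5), (3.0, 1.0), (6.0, 2.0)])
def test_conv_pdf_matches_bruteforce_convolution(lamT, siglam):
    lam = 0.03
    T, sig = lamT / lam, siglam / lam
    cp = ConvolvedTimingParams(lam=lam, T=T, sigma=sig)
    pc = crystal_for_lamT(lamT, L=T * 0.2998)
    d_grid = np.linspace(-T - 4 * sig, T + 4 * sig, 31)

    def numeric(d):
        f = lambda x: ctr_pdf(x, pc) * math.exp(-0.5 * ((d - x) / sig) ** 2) / (sig * math.sqrt(2 * math.pi))
        val, _ = integrate.quad(f, -T, T, limit=400)
        return val

    oracle = np.array([numeric(d) for d in d_grid])
    np.testing.assert_allclose(conv_pdf(d_grid, cp), oracle, atol=1e-7)
    # and the raw closed erf form agrees at these moderate parameters
    np.testing.assert_allclose(conv_pdf(d_grid, cp), conv_pdf_reference(d_grid, cp), atol=1e-10)


def test_conv_pdf_symmetry_and_small_sigma_limit(crystal20):
    cp = ConvolvedTimingParams(lam=crystal20.lam, T=crystal20.T, sigma=24.0)
    d = np.linspace(-200, 200, 401)
    np.testing.assert_array_equal(conv_pdf(d, cp), conv_pdf(-d, cp))
    tiny = ConvolvedTimingParams(lam=crystal20.lam, T=crystal20.T, sigma=1e-3)
    g = np.linspace(-0.9 * crystal20.T, 0.9 * crystal20.T, 121)
    np.testing.assert_allclose(conv_pdf(g, tiny), ctr_pdf(g, crystal20), atol=1e-6)


def test_conv_pdf_gaussian_limit_matched_variance(crystal20):
    """For sigma*lam >= 10 the kernel is Gaussian with variance sigma^2 + Var_CTR."""
    lam, T = crystal20.lam, crystal20.T
    sig = 10.0 / lam
    cp = ConvolvedTimingParams(lam=lam, T=T, sigma=sig)
    stot = math.sqrt(sig**2 + 2.0 * truncated_exp_var(L=T, beta=lam))
    g = np.linspace(-6 * stot, 6 * stot, 401)
    ref = GaussianKernel(sigma=stot).pdf(g)
    assert np.max(np.abs(conv_pdf(g, cp) - ref)) < 1e-4 * ref.max()


def test_conv_variance_identities(crystal20):
    lam, T = crystal20.lam, crystal20.T
    var_ctr, _ = integrate.quad(lambda d: d * d * ctr_pdf(d, crystal20), -T, T, limit=300)
    assert var_ctr == pytest.approx(2.0 * truncated_exp_var(L=T, beta=lam), rel=1e-10)
    cp = ConvolvedTimingParams(lam=lam, T=T, sigma=24.0)
    var_conv, _ = integrate.quad(lambda d: d * d * conv_pdf(d, cp), -600, 600, limit=400)
    assert var_conv == pytest.approx(var_ctr + 24.0**2, rel=1e-9)


def test_conv_cdf_properties_and_quadrature(crystal20):
    cp = ConvolvedTimingParams(lam=crystal20.lam, T=crystal20.T, sigma=24.0)
    assert conv_cdf(0.0, cp) == pytest.approx(0.5, abs=1e-8)
    lo = -crystal20.T - 8 * 24.0
    assert conv_cdf(lo, cp) == pytest.approx(0.0, abs=1e-8)
    assert conv_cdf(-lo, cp) == pytest.approx(1.0, abs=1e-8)
    grid = np.linspace(lo, -lo, 301)
    assert np.all(np.diff(conv_cdf(grid, cp)) >= 0)
    for d in (-100.0, -20.0, 35.0, 150.0):
        ref, _ = integrate.quad(lambda x: conv_pdf(x, cp), lo, d, limit=400)
        assert conv_cdf(d, cp) == pytest.approx(ref, abs=1e-8)


def test_conv_cdf_matches_simulated_blurred_differences(crystal20):
    """Kolmogorov distance to the empirical CDF of 1e6 blurred draws < 3e-3."""
    from scipy.stats import kstest

    cfg = TimingSimConfig(crystal=crystal20, n_events=1_000_000, seed=404, fwhm_add=40.0)
    dt = sample_time_differences(cfg)
    kern = ConvolvedKernel.from_crystal(crystal20, cfg.sigma_difference)
    assert kstest(dt, lambda x: kern.cdf(x)).statistic < 3e-3


def test_conv_overflow_reports_parameters():
    bad = ConvolvedTimingParams(lam=1.0, T=1e5, sigma=10.0)  # lam*T = 1e5
    with pytest.raises(FloatingPointError, match="lam"):
        conv_pdf(0.0, bad)


# ---------------------------------------------------------------------------
# FWHM and binning utilities
# ---------------------------------------------------------------------------


def test_kernel_fwhm_closed_forms(crystal20):
    assert kernel_fwhm(GaussianKernel(sigma=10.0)) == pytest.approx(23.5482, abs=1e-4)
    lam = 0.03
    assert kernel_fwhm(LaplaceKernel(lam=lam)) == pytest.approx(2 * math.log(2) / lam, rel=1e-9)
    # dense-grid oracle for the CTR kernel
    k = CTRKernel(crystal20)
    grid = np.linspace(0, crystal20.T, 400_001)
    vals = k.pdf(grid)
    half = 0.5 * vals[0]
    crossing = grid[np.argmax(vals < half)]
    assert k.fwhm() == pytest.approx(2 * crossing, abs=1e-3)
    assert k.fwhm() == pytest.approx(2 * crossing, rel=1e-5)


def test_kernel_fwhm_rejects_bimodal():
    class Bimodal(GaussianKernel):
        def pdf(self, d):
            return 0.5 * (GaussianKernel(sigma=1.0, mu=-5.0).pdf(d) + GaussianKernel(sigma=1.0, mu=5.0).pdf(d))

    with pytest.raises(ValueError, match="unimodal"):
        kernel_fwhm(Bimodal(sigma=1.0))


def test_bin_probabilities_telescoping_and_quadrature(crystal20):
    k = CTRKernel(crystal20)
    T = crystal20.T
    edges = np.linspace(-T, T, 41)
    masses = bin_probabilities(k, edges)
    assert np.all(masses >= 0)
    assert masses.sum() == pytest.approx(1.0, abs=1e-9)
    assert bin_probabilities(k, np.array([-T, T]))[0] == pytest.approx(1.0, abs=1e-12)
    for i in (0, 10, 20, 35):
        ref, _ = integrate.quad(lambda d: ctr_pdf(d, crystal20), edges[i], edges[i + 1], limit=200)
        assert masses[i] == pytest.approx(ref, abs=1e-8)
    with pytest.raises(ValueError):
        bin_probabilities(k, np.array([0.0, -1.0, 1.0]))


@pytest.mark.parametrize(
    "kernel",
    [
        CTRKernel(CrystalTimingParams(L=20.0)),
        LaplaceKernel(lam=0.026),
        GaussianKernel(sigma=17.0, mu=1.5),
        ConvolvedKernel(ConvolvedTimingParams(lam=0.026, T=66.7, sigma=24.0)),
    ],
    ids=["ctr", "laplace", "gaussian", "conv"],
)
def test_kernel_config_roundtrip(kernel):
    cfg = kernel_to_config(kernel)
    back = kernel_from_config(cfg)
    d = np.linspace(-80, 80, 33)
    np.testing.assert_allclose(back.pdf(d), kernel.pdf(d), rtol=1e-12)
    np.testing.assert_allclose(back.cdf(d), kernel.cdf(d), rtol=0, atol=1e-12)
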