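import math

import numpy as np
import pytest

from phasemap.energy_model import KB
from phasemap.tail_model import (
    cdf_from_hist,
    corrected_mu_ex,
    detect_outlier,
    estimate_umin_blocks,
    fit_log_cdf,
    umin_from_fcf,
)
from phasemap.widom_mu import EnergyHistogram, mu_ex_raw


def _hist(bin_width, origin, counts, f_cf=1.0, n_total=None):
    counts = np.asarray(counts, dtype=np.int64)
    m_cf = int(counts.sum())
    return EnergyHistogram(
        bin_width=bin_width, origin=origin, counts=counts, f_cf=f_cf,
        m_cf=m_cf, n_total=n_total or m_cf, n_configs=1, n_orientations=1,
    )


def _exponential_hist(alpha, u_min, bin_width=0.016, A=1e13, u_max=0.0):
    """Histogram whose CDF is exactly A*e^{alpha*U} on [u_min, 0], plus a
    bulk bin at U=0 so the total is dominated by near-zero energies.
    A ~ 1e13 puts the CDF=1e4 level near U = -12, mimicking production
    scale so bin-count rounding never distorts the fit window."""
    lo = int(round(u_min / bin_width))
    idx = np.arange(lo, 1)
    u_hi = (idx + 0.5) * bin_width
    u_lo = (idx - 0.5) * bin_width
    mass = A * (np.exp(alpha * np.minimum(u_hi, 0.0)) - np.exp(alpha * np.maximum(u_lo, u_min)))
    counts = np.rint(np.clip(mass, 0.0, None)).astype(np.int64)
    counts[-1] += int(50 * A)  # bulk at U ~ 0
    return _hist(bin_width, lo, counts)


class TestCdf:
    def test_single_bin_step(self):
        h = _hist(0.5, -4, [7])
        u, c = cdf_from_hist(h)
        assert list(u) == [-2.0]
        assert list(c) == [7.0]

    def test_total_is_mcf(self):
        h = _hist(0.5, -4, [1, 0, 2, 5])
        u, c = cdf_from_hist(h)
        assert c[-1] == h.m_cf

    def test_exponential_cdf_log_linear(self):
        alpha = 1.7
        h = _exponential_hist(alpha, u_min=-16.0)
        u, c = cdf_from_hist(h)
        sel = (u > -12.0) & (u < -4.0)
        slope = np.polyfit(u[sel], np.log(c[sel]), 1)[0]
        assert slope == pytest.approx(alpha, rel=0.01)


class TestFitLogCdf:
    @pytest.mark.parametrize("alpha", [1.5, 1.7, 2.1])
    def test_recovers_slope(self, alpha):
        h = _exponential_hist(alpha, u_min=-16.0)
        model = fit_log_cdf(cdf_from_hist(h), window=(-11.0, -4.0))
        assert model.alpha == pytest.approx(alpha, rel=0.02)

    def test_linear_input_extrapolates_exactly(self):
        u = np.linspace(-10.0, -4.0, 40)
        lnc = 30.0 + 1.7 * u
        model = fit_log_cdf((u, np.exp(lnc)), window=(-10.0, -4.0))
        for probe in (-11.0, -14.0, -20.0):
            assert model.predict_log_cdf(probe)[0] == pytest.approx(30.0 + 1.7 * probe, abs=1e-8)

    def test_sparse_window_errors(self):
        u = np.array([-5.0, -4.5])
        with pytest.raises(ValueError):
            fit_log_cdf((u, np.array([10.0, 100.0])), window=(-5.0, -4.0))


class TestUminFromFcf:
    def test_closed_form_exponential(self):
        # exact exponential CDF A e^{alpha U}: U_min = ln(f^gamma / A) / alpha
        alpha, A = 1.7, 1e7
        u = np.linspace(-9.0, -4.0, 60)
        model = fit_log_cdf((u, A * np.exp(alpha * u)), window=(-9.0, -4.0))
        f_cf = 0.7
        expected = (0.25 * math.log(f_cf) - math.log(A)) / alpha
        assert umin_from_fcf(f_cf, model) == pytest.approx(expected, rel=1e-6)

    def test_monotone_in_fcf(self):
        alpha, A = 1.7, 1e7
        u = np.linspace(-6.0, -4.0, 60)
        model = fit_log_cdf((u, A * np.exp(alpha * u)), window=(-6.0, -4.0))
        u1 = umin_from_fcf(1.0, model)
        u2 = umin_from_fcf(0.5, model)
        # lower clash-free fraction (denser solution) allows a deeper bound
        assert u2 < u1

    def test_fcf_one_hits_cdf_one(self):
        alpha, A = 2.0, 1e6
        u = np.linspace(-6.0, -4.0, 50)
        model = fit_log_cdf((u, A * np.exp(alpha * u)), window=(-6.0, -4.0))
        assert umin_from_fcf(1.0, model) == pytest.approx(-math.log(A) / alpha, rel=1e-6)


class TestUminBlocks:
    @pytest.mark.parametrize("alpha", [1.5, 1.7, 2.1])
    def test_recovers_bound_from_block_minima(self, alpha):
        """Samples from the exact truncated-exponential model: the fitted
        asymptote recovers the true bound U_min within 5%."""
        rng = np.random.default_rng(int(alpha * 100))
        # the bound must be reachable at the largest block size:
        # exp(alpha*|u_min|) = e^9 ~ 8e3 samples saturates the minima
        u_min = -9.0 / alpha
        n_ori, per_ori = 512, 400
        raw = rng.random((n_ori, per_ori))
        # inverse CDF of density ~ alpha e^{alpha u} on [u_min, 0]
        z = raw * (1.0 - math.exp(alpha * u_min)) + math.exp(alpha * u_min)
        u = np.log(z) / alpha
        mins = u.min(axis=1)
        m_vals = [1, 2, 4, 8, 16, 32, 64, 128]
        u_hat = [
            float(np.mean(mins.reshape(-1, m).min(axis=1))) for m in m_vals
        ]
        fit = estimate_umin_blocks({"c": (np.array(m_vals, float), np.array(u_hat))})
        assert fit.u_min["c"] == pytest.approx(u_min, rel=0.05)
        assert 0.6 <= fit.delta["c"] <= 1.0

    def test_plateau_data(self):
        m = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        u_hat = np.full(5, -9.3)
        fit = estimate_umin_blocks({"c": (m, u_hat)})
        assert fit.u_min["c"] == pytest.approx(-9.3, abs=0.05)
        assert fit.E["c"] == pytest.approx(0.0, abs=0.05)

    def test_shared_d_across_concentrations(self):
        m = np.array([1.0, 4.0, 16.0, 64.0, 256.0])
        data = {}
        for i, (um, e) in enumerate([(-10.0, 3.0), (-12.0, 4.0)]):
            data[i] = (m, um + e / (1.0 + (m / 8.0) ** 0.8))
        fit = estimate_umin_blocks(data)
        assert fit.u_min[0] == pytest.approx(-10.0, rel=0.02)
        assert fit.u_min[1] == pytest.approx(-12.0, rel=0.02)
        assert fit.D == pytest.approx(8.0, rel=0.1)


class TestCorrectedMu:
    def test_exponential_histogram_correction_is_noop(self):
        h = _exponential_hist(1.7, u_min=-12.0)
        model = fit_log_cdf(cdf_from_hist(h), window=(-10.0, -4.0))
        T = 271.0
        raw = mu_ex_raw(h, T).beta_mu_ex
        corr = corrected_mu_ex(h, model, -12.0, T).beta_mu_ex
        assert corr == pytest.approx(raw, abs=2e-3)

    def test_outlier_insensitivity(self):
        """A single spurious very-low-energy count moves the raw estimate but
        barely touches the corrected one."""
        T = 260.0
        beta = 1.0 / (KB * T)
        h_clean = _exponential_hist(1.7, u_min=-12.0)
        # one spurious count at U = -18, well below the true bound
        new_origin = int(round(-18.0 / h_clean.bin_width))
        shift = h_clean.origin - new_origin
        counts_out = np.zeros(shift + len(h_clean.counts), dtype=np.int64)
        counts_out[shift:] = h_clean.counts
        counts_out[0] += 1
        h_out = _hist(h_clean.bin_width, new_origin, counts_out)
        model = fit_log_cdf(cdf_from_hist(h_out), window=(-10.0, -4.0))
        raw_clean = mu_ex_raw(h_clean, T).beta_mu_ex
        raw_out = mu_ex_raw(h_out, T).beta_mu_ex
        corr_out = corrected_mu_ex(h_out, model, -12.0, T).beta_mu_ex
        assert abs(raw_out - raw_clean) > 0.1
        assert abs(corr_out - mu_ex_raw(h_clean, T).beta_mu_ex) < 5e-3

    def test_beta_zero_limit_is_steric(self):
        h = _exponential_hist(1.7, u_min=-12.0, A=1e6)
        h = _hist(h.bin_width, h.origin, h.counts, f_cf=0.9, n_total=int(h.m_cf / 0.9))
        model = fit_log_cdf(cdf_from_hist(h), window=(-10.0, -4.0))
        very_hot = 1.0 / (KB * 1e-6)
        corr = corrected_mu_ex(h, model, -14.0, very_hot).beta_mu_ex
        assert corr == pytest.approx(-math.log(0.9), abs=1e-5)

    def test_mass_conservation(self):
        h = _exponential_hist(2.1, u_min=-11.0)
        model = fit_log_cdf(cdf_from_hist(h), window=(-9.0, -4.0))
        # reconstruct the corrected weights the same way corrected_mu_ex does,
        # via the beta->0 limit: sum of weights = exp(log_sum) at beta=0
        very_hot = 1.0 / (KB * 1e-9)
        corr = corrected_mu_ex(h, model, -13.0, very_hot).beta_mu_ex
        # f_cf = 1 here, so beta*mu_ex(beta->0) = -ln(total/M_CF)
        assert math.exp(-corr) == pytest.approx(1.0, rel=1e-3)


class TestOutlierDetection:
    def test_matches_expectation(self):
        alpha, A = 1.7, 1e7
        u = np.linspace(-9.0, -4.0, 60)
        model = fit_log_cdf((u, A * np.exp(alpha * u)), window=(-9.0, -4.0))
        expected = -math.log(A) / alpha  # CDF = 1 point
        assert not detect_outlier(model, expected)
        assert not detect_outlier(model, expected - 0.99)
        assert detect_outlier(model, expected - 1.5)
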