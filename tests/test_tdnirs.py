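"""TD-NIRS inversion: IRF metrics, convolution fit, chromophores, phantom QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsdcs import (
    OpticalProperties,
    compute_chromophores,
    compute_irf_metrics,
    compute_phantom_effective,
    fit_dtof,
    interpolate_props,
)
from nirsdcs.extinction import mua_from_chromophores
from nirsdcs.synthetic import PHANTOM_PROPS, delta_irf, generate_dtof
from nirsdcs.tdnirs import dtof_objective


def _gauss_hist(edges, center, sigma_ns, amp=1e5):
    centers = 0.5 * (edges[:-1] + edges[1:])
    return amp * np.exp(-0.5 * ((centers - center) / sigma_ns) ** 2)


class TestIRFMetrics:
    def test_symmetric_gaussian_barycenter(self, spec):
        rec = compute_irf_metrics(spec.time_edges_ns, _gauss_hist(spec.time_edges_ns, 3.9, 0.1))
        assert rec.barycenter_ns == pytest.approx(3.9, abs=1e-3)

    def test_gaussian_fwhm_closed_form(self, spec):
        """sigma = 100 ps -> FWHM = 2 sqrt(2 ln 2) * 100 = 235.48 ps."""
        rec = compute_irf_metrics(spec.time_edges_ns, _gauss_hist(spec.time_edges_ns, 3.9, 0.1))
        bin_ps = 1000.0 * np.diff(spec.time_edges_ns).mean()
        assert abs(rec.fwhm_ps - 235.482) < bin_ps

    def test_translation_equivariance(self, spec):
        h = _gauss_hist(spec.time_edges_ns, 3.9, 0.1)
        shift_bins = 54  # ~0.5 ns on the default grid
        shifted = np.roll(h, shift_bins)
        a = compute_irf_metrics(spec.time_edges_ns, h)
        b = compute_irf_metrics(spec.time_edges_ns, shifted)
        dt = shift_bins * np.diff(spec.time_edges_ns).mean()
        assert b.barycenter_ns - a.barycenter_ns == pytest.approx(dt, abs=1e-9)
        assert b.fwhm_ps == pytest.approx(a.fwhm_ps, abs=1e-6)

    def test_all_zero_histogram_rejected(self, spec):
        with pytest.raises(ValueError):
            compute_irf_metrics(spec.time_edges_ns, np.zeros(spec.time_edges_ns.size - 1))


class TestFitDtof:
    def test_noiseless_inverse_identity(self, spec, geom):
        """Noiseless self-generated curve with a delta IRF returns the
        generating properties to optimizer tolerance."""
        truth = OpticalProperties(0.17, 11.0, 685.0)
        d = generate_dtof(truth, geom, spec, delta_irf(spec.time_edges_ns),
                          dark_rate_cps=0.0, noise=False)
        d.background_window = (0, 0)  # the curve starts at t=0 with a delta IRF
        irf = compute_irf_metrics(spec.time_edges_ns, delta_irf(spec.time_edges_ns),
                                  background_bins=0)
        props, diag = fit_dtof(d, irf, geom)
        assert diag.converged
        assert props.mua == pytest.approx(truth.mua, rel=1e-4)
        assert props.musp == pytest.approx(truth.musp, rel=1e-4)

    def test_phantom_preset_recovery(self, spec, geom, irf_shape, irf_record):
        """20 seeded phantom DTOFs at 1e6 counts: mean recovered mua within 5%."""
        props = PHANTOM_PROPS[685.0]
        muas = []
        for s in range(20):
            d = generate_dtof(props, geom, spec, irf_shape,
                              rng=np.random.default_rng(s + 1))
            fit, _ = fit_dtof(d, irf_record, geom)
            muas.append(fit.mua)
        assert abs(np.mean(muas) - props.mua) / props.mua < 0.05

    def test_grid_search_oracle_agreement(self, spec, geom, irf_shape, irf_record):
        """Brute-force grid minimization of the same objective lands within
        one grid cell of the optimizer's solution, on 5 random instances."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            truth = OpticalProperties(rng.uniform(0.1, 0.3), rng.uniform(7.0, 14.0), 685.0)
            d = generate_dtof(truth, geom, spec, irf_shape, rng=rng)
            fit, _ = fit_dtof(d, irf_record, geom)
            mua_grid = np.linspace(0.8 * truth.mua, 1.2 * truth.mua, 15)
            musp_grid = np.linspace(0.8 * truth.musp, 1.2 * truth.musp, 15)
            obj = np.array(
                [[dtof_objective(a, s, d, irf_record, geom) for s in musp_grid] for a in mua_grid]
            )
            i, j = np.unravel_index(np.argmin(obj), obj.shape)
            assert abs(mua_grid[i] - fit.mua) <= np.diff(mua_grid)[0]
            assert abs(musp_grid[j] - fit.musp) <= np.diff(musp_grid)[0]

    def test_dispersion_decreases_with_counts(self, spec, geom, irf_shape, irf_record):
        sds = []
        for counts in (1e5, 1e6, 1e7):
            fits = []
            for s in range(8):
                d = generate_dtof(PHANTOM_PROPS[685.0], geom, spec, irf_shape,
                                  total_counts=counts, rng=np.random.default_rng(100 + s))
                fits.append(fit_dtof(d, irf_record, geom)[0].mua)
            sds.append(np.std(fits))
        assert sds[0] > sds[1] > sds[2]

    def test_empty_histogram_rejected(self, spec, geom, irf_record):
        from nirsdcs.tdnirs import DTOFHistogram

        d = DTOFHistogram(spec.time_edges_ns, np.zeros(spec.time_edges_ns.size - 1), 685.0)
        with pytest.raises(ValueError):
            fit_dtof(d, irf_record, geom)

    def test_dynamic_range_definition(self, spec, geom, irf_shape, irf_record):
        """DR = max(DTOF) / sd(background window)."""
        d = generate_dtof(PHANTOM_PROPS[685.0], geom, spec, irf_shape,
                          rng=np.random.default_rng(2))
        _, diag = fit_dtof(d, irf_record, geom)
        b0, b1 = d.background_window
        expected = d.counts.max() / d.counts[b0:b1].std(ddof=1)
        assert diag.dynamic_range == pytest.approx(expected)


class TestChromophores:
    def test_pure_oxyhemoglobin_is_fully_saturated(self):
        mua685 = mua_from_chromophores(50.0, 0.0, 685.0)
        mua828 = mua_from_chromophores(50.0, 0.0, 828.0)
        state = compute_chromophores(
            OpticalProperties(mua685, 10.0, 685.0), OpticalProperties(mua828, 10.0, 828.0)
        )
        assert state.sto2_pct == pytest.approx(100.0, abs=1e-9)

    @given(
        hbo=st.floats(1.0, 150.0),
        hbr=st.floats(1.0, 150.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_round_trip_identity(self, hbo, hbr):
        """(HbO, HbR) -> mua -> inversion recovers the concentrations."""
        p685 = OpticalProperties(mua_from_chromophores(hbo, hbr, 685.0), 10.0, 685.0)
        p828 = OpticalProperties(mua_from_chromophores(hbo, hbr, 828.0), 10.0, 828.0)
        state = compute_chromophores(p685, p828)
        assert state.hbo_um == pytest.approx(hbo, rel=1e-9)
        assert state.hbr_um == pytest.approx(hbr, rel=1e-9)

    def test_hand_solved_two_by_two(self):
        """Independent hand solve of the 2x2 system (Cramer's rule) matches."""
        from nirsdcs.extinction import LN10, EXTINCTION_HEMOGLOBIN

        mua685, mua828 = 0.22, 0.23
        e1o, e1r = EXTINCTION_HEMOGLOBIN[685.0]
        e2o, e2r = EXTINCTION_HEMOGLOBIN[828.0]
        k = LN10 * 1e-6
        det = (e1o * e2r - e1r * e2o) * k * k
        hbo = (mua685 * k * e2r - k * e1r * mua828) / det
        hbr = (k * e1o * mua828 - mua685 * k * e2o) / det
        state = compute_chromophores(
            OpticalProperties(mua685, 10.0, 685.0), OpticalProperties(mua828, 10.0, 828.0)
        )
        assert state.hbo_um == pytest.approx(hbo, rel=1e-12)
        assert state.hbr_um == pytest.approx(hbr, rel=1e-12)

    def test_group_mean_absorption_gives_literature_scale_thb(self):
        """Healthy group-mean mua (0.22, 0.23 cm^-1) inverts to ~113 uM total
        hemoglobin, consistent with reported cohort values within 15%."""
        state = compute_chromophores(
            OpticalProperties(0.22, 10.0, 685.0), OpticalProperties(0.23, 10.0, 828.0)
        )
        assert abs(state.thb_um - 112.88) / 112.88 < 0.15

    def test_linearity_scaling(self):
        a = compute_chromophores(
            OpticalProperties(0.2, 10.0, 685.0), OpticalProperties(0.21, 10.0, 828.0)
        )
        b = compute_chromophores(
            OpticalProperties(0.4, 10.0, 685.0), OpticalProperties(0.42, 10.0, 828.0)
        )
        assert b.hbo_um == pytest.approx(2 * a.hbo_um, rel=1e-12)
        assert b.thb_um == pytest.approx(2 * a.thb_um, rel=1e-12)
        assert b.sto2_pct == pytest.approx(a.sto2_pct, rel=1e-12)

    def test_negative_concentration_flagged_not_raised(self):
        state = compute_chromophores(
            OpticalProperties(1e-4, 10.0, 685.0), OpticalProperties(0.5, 10.0, 828.0)
        )
        assert state.negative_warning

    def test_props_interpolation(self):
        p = interpolate_props(
            OpticalProperties(0.2, 12.0, 685.0), OpticalProperties(0.3, 9.0, 828.0), 785.0
        )
        f = (785.0 - 685.0) / (828.0 - 685.0)
        assert p.mua == pytest.approx(0.2 + f * 0.1)
        assert p.musp == pytest.approx(12.0 - f * 3.0)


class TestPhantomEffective:
    def test_identical_repetitions_zero_cv(self):
        f685 = [OpticalProperties(0.23, 12.8, 685.0)] * 20
        f828 = [OpticalProperties(0.19, 9.5, 828.0)] * 20
        rec = compute_phantom_effective(f685, f828)
        assert rec.thb_cv_pct == pytest.approx(0.0, abs=1e-10)
        assert rec.sto2_cv_pct == pytest.approx(0.0, abs=1e-10)

    def test_simulated_session_cv_order_of_magnitude(self, spec, geom, irf_shape, irf_record):
        """Intra-phantom tHb CV at 1e6 counts sits at the ~1% scale."""
        fits = {685.0: [], 828.0: []}
        for wl in (685.0, 828.0):
            for s in range(20):
                d = generate_dtof(PHANTOM_PROPS[wl], geom, spec, irf_shape,
                                  rng=np.random.default_rng(int(wl) * 100 + s))
                fits[wl].append(fit_dtof(d, irf_record, geom)[0])
        rec = compute_phantom_effective(fits[685.0], fits[828.0])
        assert 0.05 < rec.thb_cv_pct < 5.0

    def test_mua_sensitivity_direction(self):
        """Doubling mua at 685 only raises HbR (hence tHb) and lowers StO2."""
        f685 = [OpticalProperties(0.22, 12.8, 685.0), OpticalProperties(0.44, 12.8, 685.0)]
        f828 = [OpticalProperties(0.19, 9.5, 828.0)] * 2
        rec = compute_phantom_effective(f685, f828)
        s0, s1 = rec.per_repetition
        assert s1.hbr_um > s0.hbr_um
        assert s1.thb_um != s0.thb_um
        assert s1.sto2_pct < s0.sto2_pct

    def test_mismatched_repetitions_rejected(self):
        with pytest.raises(ValueError):
            compute_phantom_effective(
                [OpticalProperties(0.2, 10, 685.0)] * 3, [OpticalProperties(0.2, 10, 828.0)] * 2
            )
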