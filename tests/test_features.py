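"""Feature schema counts, peak-fit oracles and window summaries."""

import numpy as np
import pytest

from sstmon.errors import RangeError, SchemaError, SelectionError
from sstmon.features import (
    FitConfig,
    ScanConfig,
    SchemaConfig,
    WindowConfig,
    extract_features,
    fit_expected_peak,
    select_scans,
    window_features,
)
from sstmon.io import Acquisition, ProfileSpectrum
from sstmon.registry import ExpectedPeak, default_registry, qc_peaks

from conftest import gaussian_spectrum

GAUSS_FWHM = 2 * np.sqrt(2 * np.log(2))


class TestScanSelection:
    def test_qc_triple_follows_tic_apex(self, noisy_acq, compact_chron):
        acq, _ = noisy_acq
        sel = select_scans(acq)
        apex = compact_chron.apex_scan
        assert sel.qc_scan_indices == (apex, apex + 1, apex + 2)
        assert sel.background_scan_index == 18
        assert sel.noise_scan_index == len(acq) - 3

    def test_apex_at_final_scan_raises(self):
        spectra = [
            ProfileSpectrum(i, np.array([100.0, 101.0]), np.full(2, float(i + 1)))
            for i in range(25)
        ]
        acq = Acquisition(spectra=spectra)
        with pytest.raises(SelectionError, match="no room"):
            select_scans(acq, ScanConfig(background_scan_index=3))

    def test_flat_chronogram_raises(self):
        spectra = [
            ProfileSpectrum(i, np.array([100.0, 101.0]), np.ones(2)) for i in range(25)
        ]
        with pytest.raises(SelectionError, match="flat"):
            select_scans(Acquisition(spectra=spectra))


class TestPeakFit:
    def test_noiseless_gaussian_closed_form(self):
        """sigma = 0.01 Th: FWHM must be 2*sqrt(2 ln 2)*sigma ~ 0.02355 Th."""
        spec = gaussian_spectrum(mu=305.0968, sigma=0.01, height=1e6)
        peak = ExpectedPeak("p", 305.0968, "monoisotopic")
        fit = fit_expected_peak(spec, peak)
        assert fit.found
        assert fit.apex_height == pytest.approx(1e6, rel=0.01)
        assert fit.widths[0.5] == pytest.approx(GAUSS_FWHM * 0.01, rel=0.02)
        assert abs(fit.ppm_error) < 0.01

    def test_symmetric_peak_has_unit_symmetry_and_high_gof(self):
        spec = gaussian_spectrum()
        fit = fit_expected_peak(spec, ExpectedPeak("p", 305.0968, "monoisotopic"))
        assert fit.symmetry == pytest.approx(1.0, abs=1e-6)
        assert fit.gaussian_gof >= 0.99

    def test_right_tailed_peak_has_symmetry_above_one(self):
        spec = gaussian_spectrum()
        y = spec.intensity.copy()
        right = spec.mz >= 305.0968
        y[right] += 2e5 * np.exp(-(spec.mz[right] - 305.0968) / 0.02)
        tailed = ProfileSpectrum(0, spec.mz, y)
        fit = fit_expected_peak(tailed, ExpectedPeak("p", 305.0968, "monoisotopic"))
        assert fit.symmetry > 1.1
        assert fit.gaussian_gof < 0.999

    def test_width_monotonicity_across_height_fractions(self, noisy_acq, compact_chron):
        acq, _ = noisy_acq
        apex = acq[compact_chron.apex_scan]
        for peak in qc_peaks(default_registry()):
            fit = fit_expected_peak(apex, peak)
            if fit.found:
                assert (
                    fit.widths[0.1] >= fit.widths[0.25]
                    >= fit.widths[0.5] >= fit.widths[0.75]
                )

    def test_absent_peak_yields_sentinel(self):
        x = 305.0968 + np.arange(-200, 201) * 1e-3
        spec = ProfileSpectrum(0, x, np.zeros(x.size))
        fit = fit_expected_peak(spec, ExpectedPeak("p", 305.0968, "monoisotopic"))
        assert not fit.found
        assert fit.apex_height == 0.0
        assert fit.widths[0.5] == 0.0
        assert fit.ppm_error == pytest.approx(0.05 / 305.0968 * 1e6)
        assert fit.gaussian_gof == 0.0

    def test_window_outside_spectrum_raises_range_error(self):
        spec = gaussian_spectrum()
        with pytest.raises(RangeError):
            fit_expected_peak(spec, ExpectedPeak("p", 999.0, "monoisotopic"))

    def test_subsequent_peaks_counted_nearest_first(self):
        spec = gaussian_spectrum(mu=400.0, sigma=0.005, height=1e6, span=3.0)
        y = spec.intensity.copy()
        for offset, h in ((0.3, 5e4), (0.6, 2e4)):
            y += h * np.exp(-0.5 * ((spec.mz - 400.0 - offset) / 0.005) ** 2)
        fit = fit_expected_peak(
            ProfileSpectrum(0, spec.mz, y), ExpectedPeak("p", 400.0, "monoisotopic")
        )
        assert fit.n_subsequent_peaks == 2
        assert fit.subsequent_intensity_ratios[0] == pytest.approx(0.05, rel=0.05)
        assert fit.subsequent_intensity_ratios[1] == pytest.approx(0.02, rel=0.05)

    def test_relative_height_against_parent(self):
        spec = gaussian_spectrum(mu=500.0, sigma=0.008, height=1e6, span=3.0)
        y = spec.intensity + 1e5 * np.exp(
            -0.5 * ((spec.mz - 501.0) / 0.008) ** 2
        )
        spec2 = ProfileSpectrum(0, spec.mz, y)
        parent = ExpectedPeak("m", 500.0, "monoisotopic")
        child = ExpectedPeak("i", 501.0, "isotopologue", "m", 0.2)
        pf = fit_expected_peak(spec2, parent)
        cf = fit_expected_peak(spec2, child, parent_fit=pf)
        assert cf.relative_height == pytest.approx(0.1, rel=0.01)
        assert cf.abundance_deviation == pytest.approx(-0.1, abs=0.01)


class TestWindowFeatures:
    CFG = WindowConfig(percentiles=(25, 50, 75), top_percentiles=(50,))

    def test_three_peaks_counted(self):
        x = 100 + np.arange(0, 5000) * 1e-2
        y = np.zeros(x.size)
        for mu in (110.0, 120.0, 130.0):
            y += 1e5 * np.exp(-0.5 * ((x - mu) / 0.05) ** 2)
        rows = window_features(
            ProfileSpectrum(0, x, y), [(100.0, 150.0)], [], self.CFG
        )
        assert rows[0][0] == 3.0
        assert rows[0][1] == pytest.approx(y.sum())

    def test_empty_window_is_all_zero(self):
        x = np.array([100.0, 100.1, 100.2])
        rows = window_features(
            ProfileSpectrum(0, x, np.zeros(3)), [(100.0, 150.0), (150.0, 200.0)],
            [], self.CFG,
        )
        assert (rows[0] == 0).all() and (rows[1] == 0).all()

    def test_expected_ion_excluded_from_percentiles(self):
        """A huge expected ion must not move the window percentiles."""
        x = 100 + np.arange(0, 5000) * 1e-2
        rng = np.random.default_rng(0)
        base = rng.uniform(10, 20, x.size)
        contaminant = 5e3 * np.exp(-0.5 * ((x - 132.0) / 0.01) ** 2)
        expected_ion = 1e7 * np.exp(-0.5 * ((x - 120.0) / 0.01) ** 2)
        excl = [ExpectedPeak("e", 120.0, "monoisotopic")]
        rows_with = window_features(
            ProfileSpectrum(0, x, base + contaminant + expected_ion),
            [(100.0, 150.0)], excl, self.CFG,
        )
        rows_without = window_features(
            ProfileSpectrum(0, x, base + contaminant),
            [(100.0, 150.0)], excl, self.CFG,
        )
        np.testing.assert_allclose(rows_with[0][2:5], rows_without[0][2:5], rtol=1e-9)

    def test_empty_window_list_rejected(self):
        spec = gaussian_spectrum()
        with pytest.raises(SchemaError):
            window_features(spec, [], [], self.CFG)


class TestExtractFeatures:
    def test_vector_totals_and_subtotals(self, noisy_fv):
        assert len(noisy_fv) == 2850
        assert noisy_fv.subtotals() == {
            "qc_peak": 1720, "qc_window": 720, "background_lockmass": 140,
            "background_window": 180, "noise_window": 90,
        }

    def test_count_conservation(self, noisy_fv):
        sub = noisy_fv.subtotals()
        assert sub["qc_peak"] + sub["qc_window"] == 2440
        assert sub["background_lockmass"] + sub["background_window"] == 320

    def test_names_unique_and_order_deterministic(self, noisy_fv, noiseless_fv):
        assert len(set(noisy_fv.names)) == 2850
        assert noisy_fv.names == noiseless_fv.names

    def test_identical_acquisitions_give_identical_vectors(self, noisy_acq, registry):
        acq, _ = noisy_acq
        assert extract_features(acq, registry) == extract_features(acq, registry)

    def test_sd_features_zero_for_identical_qc_scans(self, noiseless_acq, registry):
        """Three identical QC scans: every sd feature must be exactly 0."""
        acq, _ = noiseless_acq
        apex = acq[28]
        bg = acq[10]
        zero = acq[len(acq) - 2]

        def reindex(s, i):
            return ProfileSpectrum(i, s.mz, s.intensity, s.is_profile, float(i))

        small = Acquisition(
            spectra=[
                reindex(bg, 0),
                reindex(apex, 1), reindex(apex, 2), reindex(apex, 3),
                reindex(bg, 4),
                reindex(zero, 5),
            ]
        )
        cfg = SchemaConfig(
            scan=ScanConfig(background_scan_index=0, noise_scan_index=5)
        )
        fv = extract_features(small, registry, cfg)
        sd_vals = [v for v, s in zip(fv.values, fv.stat) if s == "sd"]
        assert np.all(np.asarray(sd_vals) == 0.0)
        mean_map = {
            n.replace(":mean", ""): v
            for n, v, s in zip(fv.names, fv.values, fv.stat) if s == "mean"
        }
        single = extract_features(small, registry, cfg)
        assert fv == single  # determinism of the degenerate case

    def test_wrong_registry_size_rejected(self, noisy_acq, registry):
        acq, _ = noisy_acq
        with pytest.raises(SchemaError, match="registry"):
            extract_features(acq, registry[:-3])

    def test_registry_default_holds_37_qc_peaks(self, registry):
        assert len(qc_peaks(registry)) == 37
        assert len(registry) == 39
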