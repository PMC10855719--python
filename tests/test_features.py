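import dataclasses

import numpy as np
import pytest

from sparkspec.features import (
    FeatureMatrix,
    PeakDetection,
    build_matrix,
    detect_line,
    detect_peaks,
    feature_scores,
    integrate_feature,
    match_lines,
    select_panel,
)
from sparkspec.preprocessing import local_baseline, normalize_total
from sparkspec.spectra_io import apply_qc
from sparkspec.synthetic_data import (
    CohortConfig,
    LineSpec,
    default_line_catalogue,
    simulate_cohort,
)

from conftest import add_gaussian, cohort_of, flat_spectrum, random_spectrum
from oracles import brute_detect_peaks, gaussian_window_area


class TestDetectPeaks:
    def test_monotone_spectrum_empty(self):
        grid = 200.0 + 0.02 * np.arange(100)
        from conftest import make_spectrum

        s = make_spectrum(grid, np.linspace(1.0, 2.0, 100))
        assert detect_peaks(s, min_snr=0.0) == []

    def test_single_gaussian_apex_at_nearest_grid_point(self):
        s = flat_spectrum(1.0, start=277.002, stop=282.002, step=0.02)
        s = add_gaussian(s, 279.522, 100.0, 0.03)
        peaks = detect_peaks(s, min_snr=5.0)
        assert len(peaks) == 1
        nearest = s.wavelengths_nm[np.argmin(np.abs(s.wavelengths_nm - 279.522))]
        assert peaks[0].apex_nm == nearest

    def test_two_gaussians_ascending_order(self):
        s = flat_spectrum(1.0, start=275.0, stop=290.0, step=0.02)
        s = add_gaussian(s, 279.522, 100.0, 0.03)
        s = add_gaussian(s, 285.213, 80.0, 0.03)
        peaks = detect_peaks(s, min_snr=5.0)
        assert len(peaks) == 2
        assert peaks[0].apex_nm < peaks[1].apex_nm

    def test_matches_brute_oracle(self, rng):
        for _ in range(50):
            s = random_spectrum(rng, n=int(rng.integers(64, 400)), step=0.02)
            got = [(p.apex_index, p.snr) for p in detect_peaks(s, min_snr=1.0)]
            want = brute_detect_peaks(
                s.wavelengths_nm, s.intensities, min_snr=1.0
            )
            assert [g[0] for g in got] == [w[0] for w in want]
            np.testing.assert_allclose(
                [g[1] for g in got], [w[1] for w in want], rtol=1e-9
            )

    def test_plateau_resolved_leftmost(self):
        grid = 200.0 + 0.02 * np.arange(120)
        y = np.full(120, 1.0)
        y[60:63] = 2.0  # 3-point plateau above surroundings
        from conftest import make_spectrum

        s = make_spectrum(grid, y)
        peaks = detect_peaks(s, min_snr=0.0)
        assert [p.apex_index for p in peaks] == [60]


class TestMatchLines:
    def _peak(self, nm):
        return PeakDetection(apex_nm=nm, apex_index=0, height=1.0, snr=100.0)

    def test_carbon_matched(self):
        out = match_lines([self._peak(247.856)], default_line_catalogue())
        assert out[0].matched_species == "C"

    def test_iron_not_carbon(self):
        out = match_lines([self._peak(248.327)], default_line_catalogue(), tol_nm=0.05)
        assert out[0].matched_species == "Fe"
        assert out[0].matched_wavelength_nm == 248.327

    def test_unmatched_far_peak(self):
        out = match_lines([self._peak(300.0)], default_line_catalogue(), tol_nm=0.05)
        assert out[0].matched_species is None

    def test_partial_injection(self):
        # two peaks near one line: only the nearer claims it
        cat = [LineSpec("X", 250.0, 0.03, 10.0, 1.0)]
        peaks = [self._peak(250.02), self._peak(250.01)]
        out = match_lines(peaks, cat, tol_nm=0.05)
        assert out[1].matched_species == "X"
        assert out[0].matched_species is None

    def test_broad_tolerance_for_molecular_band(self):
        out = match_lines([self._peak(516.8)], default_line_catalogue())
        assert out[0].matched_species == "C2"

    def test_empty_catalogue_rejected(self):
        with pytest.raises(ValueError, match="catalogue"):
            match_lines([self._peak(250.0)], [])

    def test_injection_property_random(self, rng):
        cat = default_line_catalogue()
        for _ in range(20):
            peaks = [
                self._peak(float(rng.uniform(210.0, 780.0))) for _ in range(15)
            ]
            out = match_lines(peaks, cat)
            claimed = [
                (p.matched_species, p.matched_wavelength_nm)
                for p in out
                if p.matched_species is not None
            ]
            assert len(claimed) == len(set(claimed))


def _panel_cohort(n_present, n_total=100):
    """Flat spectra; the Mg line appears in exactly ``n_present`` of them."""
    spectra = []
    for i in range(n_total):
        s = flat_spectrum(
            5.0,
            start=277.0,
            stop=282.0,
            step=0.02,
            spectrum_id=f"S{i:04d}",
            patient_id=f"P{i % 4:02d}",
            tissue_label="normal" if i % 2 == 0 else "abnormal",
        )
        if i < n_present:
            s = add_gaussian(s, 279.522, 100.0, 0.03)
        spectra.append(s)
    return cohort_of(spectra)


class TestSelectPanel:
    def test_five_percent_retained(self, single_line_catalogue):
        panel = select_panel(
            _panel_cohort(5), single_line_catalogue, min_occurrence=0.05
        )
        assert len(panel) == 1
        assert panel.lines[0].occurrence_rate == pytest.approx(0.05)

    def test_four_percent_dropped(self, single_line_catalogue):
        panel = select_panel(
            _panel_cohort(4), single_line_catalogue, min_occurrence=0.05
        )
        assert len(panel) == 0

    def test_monotone_in_min_occurrence(self, single_line_catalogue):
        cohort = _panel_cohort(30)
        sizes = [
            len(select_panel(cohort, single_line_catalogue, min_occurrence=t))
            for t in (0.05, 0.2, 0.5)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_cohort_errors(self, single_line_catalogue):
        with pytest.raises(ValueError, match="empty"):
            select_panel(cohort_of([]), single_line_catalogue)

    def test_full_catalogue_panel_on_low_noise_cohort(self):
        cfg = CohortConfig(
            n_patients=2,
            per_patient_counts=[(3, 3), (3, 3)],
            noise_sd=2.0,
            qc_fail_fraction=0.0,
            seed=4,
        )
        cohort = apply_qc(simulate_cohort(cfg))
        panel = select_panel(cohort, default_line_catalogue())
        assert len(panel) == 17

    def test_detect_line_agrees_with_detect_peaks_route(self, rng):
        cat = [LineSpec("Mg", 279.522, 0.03, 100.0, 1.0)]
        for k in range(20):
            s = flat_spectrum(5.0, start=277.0, stop=282.0, step=0.02)
            noisy = s.with_intensities(
                np.abs(s.intensities + rng.normal(0, 1.0, len(s)))
            )
            if k % 2 == 0:
                noisy = add_gaussian(noisy, 279.522, 200.0, 0.03)
            via_line = detect_line(noisy, cat[0], cat, min_snr=20.0)
            peaks = match_lines(detect_peaks(noisy, min_snr=0.0), cat)
            via_peaks = any(
                p.matched_species == "Mg" and p.snr > 20.0 for p in peaks
            )
            assert via_line == via_peaks


class TestIntegrateFeature:
    def test_spectrum_equal_to_baseline_gives_zero(self):
        s = flat_spectrum(5.0)
        base = local_baseline(s, 248.0)
        assert integrate_feature(s, 248.0, 0.09, base) == 0.0

    def test_gaussian_area_closed_form(self):
        s = flat_spectrum(0.0, start=276.0, stop=283.0, step=0.005)
        amp, sigma = 100.0, 0.03
        s = add_gaussian(s, 279.522, amp, sigma)
        base = local_baseline(s, 279.522)
        hw = 3 * sigma
        got = integrate_feature(s, 279.522, hw, base)
        want = gaussian_window_area(amp, sigma, hw)
        assert got == pytest.approx(want, rel=1e-3)

    def test_window_outside_range_errors(self):
        s = flat_spectrum(5.0)
        base = local_baseline(s, 248.0)
        with pytest.raises(ValueError, match="window"):
            integrate_feature(s, 249.9, 0.5, base)

    def test_amplitude_monotonicity(self):
        vals = []
        for amp in (50.0, 100.0):
            s = flat_spectrum(1.0, start=277.0, stop=282.0, step=0.02)
            s = add_gaussian(s, 279.522, amp, 0.03)
            norm = normalize_total(s)
            base = local_baseline(norm, 279.522)
            vals.append(integrate_feature(norm, 279.522, 0.09, base))
        assert vals[0] < vals[1]

    def test_scale_invariance_after_normalization(self, rng):
        s = random_spectrum(rng, n=300, start=278.0, step=0.02)
        norm1 = normalize_total(s)
        norm2 = normalize_total(s.with_intensities(s.intensities * 123.0))
        center = float(s.wavelengths_nm[150])
        b1 = local_baseline(norm1, center)
        b2 = local_baseline(norm2, center)
        f1 = integrate_feature(norm1, center, 0.09, b1)
        f2 = integrate_feature(norm2, center, 0.09, b2)
        assert f2 == pytest.approx(f1, rel=1e-9)


@pytest.fixture(scope="module")
def small_run():
    cfg = CohortConfig(
            n_patients=2,
            per_patient_counts=[(3, 3), (3, 3)],
        grid_start_nm=240.0,
        grid_end_nm=300.0,
        noise_sd=5.0,
        qc_fail_fraction=0.0,
        seed=7,
    )
    cat = [l for l in default_line_catalogue() if l.wavelength_nm < 300.0]
    cohort = apply_qc(simulate_cohort(cfg, cat))
    panel = select_panel(cohort, cat)
    matrix = build_matrix(cohort, panel, catalogue=cat)
    return cohort, cat, panel, matrix


class TestBuildMatrixAndScores:
    def test_matrix_shape_and_row_order(self, small_run):
        cohort, _, panel, matrix = small_run
        assert matrix.values.shape == (len(cohort), len(panel))
        assert list(matrix.spectrum_ids) == [s.spectrum_id for s in cohort.spectra]

    def test_values_finite_nonnegative(self, small_run):
        _, _, _, matrix = small_run
        assert np.all(np.isfinite(matrix.values))
        assert np.all(matrix.values >= 0)

    def test_scores_directional(self, small_run):
        # Mg fold-change >> Ca's: its separability score must dominate
        cfg = CohortConfig(
            n_patients=2,
            per_patient_counts=[(6, 6), (6, 6)],
            noise_sd=5.0,
            qc_fail_fraction=0.0,
            seed=9,
        )
        cat = default_line_catalogue()
        cohort = apply_qc(simulate_cohort(cfg, cat))
        panel = select_panel(cohort, cat)
        matrix = build_matrix(cohort, panel, catalogue=cat)
        scores = dict(feature_scores(matrix))
        assert scores["Mg_279.522"] > scores["Ca_393.366"]

    def test_identical_classes_score_zero(self):
        values = np.tile(np.arange(4.0)[:, None], (2, 1))
        matrix = FeatureMatrix(
            values=values,
            feature_names=["f"],
            labels=np.array(["normal"] * 4 + ["abnormal"] * 4, dtype=object),
            patient_ids=np.array(["P"] * 8, dtype=object),
            spectrum_ids=np.array([f"S{i}" for i in range(8)], dtype=object),
        )
        assert feature_scores(matrix)[0][1] == 0.0

    def test_disjoint_support_scores_highest(self):
        rng = np.random.default_rng(0)
        n = 20
        sep = np.concatenate([rng.uniform(0, 1, n), rng.uniform(10, 11, n)])
        noise = rng.uniform(0, 1, 2 * n)
        matrix = FeatureMatrix(
            values=np.column_stack([noise, sep]),
            feature_names=["noise", "sep"],
            labels=np.array(["normal"] * n + ["abnormal"] * n, dtype=object),
            patient_ids=np.array(["P"] * 2 * n, dtype=object),
            spectrum_ids=np.array([f"S{i}" for i in range(2 * n)], dtype=object),
        )
        assert feature_scores(matrix)[0][0] == "sep"

    def test_single_class_errors(self):
        matrix = FeatureMatrix(
            values=np.ones((3, 1)),
            feature_names=["f"],
            labels=np.array(["normal"] * 3, dtype=object),
            patient_ids=np.array(["P"] * 3, dtype=object),
            spectrum_ids=np.array(["a", "b", "c"], dtype=object),
        )
        with pytest.raises(ValueError, match="both classes"):
            feature_scores(matrix)

    def test_empty_panel_errors(self, small_run):
        cohort, cat, _, _ = small_run
        from sparkspec.features import FeaturePanel

        with pytest.raises(ValueError, match="panel"):
            build_matrix(cohort, FeaturePanel(lines=[]), catalogue=cat)
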