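import numpy as np
import pytest

from sparkspec.spectra_io import Cohort, QCRecord, Spectrum
from sparkspec.synthetic_data import CohortConfig, LineSpec


def make_spectrum(
    wavelengths,
    intensities,
    spectrum_id="S0000",
    patient_id="P01",
    tissue_label="normal",
):
    return Spectrum(
        spectrum_id=spectrum_id,
        patient_id=patient_id,
        sample_id=f"{patient_id}-X",
        tissue_label=tissue_label,
        wavelengths_nm=np.asarray(wavelengths, dtype=float),
        intensities=np.asarray(intensities, dtype=float),
    )


def flat_spectrum(value=5.0, start=246.0, stop=250.0, step=0.02, **kw):
    grid = start + step * np.arange(int(round((stop - start) / step)) + 1)
    return make_spectrum(grid, np.full(grid.size, float(value)), **kw)


def add_gaussian(spectrum, center, amp, sigma):
    d = spectrum.wavelengths_nm - center
    return spectrum.with_intensities(
        spectrum.intensities + amp * np.exp(-0.5 * (d / sigma) ** 2)
    )


def random_spectrum(rng, n=None, start=None, step=None, **kw):
    n = n or int(rng.integers(64, 513))
    step = step or float(rng.uniform(0.01, 0.03))
    start = start if start is not None else float(rng.uniform(200.0, 700.0))
    grid = start + step * np.arange(n)
    intens = rng.gamma(shape=2.0, scale=10.0, size=n)
    return make_spectrum(grid, intens, **kw)


def cohort_of(spectra, statuses=None):
    if statuses is None:
        statuses = ["ok"] * len(spectra)
    return Cohort(
        spectra=list(spectra),
        qc=[QCRecord(s.spectrum_id, st) for s, st in zip(spectra, statuses)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim_config():
    """Cheap cohort config covering the C/Fe/Mg region only."""
    return CohortConfig(
        n_patients=2,
        per_patient_counts=[(3, 3), (3, 3)],
        grid_start_nm=240.0,
        grid_end_nm=300.0,
        noise_sd=5.0,
        qc_fail_fraction=0.0,
        seed=7,
    )


@pytest.fixture
def single_line_catalogue():
    return [LineSpec("Mg", 279.522, 0.03, 400.0, 5.0)]
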