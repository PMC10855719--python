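"""Synthetic electrosurgical-spark emission spectrum cohorts.

The generator produces cohorts with the statistical structure the analysis
assumes: Gaussian emission lines at catalogued wavelengths, tissue-dependent
amplitude fold-changes, a shared per-patient log-amplitude random effect,
per-line per-spectrum log-amplitude jitter, a flat continuum pedestal,
additive detector noise, and occasional manifest-level QC failures.

Line amplitudes follow

    A_l = base_amplitude_l * abnormal_multiplier_l^{1[tissue=abnormal]}
          * exp(patient_effect + jitter_l),      jitter_l ~ N(0, sigma_spectrum^2)

and the intensity on the grid is

    I(lam) = baseline_level + sum_l A_l exp(-(lam-lam_l)^2 / (2 sigma_l^2))
             + eps(lam),                         eps ~ N(0, noise_sd^2),

clipped at zero so intensities stay non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sparkspec.spectra_io import Cohort, QCRecord, Spectrum

#: Per-patient (normal, abnormal) spectrum counts of the 18-patient
#: reference cohort the defaults emulate.
DEFAULT_PER_PATIENT_COUNTS: tuple[tuple[int, int], ...] = (
    (37, 39),
    (24, 17),
    (20, 7),
    (64, 42),
    (56, 3),
    (70, 60),
    (14, 2),
    (22, 15),
    (17, 59),
    (11, 10),
    (21, 75),
    (11, 16),
    (25, 65),
    (12, 6),
    (11, 2),
    (9, 23),
    (27, 36),
    (30, 17),
)

#: Gaussian sigma of narrow atomic lines, nm. Broad molecular/resonance
#: entries (Na, C2) use 10x this.
ATOMIC_SIGMA_NM = 0.03
BROAD_SIGMA_NM = 0.3

#: Manifest-level failure categories the generator can assign.
_FAILURE_STATUSES = (
    "instrument_contamination",
    "poor_spectral_quality",
    "memory_error",
)


@dataclass(frozen=True)
class LineSpec:
    """One emission line of the simulation catalogue.

    ``base_amplitude`` is the peak amplitude (counts) in normal tissue;
    ``abnormal_multiplier`` is the fold-change applied in abnormal tissue.
    """

    species: str
    wavelength_nm: float
    profile_sigma_nm: float
    base_amplitude: float
    abnormal_multiplier: float

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError(f"{self.species}: wavelength must be positive")
        if self.profile_sigma_nm <= 0:
            raise ValueError(f"{self.species}: profile_sigma_nm must be positive")
        if self.base_amplitude <= 0:
            raise ValueError(f"{self.species}: base_amplitude must be positive")
        if self.abnormal_multiplier <= 0:
            raise ValueError(f"{self.species}: abnormal_multiplier must be positive")


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic cohort generator."""

    n_patients: int = 18
    per_patient_counts: list[tuple[int, int]] = field(
        default_factory=lambda: [tuple(c) for c in DEFAULT_PER_PATIENT_COUNTS]
    )
    sigma_patient: float = 0.25
    sigma_spectrum: float = 0.20
    baseline_level: float = 200.0
    noise_sd: float = 10.0
    grid_start_nm: float = 200.0
    grid_end_nm: float = 800.0
    grid_step_nm: float = 0.02
    qc_fail_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.per_patient_counts = [tuple(c) for c in self.per_patient_counts]
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if len(self.per_patient_counts) != self.n_patients:
            raise ValueError(
                f"per_patient_counts has {len(self.per_patient_counts)} entries "
                f"for {self.n_patients} patients"
            )
        if self.sigma_patient < 0 or self.sigma_spectrum < 0:
            raise ValueError("effect SDs must be non-negative")
        if self.baseline_level < 0 or self.noise_sd < 0:
            raise ValueError("baseline_level and noise_sd must be non-negative")
        if not self.grid_start_nm < self.grid_end_nm:
            raise ValueError("grid_start_nm must be below grid_end_nm")
        if self.grid_step_nm <= 0:
            raise ValueError("grid_step_nm must be positive")
        if not 0 <= self.qc_fail_fraction < 1:
            raise ValueError("qc_fail_fraction must be in [0, 1)")

    def wavelength_grid(self) -> np.ndarray:
        n = int(round((self.grid_end_nm - self.grid_start_nm) / self.grid_step_nm)) + 1
        return self.grid_start_nm + self.grid_step_nm * np.arange(n)


def default_line_catalogue() -> list[LineSpec]:
    """The 17-entry default catalogue: 16 atomic lines plus the C2 band.

    Fold-changes follow the qualitative tissue pattern the analysis targets:
    P, Zn, Mg and K enriched in abnormal tissue, C2 enriched in normal
    (fatty) tissue, Ca nearly equal, and C/Fe/Na tissue-neutral. Na and the
    C2 band are broad; all other entries are narrow atomic lines.
    """
    a = ATOMIC_SIGMA_NM
    b = BROAD_SIGMA_NM
    lines = [
        LineSpec("P", 213.618, a, 800.0, 3.5),
        LineSpec("Zn", 213.855, a, 700.0, 3.5),
        LineSpec("Zn", 214.914, a, 600.0, 3.0),
        LineSpec("C", 247.856, a, 5000.0, 1.0),
        LineSpec("Fe", 248.327, a, 600.0, 1.0),
        LineSpec("Mg", 279.522, a, 900.0, 5.0),
        LineSpec("Mg", 279.805, a, 700.0, 4.5),
        LineSpec("Mg", 280.270, a, 600.0, 4.0),
        LineSpec("Mg", 285.213, a, 500.0, 3.5),
        LineSpec("Ca", 393.366, a, 1500.0, 1.05),
        LineSpec("Ca", 396.847, a, 1300.0, 1.05),
        LineSpec("Ca", 422.673, a, 900.0, 1.05),
        LineSpec("Ca", 435.838, a, 700.0, 1.05),
        LineSpec("C2", 516.49, b, 1500.0, 0.45),
        LineSpec("Na", 588.995, b, 2000.0, 1.0),
        LineSpec("K", 766.490, a, 1200.0, 2.5),
        LineSpec("K", 769.896, a, 900.0, 2.5),
    ]
    return sorted(lines, key=lambda l: l.wavelength_nm)


def simulate_spectrum(
    catalogue: list[LineSpec],
    tissue: str,
    patient_effect: float,
    config: CohortConfig,
    rng: np.random.Generator,
    *,
    spectrum_id: str = "S0000",
    patient_id: str = "P00",
    sample_id: str = "",
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Draw one spectrum. Each line gets its own per-spectrum log-amplitude
    jitter so that relative line intensities vary even after per-spectrum
    normalization downstream."""
    if tissue not in ("normal", "abnormal"):
        raise ValueError(f"tissue must be normal|abnormal, got {tissue!r}")
    if grid is None:
        grid = config.wavelength_grid()
    intens = np.full(grid.size, float(config.baseline_level))
    jitter = rng.normal(0.0, config.sigma_spectrum, size=len(catalogue))
    for line, jit in zip(catalogue, jitter):
        amp = line.base_amplitude
        if tissue == "abnormal":
            amp *= line.abnormal_multiplier
        amp *= np.exp(patient_effect + jit)
        # evaluate only within +-8 sigma; the tail beyond is < 1e-13 of peak
        half = 8.0 * line.profile_sigma_nm
        lo = np.searchsorted(grid, line.wavelength_nm - half, side="left")
        hi = np.searchsorted(grid, line.wavelength_nm + half, side="right")
        if lo >= hi:
            continue
        d = grid[lo:hi] - line.wavelength_nm
        intens[lo:hi] += amp * np.exp(-0.5 * (d / line.profile_sigma_nm) ** 2)
    if config.noise_sd > 0:
        intens = intens + rng.normal(0.0, config.noise_sd, size=grid.size)
    np.maximum(intens, 0.0, out=intens)
    return Spectrum(
        spectrum_id=spectrum_id,
        patient_id=patient_id,
        sample_id=sample_id,
        tissue_label=tissue,
        wavelengths_nm=grid,
        intensities=intens,
    )


def simulate_cohort(
    config: CohortConfig, catalogue: list[LineSpec] | None = None
) -> Cohort:
    """Generate a full cohort, reproducible from ``config.seed``.

    Patient ``i`` receives a single log-amplitude random effect shared by
    all its spectra; ``per_patient_counts[i]`` fixes the number of normal
    and abnormal spectra. A ``qc_fail_fraction`` of spectra is flagged with
    a random manifest-level failure status.
    """
    if catalogue is None:
        catalogue = default_line_catalogue()
    rng = np.random.default_rng(config.seed)
    grid = config.wavelength_grid()
    effects = rng.normal(0.0, config.sigma_patient, size=config.n_patients)
    spectra: list[Spectrum] = []
    qc: list[QCRecord] = []
    idx = 0
    for i, (n_normal, n_abnormal) in enumerate(config.per_patient_counts):
        pid = f"P{i + 1:02d}"
        for tissue, count, tag in (
            ("normal", n_normal, "N"),
            ("abnormal", n_abnormal, "A"),
        ):
            for _ in range(count):
                sid = f"S{idx:04d}"
                spectra.append(
                    simulate_spectrum(
                        catalogue,
                        tissue,
                        effects[i],
                        config,
                        rng,
                        spectrum_id=sid,
                        patient_id=pid,
                        sample_id=f"{pid}-{tag}",
                        grid=grid,
                    )
                )
                if config.qc_fail_fraction > 0 and rng.random() < config.qc_fail_fraction:
                    status = _FAILURE_STATUSES[
                        rng.integers(0, len(_FAILURE_STATUSES))
                    ]
                else:
                    status = "ok"
                qc.append(QCRecord(spectrum_id=sid, status=status))
                idx += 1
    return Cohort(spectra=spectra, qc=qc)
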