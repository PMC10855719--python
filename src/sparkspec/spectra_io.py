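"""Reading, writing and QC filtering of spark-emission spectrum cohorts.

A spectrum lives in a plain two-column delimited text file with header
``wavelength_nm,intensity``; all acquisition metadata (patient, sample,
tissue label, QC status) lives in a cohort manifest — a delimited text file
with columns ``spectrum_id, patient_id, sample_id, tissue_label, qc_status,
file``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUE_LABELS = ("normal", "abnormal", "unlabeled")

#: Manifest-level exclusion categories plus the carbon-SNR gate applied in
#: preprocessing. Only ``ok`` spectra enter analysis.
QC_STATUSES = (
    "ok",
    "instrument_contamination",
    "poor_spectral_quality",
    "memory_error",
    "low_carbon_snr",
)

WAVELENGTH_MIN_NM = 150.0
WAVELENGTH_MAX_NM = 900.0

MANIFEST_COLUMNS = (
    "spectrum_id",
    "patient_id",
    "sample_id",
    "tissue_label",
    "qc_status",
    "file",
)

SPECTRUM_HEADER = "wavelength_nm,intensity"


@dataclass
class Spectrum:
    """One acquisition: a wavelength grid, intensities and identifying metadata.

    Invariants enforced on construction: wavelengths strictly increasing and
    within [150, 900] nm; intensities finite, non-negative and of equal
    length; positive integration time.
    """

    spectrum_id: str
    patient_id: str
    sample_id: str
    tissue_label: str
    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    integration_time_ms: float = 100.0

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.tissue_label not in TISSUE_LABELS:
            raise ValueError(
                f"{self.spectrum_id}: unknown tissue_label {self.tissue_label!r}"
            )
        if self.wavelengths_nm.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError(f"{self.spectrum_id}: expected 1-D arrays")
        if len(self.wavelengths_nm) != len(self.intensities):
            raise ValueError(
                f"{self.spectrum_id}: wavelength/intensity length mismatch "
                f"({len(self.wavelengths_nm)} vs {len(self.intensities)})"
            )
        if len(self.wavelengths_nm) == 0:
            raise ValueError(f"{self.spectrum_id}: empty spectrum")
        if not np.all(np.isfinite(self.wavelengths_nm)):
            raise ValueError(f"{self.spectrum_id}: non-finite wavelength")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError(
                f"{self.spectrum_id}: wavelengths must be strictly increasing"
            )
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if lo < WAVELENGTH_MIN_NM or hi > WAVELENGTH_MAX_NM:
            raise ValueError(
                f"{self.spectrum_id}: wavelengths [{lo}, {hi}] outside "
                f"[{WAVELENGTH_MIN_NM}, {WAVELENGTH_MAX_NM}] nm"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"{self.spectrum_id}: non-finite intensity")
        if np.any(self.intensities < 0):
            raise ValueError(f"{self.spectrum_id}: negative intensity")
        if self.integration_time_ms <= 0:
            raise ValueError(f"{self.spectrum_id}: non-positive integration time")

    def __len__(self) -> int:
        return len(self.wavelengths_nm)

    def covers(self, lo_nm: float, hi_nm: float) -> bool:
        """True if [lo_nm, hi_nm] lies inside the recorded wavelength range."""
        return bool(
            self.wavelengths_nm[0] <= lo_nm and hi_nm <= self.wavelengths_nm[-1]
        )

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return replace(self, intensities=intensities)


@dataclass(frozen=True)
class QCRecord:
    spectrum_id: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in QC_STATUSES:
            raise ValueError(
                f"{self.spectrum_id}: unknown qc status {self.status!r}"
            )


@dataclass
class Cohort:
    """All spectra of a study plus one QC record per spectrum."""

    spectra: list[Spectrum] = field(default_factory=list)
    qc: list[QCRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.spectrum_id for s in self.spectra]
        dupes = [sid for sid, k in Counter(ids).items() if k > 1]
        if dupes:
            raise ValueError(f"duplicate spectrum_id(s): {dupes}")
        qc_ids = {r.spectrum_id for r in self.qc}
        if len(qc_ids) != len(self.qc):
            raise ValueError("duplicate QC records")
        if qc_ids != set(ids):
            raise ValueError("QC records do not cover the spectra exactly")

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def patient_ids(self) -> list[str]:
        """Distinct patient ids in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.spectra:
            seen.setdefault(s.patient_id, None)
        return list(seen)

    def qc_status(self, spectrum_id: str) -> str:
        for rec in self.qc:
            if rec.spectrum_id == spectrum_id:
                return rec.status
        raise KeyError(spectrum_id)

    def status_counts(self) -> Counter:
        return Counter(rec.status for rec in self.qc)


def read_spectrum(
    path: str | Path,
    *,
    spectrum_id: str | None = None,
    patient_id: str = "",
    sample_id: str = "",
    tissue_label: str = "unlabeled",
    integration_time_ms: float = 100.0,
) -> Spectrum:
    """Read one two-column spectrum file; metadata comes from the caller.

    Unsorted rows are sorted with a warning; non-numeric rows, negative
    intensities and duplicate wavelengths are rejected with the offending
    row index (0-based, excluding the header).
    """
    path = Path(path)
    if spectrum_id is None:
        spectrum_id = path.stem
    df = pd.read_csv(path)
    expected = ["wavelength_nm", "intensity"]
    if list(df.columns)[:2] != expected:
        raise ValueError(
            f"{path}: expected header '{SPECTRUM_HEADER}', got {list(df.columns)}"
        )
    wav = pd.to_numeric(df["wavelength_nm"], errors="coerce")
    inten = pd.to_numeric(df["intensity"], errors="coerce")
    bad = np.flatnonzero(wav.isna() | inten.isna())
    if bad.size:
        raise ValueError(f"{path}: non-numeric value at row {bad[0]}")
    neg = np.flatnonzero(inten.to_numpy() < 0)
    if neg.size:
        raise ValueError(f"{path}: negative intensity at row {neg[0]}")
    w = wav.to_numpy(dtype=float)
    y = inten.to_numpy(dtype=float)
    if not np.all(np.diff(w) > 0):
        dup = np.flatnonzero(np.diff(np.sort(w)) == 0)
        if dup.size:
            raise ValueError(f"{path}: duplicate wavelength at sorted row {dup[0]}")
        logger.warning("%s: wavelengths out of order; sorting", path)
        order = np.argsort(w, kind="stable")
        w, y = w[order], y[order]
    return Spectrum(
        spectrum_id=spectrum_id,
        patient_id=patient_id,
        sample_id=sample_id,
        tissue_label=tissue_label,
        wavelengths_nm=w,
        intensities=y,
        integration_time_ms=integration_time_ms,
    )


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column text, lossless to better than 1e-9
    relative."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(SPECTRUM_HEADER + "\n")
        for w, y in zip(spectrum.wavelengths_nm, spectrum.intensities):
            fh.write(f"{float(w)!r},{float(y)!r}\n")


def read_cohort(manifest_path: str | Path, spectra_dir: str | Path) -> Cohort:
    """Load a cohort from its manifest, reading every referenced spectrum
    file relative to ``spectra_dir`` and populating QC records."""
    manifest_path = Path(manifest_path)
    spectra_dir = Path(spectra_dir)
    df = pd.read_csv(manifest_path, dtype=str)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{manifest_path}: missing columns {missing_cols}")
    dupes = df["spectrum_id"][df["spectrum_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{manifest_path}: duplicate spectrum_id(s) {dupes}")
    spectra: list[Spectrum] = []
    qc: list[QCRecord] = []
    for row in df.itertuples(index=False):
        if row.tissue_label not in TISSUE_LABELS:
            raise ValueError(
                f"{row.spectrum_id}: unknown tissue_label {row.tissue_label!r}"
            )
        spath = spectra_dir / row.file
        if not spath.exists():
            raise FileNotFoundError(f"{row.spectrum_id}: spectrum file {spath} not found")
        spectra.append(
            read_spectrum(
                spath,
                spectrum_id=row.spectrum_id,
                patient_id=row.patient_id,
                sample_id=row.sample_id,
                tissue_label=row.tissue_label,
            )
        )
        qc.append(QCRecord(spectrum_id=row.spectrum_id, status=row.qc_status))
    return Cohort(spectra=spectra, qc=qc)


def write_cohort(
    cohort: Cohort, manifest_path: str | Path, spectra_dir: str | Path
) -> None:
    """Write manifest plus one spectrum file per spectrum."""
    manifest_path = Path(manifest_path)
    spectra_dir = Path(spectra_dir)
    spectra_dir.mkdir(parents=True, exist_ok=True)
    manifest_path.parent.mkdir(parents=True, exist_ok=True)
    status = {rec.spectrum_id: rec.status for rec in cohort.qc}
    rows = []
    for s in cohort.spectra:
        fname = f"{s.spectrum_id}.csv"
        write_spectrum(s, spectra_dir / fname)
        rows.append(
            {
                "spectrum_id": s.spectrum_id,
                "patient_id": s.patient_id,
                "sample_id": s.sample_id,
                "tissue_label": s.tissue_label,
                "qc_status": status[s.spectrum_id],
                "file": fname,
            }
        )
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        manifest_path, index=False
    )


def apply_qc(cohort: Cohort) -> Cohort:
    """Drop every spectrum whose QC status is not ``ok``.

    The number of exclusions per category is logged; an all-excluded cohort
    is returned empty with a warning.
    """
    counts = cohort.status_counts()
    for status, n in sorted(counts.items()):
        if status != "ok":
            logger.info("QC exclusion %s: %d spectra", status, n)
    status = {rec.spectrum_id: rec.status for rec in cohort.qc}
    kept = [s for s in cohort.spectra if status[s.spectrum_id] == "ok"]
    if not kept:
        logger.warning("apply_qc: no spectra passed QC")
    return Cohort(
        spectra=kept,
        qc=[QCRecord(s.spectrum_id, "ok") for s in kept],
    )
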