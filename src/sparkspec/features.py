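"""Peak detection, catalogue matching, feature-panel selection and windowed
feature integration.

A catalogue line enters the feature panel when a matching peak with SNR
strictly above the threshold is detected in at least the configured fraction
of QC-passing spectra (inclusive boundary). Feature values are
baseline-subtracted trapezoidal integrals of the total-intensity-normalized
spectrum over a window around each panel line, floored at zero, so every
spectrum yields a fixed-length feature vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from sparkspec import preprocessing
from sparkspec.preprocessing import (
    BaselineEstimate,
    DEFAULT_INNER_HW_NM,
    DEFAULT_OUTER_HW_NM,
    DEFAULT_BROAD_SCALE,
    line_windows,
    local_baseline,
    line_snr,
)
from sparkspec.spectra_io import Cohort, Spectrum
from sparkspec.synthetic_data import LineSpec

logger = logging.getLogger(__name__)

#: Peak-to-catalogue match tolerance, nm (narrow atomic lines).
DEFAULT_MATCH_TOL_NM = 0.05
#: Match tolerance for broad entries (Na, C2), nm.
DEFAULT_BROAD_MATCH_TOL_NM = 0.5
#: Integration half-width in units of the line's profile sigma.
DEFAULT_INTEGRATION_HALFWIDTH_SIGMAS = 3.0

DEFAULT_MIN_SNR = 20.0
DEFAULT_MIN_OCCURRENCE = 0.05


@dataclass
class PeakDetection:
    """A detected local maximum, optionally matched to a catalogue line."""

    apex_nm: float
    apex_index: int
    height: float
    snr: float
    matched_species: str | None = None
    matched_wavelength_nm: float | None = None


@dataclass(frozen=True)
class PanelLine:
    species: str
    wavelength_nm: float
    integration_halfwidth_nm: float
    occurrence_rate: float

    @property
    def name(self) -> str:
        return f"{self.species}_{self.wavelength_nm:g}"


@dataclass
class FeaturePanel:
    """Selected lines, ordered by ascending wavelength."""

    lines: list[PanelLine]

    def __post_init__(self) -> None:
        self.lines = sorted(self.lines, key=lambda l: l.wavelength_nm)

    def __len__(self) -> int:
        return len(self.lines)

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.lines]


@dataclass
class FeatureMatrix:
    """Spectra x panel-lines table with labels and patient ids per row."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    patient_ids: np.ndarray
    spectrum_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.spectrum_ids = np.asarray(self.spectrum_ids, dtype=object)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValueError("values shape does not match feature_names")
        if not (len(self.labels) == len(self.patient_ids) == len(self.spectrum_ids) == n):
            raise ValueError("row metadata length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def subset(self, rows: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[rows],
            feature_names=list(self.feature_names),
            labels=self.labels[rows],
            patient_ids=self.patient_ids[rows],
            spectrum_ids=self.spectrum_ids[rows],
        )


def _local_maxima_indices(y: np.ndarray) -> np.ndarray:
    """Indices of local maxima: strictly greater than both neighbouring
    values, with plateaus resolved to their leftmost point. Endpoints are
    never maxima."""
    n = y.size
    if n < 3:
        return np.array([], dtype=int)
    change = np.flatnonzero(np.diff(y) != 0)
    starts = np.concatenate(([0], change + 1))
    if starts.size < 3:
        return np.array([], dtype=int)
    vals = y[starts]
    mid = np.arange(1, starts.size - 1)
    is_peak = (vals[mid] > vals[mid - 1]) & (vals[mid] > vals[mid + 1])
    return starts[mid[is_peak]]


def detect_peaks(
    spectrum: Spectrum,
    min_snr: float,
    inner_hw: float = DEFAULT_INNER_HW_NM,
    outer_hw: float = DEFAULT_OUTER_HW_NM,
) -> list[PeakDetection]:
    """All local maxima whose SNR (against a local baseline at the apex) is
    at least ``min_snr``, in ascending apex order.

    Maxima too close to the spectrum edge for a valid flanking baseline
    (fewer than 10 grid points per flank) are skipped.
    """
    x = spectrum.wavelengths_nm
    peaks: list[PeakDetection] = []
    for i in _local_maxima_indices(spectrum.intensities):
        center = float(x[i])
        try:
            base = local_baseline(spectrum, center, inner_hw, outer_hw)
        except ValueError:
            continue
        snr = line_snr(spectrum, center, base)
        if snr >= min_snr:
            peaks.append(
                PeakDetection(
                    apex_nm=center,
                    apex_index=int(i),
                    height=float(spectrum.intensities[i]),
                    snr=snr,
                )
            )
    return peaks


def _match_tol(line: LineSpec, tol_nm: float, broad_tol_nm: float) -> float:
    return broad_tol_nm if preprocessing.is_broad(line) else tol_nm


def match_lines(
    peaks: list[PeakDetection],
    catalogue: list[LineSpec],
    tol_nm: float = DEFAULT_MATCH_TOL_NM,
    broad_tol_nm: float = DEFAULT_BROAD_MATCH_TOL_NM,
) -> list[PeakDetection]:
    """Annotate peaks with their nearest catalogue line within tolerance.

    The assignment is a partial injection: each catalogue line claims at
    most one peak and vice versa. Candidate pairs are ranked by absolute
    wavelength difference, ties broken toward the smaller line wavelength.
    """
    if not catalogue:
        raise ValueError("catalogue must be non-empty")
    candidates = []
    for pi, peak in enumerate(peaks):
        for line in catalogue:
            delta = abs(peak.apex_nm - line.wavelength_nm)
            if delta <= _match_tol(line, tol_nm, broad_tol_nm):
                candidates.append((delta, line.wavelength_nm, pi, line))
    out = [replace(p) for p in peaks]
    used_peaks: set[int] = set()
    used_lines: set[tuple[str, float]] = set()
    for delta, _, pi, line in sorted(candidates, key=lambda c: (c[0], c[1])):
        key = (line.species, line.wavelength_nm)
        if pi in used_peaks or key in used_lines:
            continue
        used_peaks.add(pi)
        used_lines.add(key)
        out[pi].matched_species = line.species
        out[pi].matched_wavelength_nm = line.wavelength_nm
    return out


def detect_line(
    spectrum: Spectrum,
    line: LineSpec,
    catalogue: list[LineSpec],
    min_snr: float,
    tol_nm: float = DEFAULT_MATCH_TOL_NM,
    broad_tol_nm: float = DEFAULT_BROAD_MATCH_TOL_NM,
    inner_hw: float = DEFAULT_INNER_HW_NM,
    outer_hw: float = DEFAULT_OUTER_HW_NM,
    broad_scale: float = DEFAULT_BROAD_SCALE,
) -> bool:
    """True iff a local maximum within the match tolerance of the line has
    SNR strictly above ``min_snr``.

    Targeted equivalent of running :func:`detect_peaks` and
    :func:`match_lines` for one catalogue line; flank regions of other
    catalogue lines are masked out of the baseline.
    """
    x = spectrum.wavelengths_nm
    tol = _match_tol(line, tol_nm, broad_tol_nm)
    lo = np.searchsorted(x, line.wavelength_nm - tol, side="left")
    hi = np.searchsorted(x, line.wavelength_nm + tol, side="right")
    if hi - lo < 1:
        return False
    # include one context point each side so window-edge maxima stay strict
    a = max(lo - 1, 0)
    b = min(hi + 1, x.size)
    local = _local_maxima_indices(spectrum.intensities[a:b]) + a
    local = local[(local >= lo) & (local < hi)]
    if local.size == 0:
        return False
    i_hw, o_hw = line_windows(line, inner_hw, outer_hw, broad_scale)
    excl = exclusion_intervals(catalogue, skip=line)
    for i in local:
        try:
            base = local_baseline(
                spectrum, float(x[i]), i_hw, o_hw, exclude_nm=excl
            )
        except ValueError:
            continue
        if line_snr(spectrum, float(x[i]), base) > min_snr:
            return True
    return False


def exclusion_intervals(
    catalogue: list[LineSpec],
    skip: LineSpec | None = None,
    n_sigmas: float = 3.0,
) -> tuple[tuple[float, float], ...]:
    """+-n_sigma intervals around every catalogue line except ``skip``; used
    to keep neighbouring lines out of baseline flanks."""
    out = []
    for other in catalogue:
        if skip is not None and (
            other.species == skip.species
            and other.wavelength_nm == skip.wavelength_nm
        ):
            continue
        half = n_sigmas * other.profile_sigma_nm
        out.append((other.wavelength_nm - half, other.wavelength_nm + half))
    return tuple(out)


def select_panel(
    cohort: Cohort,
    catalogue: list[LineSpec],
    min_snr: float = DEFAULT_MIN_SNR,
    min_occurrence: float = DEFAULT_MIN_OCCURRENCE,
    tol_nm: float = DEFAULT_MATCH_TOL_NM,
    broad_tol_nm: float = DEFAULT_BROAD_MATCH_TOL_NM,
    inner_hw: float = DEFAULT_INNER_HW_NM,
    outer_hw: float = DEFAULT_OUTER_HW_NM,
    broad_scale: float = DEFAULT_BROAD_SCALE,
    integration_halfwidth_sigmas: float = DEFAULT_INTEGRATION_HALFWIDTH_SIGMAS,
) -> FeaturePanel:
    """Keep catalogue lines detected (matched peak, SNR > ``min_snr``) in at
    least ``min_occurrence`` of the cohort's spectra (inclusive boundary)."""
    if not 0 < min_occurrence <= 1:
        raise ValueError("min_occurrence must be in (0, 1]")
    if len(cohort) == 0:
        raise ValueError("cannot select a panel from an empty cohort")
    n = len(cohort.spectra)
    panel_lines: list[PanelLine] = []
    for line in catalogue:
        hits = sum(
            detect_line(
                s,
                line,
                catalogue,
                min_snr,
                tol_nm,
                broad_tol_nm,
                inner_hw,
                outer_hw,
                broad_scale,
            )
            for s in cohort.spectra
        )
        rate = hits / n
        if rate >= min_occurrence:
            panel_lines.append(
                PanelLine(
                    species=line.species,
                    wavelength_nm=line.wavelength_nm,
                    integration_halfwidth_nm=integration_halfwidth_sigmas
                    * line.profile_sigma_nm,
                    occurrence_rate=rate,
                )
            )
        else:
            logger.info(
                "panel: dropping %s %.3f nm (occurrence %.3f < %.3f)",
                line.species,
                line.wavelength_nm,
                rate,
                min_occurrence,
            )
    return FeaturePanel(lines=panel_lines)


def integrate_feature(
    spectrum: Spectrum,
    center_nm: float,
    halfwidth_nm: float,
    baseline: BaselineEstimate,
) -> float:
    """Baseline-subtracted trapezoidal integral over
    [center - halfwidth, center + halfwidth], floored at zero."""
    x = spectrum.wavelengths_nm
    lo, hi = center_nm - halfwidth_nm, center_nm + halfwidth_nm
    if not spectrum.covers(lo, hi):
        raise ValueError(
            f"integration window [{lo}, {hi}] nm exceeds spectrum range"
        )
    a = np.searchsorted(x, lo, side="left")
    b = np.searchsorted(x, hi, side="right")
    if b - a < 2:
        raise ValueError(
            f"integration window [{lo}, {hi}] nm holds fewer than 2 grid points"
        )
    area = float(np.trapezoid(spectrum.intensities[a:b], x[a:b]))
    area -= baseline.mu * float(x[b - 1] - x[a])
    return max(area, 0.0)


def build_matrix(
    cohort: Cohort,
    panel: FeaturePanel,
    catalogue: list[LineSpec] | None = None,
    inner_hw: float = DEFAULT_INNER_HW_NM,
    outer_hw: float = DEFAULT_OUTER_HW_NM,
    broad_scale: float = DEFAULT_BROAD_SCALE,
) -> FeatureMatrix:
    """One row per spectrum in cohort order: normalize to total intensity,
    then integrate every panel line (undetected lines still yield their
    floored windowed integral, so there are no missing values)."""
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    from sparkspec.preprocessing import normalize_total

    excl_by_line: list[tuple[tuple[float, float], ...]] = []
    windows: list[tuple[float, float]] = []
    for pl in panel.lines:
        if catalogue is not None:
            match = [
                l
                for l in catalogue
                if l.species == pl.species and l.wavelength_nm == pl.wavelength_nm
            ]
            src = match[0] if match else None
        else:
            src = None
        if src is not None:
            windows.append(line_windows(src, inner_hw, outer_hw, broad_scale))
            excl_by_line.append(exclusion_intervals(catalogue, skip=src))
        else:
            broad = pl.integration_halfwidth_nm > 3.0 * preprocessing.BROAD_SIGMA_THRESHOLD_NM
            scale = broad_scale if broad else 1.0
            windows.append((inner_hw * scale, outer_hw * scale))
            excl_by_line.append(())
    rows = np.empty((len(cohort.spectra), len(panel)), dtype=float)
    labels, patients, sids = [], [], []
    for r, s in enumerate(cohort.spectra):
        norm = normalize_total(s)
        for c, pl in enumerate(panel.lines):
            i_hw, o_hw = windows[c]
            base = local_baseline(
                norm, pl.wavelength_nm, i_hw, o_hw, exclude_nm=excl_by_line[c]
            )
            rows[r, c] = integrate_feature(
                norm, pl.wavelength_nm, pl.integration_halfwidth_nm, base
            )
        labels.append(s.tissue_label)
        patients.append(s.patient_id)
        sids.append(s.spectrum_id)
    return FeatureMatrix(
        values=rows,
        feature_names=panel.names,
        labels=np.array(labels, dtype=object),
        patient_ids=np.array(patients, dtype=object),
        spectrum_ids=np.array(sids, dtype=object),
    )


def feature_scores(matrix: FeatureMatrix) -> list[tuple[str, float]]:
    """Absolute standardized mean difference between classes per feature,
    sorted descending. Requires both classes present."""
    lab = matrix.labels
    a = matrix.values[lab == "abnormal"]
    n = matrix.values[lab == "normal"]
    if len(a) == 0 or len(n) == 0:
        raise ValueError("feature_scores requires both classes")
    scores = []
    for j, name in enumerate(matrix.feature_names):
        xa, xn = a[:, j], n[:, j]
        diff = abs(xa.mean() - xn.mean())
        dof = len(xa) + len(xn) - 2
        if dof > 0:
            pooled_var = (
                (len(xa) - 1) * xa.var(ddof=1) if len(xa) > 1 else 0.0
            ) + ((len(xn) - 1) * xn.var(ddof=1) if len(xn) > 1 else 0.0)
            pooled_sd = float(np.sqrt(pooled_var / dof))
        else:
            pooled_sd = 0.0
        if pooled_sd == 0.0:
            score = 0.0 if diff == 0.0 else float("inf")
        else:
            score = diff / pooled_sd
        scores.append((name, float(score)))
    return sorted(scores, key=lambda t: -t[1])
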