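"""Local baselines, line SNR, the carbon-line quality gate and total-intensity
normalization.

The "surrounding baseline" of a line is operationalized as two flanking
annuli ``[c - outer, c - inner]`` and ``[c + inner, c + outer]`` around the
line center ``c``; their pooled mean and population standard deviation give
the baseline estimate. SNR is the baseline-subtracted peak height in units
of the baseline SD, which makes it invariant under global rescaling of the
spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from sparkspec.spectra_io import Cohort, QCRecord, Spectrum
from sparkspec.synthetic_data import LineSpec

logger = logging.getLogger(__name__)

#: Default annulus half-widths for narrow atomic lines, nm.
DEFAULT_INNER_HW_NM = 0.15
DEFAULT_OUTER_HW_NM = 0.60
#: Annulus scale factor for broad entries (Na, C2).
DEFAULT_BROAD_SCALE = 4.0
#: Lines with a profile sigma above this are treated as broad.
BROAD_SIGMA_THRESHOLD_NM = 0.1

#: Carbon atomic line used by the quality gate, and its iron neighbour that
#: must be masked out of the carbon flanks.
CARBON_LINE_NM = 247.856
IRON_LINE_NM = 248.327

DEFAULT_CARBON_SNR_MIN = 20.0

_MIN_FLANK_POINTS = 10
_MIN_POOLED_POINTS = 20


@dataclass(frozen=True)
class BaselineEstimate:
    """Local baseline mean/SD around a line center."""

    center_nm: float
    mu: float
    sd: float
    window_nm: tuple[float, float]  # (inner_halfwidth, outer_halfwidth)
    n_points: int


def is_broad(line: LineSpec) -> bool:
    return line.profile_sigma_nm > BROAD_SIGMA_THRESHOLD_NM


def line_windows(
    line: LineSpec,
    inner_hw: float = DEFAULT_INNER_HW_NM,
    outer_hw: float = DEFAULT_OUTER_HW_NM,
    broad_scale: float = DEFAULT_BROAD_SCALE,
) -> tuple[float, float]:
    """Annulus half-widths for a catalogue line; broad entries get the
    scaled windows."""
    if is_broad(line):
        return inner_hw * broad_scale, outer_hw * broad_scale
    return inner_hw, outer_hw


def _flank_indices(
    x: np.ndarray, lo: float, hi: float
) -> np.ndarray:
    a = np.searchsorted(x, lo, side="left")
    b = np.searchsorted(x, hi, side="right")
    return np.arange(a, b)


def local_baseline(
    spectrum: Spectrum,
    center_nm: float,
    inner_hw: float = DEFAULT_INNER_HW_NM,
    outer_hw: float = DEFAULT_OUTER_HW_NM,
    exclude_nm: tuple[tuple[float, float], ...] = (),
) -> BaselineEstimate:
    """Pooled mean/population-SD of the two flanking annuli.

    ``exclude_nm`` intervals (other catalogue lines) are masked out of the
    flanks after the per-flank point-count check. Constant flanks get a
    machine-epsilon-scaled SD floor instead of zero.
    """
    if not inner_hw < outer_hw:
        raise ValueError("inner_hw must be below outer_hw")
    x = spectrum.wavelengths_nm
    y = spectrum.intensities
    left = _flank_indices(x, center_nm - outer_hw, center_nm - inner_hw)
    right = _flank_indices(x, center_nm + inner_hw, center_nm + outer_hw)
    if left.size < _MIN_FLANK_POINTS or right.size < _MIN_FLANK_POINTS:
        raise ValueError(
            f"baseline at {center_nm} nm: flanks have {left.size}/{right.size} "
            f"points, need >= {_MIN_FLANK_POINTS} each"
        )
    idx = np.concatenate([left, right])
    if exclude_nm:
        keep = np.ones(idx.size, dtype=bool)
        xv = x[idx]
        for lo, hi in exclude_nm:
            keep &= (xv < lo) | (xv > hi)
        idx = idx[keep]
    if idx.size < _MIN_POOLED_POINTS:
        raise ValueError(
            f"baseline at {center_nm} nm: only {idx.size} flank points after "
            f"exclusions, need >= {_MIN_POOLED_POINTS}"
        )
    vals = y[idx]
    mu = float(vals.mean())
    sd = float(vals.std(ddof=0))
    floor = np.finfo(float).eps * max(1.0, abs(mu))
    if sd < floor:
        logger.warning(
            "baseline at %s nm: constant flanks, flooring sd to %g", center_nm, floor
        )
        sd = floor
    return BaselineEstimate(
        center_nm=center_nm,
        mu=mu,
        sd=sd,
        window_nm=(inner_hw, outer_hw),
        n_points=int(idx.size),
    )


def line_snr(
    spectrum: Spectrum, center_nm: float, baseline: BaselineEstimate
) -> float:
    """(peak_height - mu) / sd with peak_height the maximum intensity within
    +-inner_halfwidth of the center."""
    x = spectrum.wavelengths_nm
    if not spectrum.covers(center_nm, center_nm):
        raise ValueError(f"center {center_nm} nm outside spectrum range")
    inner_hw = baseline.window_nm[0]
    a = np.searchsorted(x, center_nm - inner_hw, side="left")
    b = np.searchsorted(x, center_nm + inner_hw, side="right")
    if a >= b:
        raise ValueError(f"no grid points within +-{inner_hw} nm of {center_nm} nm")
    peak_height = float(spectrum.intensities[a:b].max())
    return (peak_height - baseline.mu) / baseline.sd


def carbon_gate(
    spectrum: Spectrum,
    min_snr: float = DEFAULT_CARBON_SNR_MIN,
    inner_hw: float = DEFAULT_INNER_HW_NM,
    outer_hw: float = DEFAULT_OUTER_HW_NM,
) -> bool:
    """True (keep) iff the carbon-line SNR is >= ``min_snr``; spectra
    strictly below are to be excluded. The iron line region is masked out of
    the carbon flanks."""
    lo = CARBON_LINE_NM - outer_hw
    hi = CARBON_LINE_NM + outer_hw
    if not spectrum.covers(lo, hi):
        raise ValueError(
            f"{spectrum.spectrum_id}: spectrum does not cover the carbon line "
            f"window [{lo}, {hi}] nm"
        )
    fe_mask = (IRON_LINE_NM - 0.09, IRON_LINE_NM + 0.09)
    base = local_baseline(
        spectrum, CARBON_LINE_NM, inner_hw, outer_hw, exclude_nm=(fe_mask,)
    )
    return bool(line_snr(spectrum, CARBON_LINE_NM, base) >= min_snr)


def apply_carbon_gate(
    cohort: Cohort, min_snr: float = DEFAULT_CARBON_SNR_MIN
) -> Cohort:
    """Re-flag ``ok`` spectra failing the carbon gate as ``low_carbon_snr``.

    Spectra already excluded by manifest QC keep their status. Follow with
    :func:`sparkspec.spectra_io.apply_qc` to drop the failures.
    """
    status = {rec.spectrum_id: rec.status for rec in cohort.qc}
    n_failed = 0
    qc: list[QCRecord] = []
    for s in cohort.spectra:
        st = status[s.spectrum_id]
        if st == "ok" and not carbon_gate(s, min_snr=min_snr):
            st = "low_carbon_snr"
            n_failed += 1
        qc.append(QCRecord(spectrum_id=s.spectrum_id, status=st))
    if n_failed:
        logger.info("carbon gate: %d spectra flagged low_carbon_snr", n_failed)
    return Cohort(spectra=list(cohort.spectra), qc=qc)


def normalize_total(spectrum: Spectrum) -> Spectrum:
    """Divide intensities by their sum; output sums to 1 within 1e-9.

    Idempotent and scale-invariant; an all-zero spectrum is an error.
    """
    total = float(spectrum.intensities.sum())
    if total <= 0:
        raise ValueError(f"{spectrum.spectrum_id}: total intensity is not positive")
    return spectrum.with_intensities(spectrum.intensities / total)
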