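"""Spectral preprocessing: calibration, centroiding, averaging, background
subtraction and base-peak normalization.

The processing chain mirrors routine time-of-flight workflow: profile scans
are centroided at FWHM (contiguous region above half the local maximum), a
polynomial mass calibration is fitted against a reference standard such as
PEG 600 (protonated oligomer series) and applied, replicate scans are
averaged on a fixed m/z grid, an optional background spectrum is
subtracted, and each spectrum is rescaled so its base peak reads 100%.

All binning in this module and downstream uses half-open intervals
``[lo, lo + w)`` anchored at the lower bound of the acquisition range, so a
peak belongs to exactly one bin regardless of processing order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as P

from .errors import CalibrationError, DataError, EmptyInputError, NormalizationError
from .spectra_io import Mode, Spectrum, SpectrumCollection

#: Default calibrant-peak matching window (u); generous because matching
#: happens before calibration.
DEFAULT_MATCH_TOL_U = 0.05

#: Default calibration polynomial degree.
DEFAULT_CAL_DEGREE = 2


@dataclass(frozen=True)
class ReferenceMassList:
    """Theoretical calibrant m/z values, strictly increasing."""

    masses: np.ndarray
    name: str = "calibrant"

    def __post_init__(self):
        masses = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "masses", masses)
        if masses.ndim != 1 or len(masses) == 0:
            raise DataError("reference mass list must be a non-empty 1-D sequence")
        if np.any(np.diff(masses) <= 0):
            raise DataError("reference masses must be strictly increasing")


@dataclass(frozen=True)
class CalibrationModel:
    """Polynomial map measured m/z -> calibrated m/z.

    ``coefficients`` are in ascending degree order; ``n_matched`` is the
    number of calibrant peaks the fit used and ``rms_residual_u`` the RMS
    residual of the fit in u.
    """

    coefficients: np.ndarray
    n_matched: int
    rms_residual_u: float

    def __post_init__(self):
        coeffs = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        object.__setattr__(self, "coefficients", coeffs)
        if self.n_matched < len(coeffs):
            raise CalibrationError(
                f"{self.n_matched} matched calibrant peaks cannot constrain a "
                f"degree-{len(coeffs) - 1} polynomial"
            )
        if self.rms_residual_u < 0:
            raise CalibrationError("rms_residual_u must be non-negative")

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, mz) -> np.ndarray:
        return P.polyval(np.asarray(mz, dtype=float), self.coefficients)

    @classmethod
    def identity(cls) -> "CalibrationModel":
        return cls(np.array([0.0, 1.0]), n_matched=2, rms_residual_u=0.0)


# ---------------------------------------------------------------------------
# centroiding
# ---------------------------------------------------------------------------

def centroid_spectrum(s: Spectrum, min_rel_height: float = 0.01) -> Spectrum:
    """Reduce a profile spectrum to centroids.

    Each local intensity maximum whose apex exceeds ``min_rel_height`` of
    the base peak becomes one centroid located at the intensity-weighted
    mean m/z over the contiguous points at or above half the apex height
    (FWHM region); the centroid intensity is the summed intensity of that
    region.

    Parameters
    ----------
    s
        Profile-mode spectrum with at least 3 points.
    min_rel_height
        Apex threshold as a fraction of the base peak, in [0, 1).
    """
    if s.mode is not Mode.PROFILE:
        raise DataError("centroid_spectrum requires a profile-mode spectrum")
    if len(s) < 3:
        raise DataError(f"profile spectrum has {len(s)} points; need >= 3")
    if not (0 <= min_rel_height < 1):
        raise DataError("min_rel_height must be in [0, 1)")
    y = s.intensity
    x = s.mz
    base = y.max()
    if base <= 0:
        return s.with_peaks([], [], mode=Mode.CENTROID)
    thresh = min_rel_height * base

    # local maxima: strictly above the left neighbour, at least the right
    # (plateaus resolve to their leftmost point)
    left = np.r_[True, y[1:] > y[:-1]]
    right = np.r_[y[:-1] >= y[1:], True]
    apex_idx = np.flatnonzero(left & right & (y > thresh) & (y > 0))

    mzs, ints = [], []
    for a in apex_idx:
        half = y[a] / 2.0
        lo = a
        while lo > 0 and y[lo - 1] >= half and y[lo - 1] <= y[lo]:
            lo -= 1
        hi = a
        while hi < len(y) - 1 and y[hi + 1] >= half and y[hi + 1] <= y[hi]:
            hi += 1
        seg = slice(lo, hi + 1)
        w = y[seg]
        mzs.append(float(np.average(x[seg], weights=w)))
        ints.append(float(w.sum()))
    if not mzs:
        return s.with_peaks([], [], mode=Mode.CENTROID)
    mz_arr = np.array(mzs)
    int_arr = np.array(ints)
    order = np.argsort(mz_arr)
    mz_arr, int_arr = mz_arr[order], int_arr[order]
    # shared FWHM regions can duplicate a centroid position; keep the first
    keep = np.r_[True, np.diff(mz_arr) > 0]
    return s.with_peaks(mz_arr[keep], int_arr[keep], mode=Mode.CENTROID)


# ---------------------------------------------------------------------------
# mass calibration
# ---------------------------------------------------------------------------

def fit_calibration(
    s: Spectrum,
    ref: ReferenceMassList,
    match_tol_u: float = DEFAULT_MATCH_TOL_U,
    degree: int = DEFAULT_CAL_DEGREE,
) -> CalibrationModel:
    """Fit a polynomial mass calibration from a calibrant spectrum.

    Each reference mass is matched to its nearest observed centroid within
    ``match_tol_u``; unmatched references are ignored.  A least-squares
    polynomial of the given degree maps measured to reference m/z.
    """
    if degree not in (1, 2, 3):
        raise CalibrationError(f"calibration degree must be 1, 2 or 3, got {degree}")
    if s.mode is not Mode.CENTROID:
        raise DataError("fit_calibration requires a centroided spectrum")
    if len(s) == 0:
        raise EmptyInputError("calibrant spectrum is empty")
    measured, target = [], []
    for m_ref in ref.masses:
        j = int(np.argmin(np.abs(s.mz - m_ref)))
        if abs(s.mz[j] - m_ref) <= match_tol_u:
            measured.append(s.mz[j])
            target.append(m_ref)
    n = len(measured)
    if n < degree + 1:
        raise CalibrationError(
            f"only {n} calibrant peaks matched within {match_tol_u} u; "
            f"degree {degree} needs at least {degree + 1}"
        )
    coeffs = P.polyfit(np.array(measured), np.array(target), degree)
    resid = P.polyval(np.array(measured), coeffs) - np.array(target)
    return CalibrationModel(coeffs, n_matched=n,
                            rms_residual_u=float(np.sqrt(np.mean(resid**2))))


def apply_calibration(s: Spectrum, model: CalibrationModel) -> Spectrum:
    """Map every m/z through the calibration polynomial.

    Intensities are untouched.  The polynomial must be monotone increasing
    over the spectrum's acquisition range; a non-monotone map would
    scramble peak order and is rejected.
    """
    lo, hi = s.acquisition_range
    grid = np.linspace(lo, hi, 512)
    mapped_grid = model(grid)
    if np.any(np.diff(mapped_grid) <= 0):
        raise CalibrationError(
            "calibration polynomial is not monotone increasing over "
            f"[{lo}, {hi}]; calibration rejected"
        )
    if len(s) == 0:
        return s
    new_mz = model(s.mz)
    meta = dict(s.meta)
    meta["acquisition_range"] = (
        min(lo, float(new_mz.min())), max(hi, float(new_mz.max()))
    )
    return Spectrum(new_mz, s.intensity, s.mode, s.polarity, meta)


# ---------------------------------------------------------------------------
# grid helpers, averaging, background subtraction
# ---------------------------------------------------------------------------

def _bin_index(mz: np.ndarray, lo: float, width: float) -> np.ndarray:
    """Half-open bin index [lo + k*w, lo + (k+1)*w) for each m/z."""
    return np.floor((mz - lo) / width).astype(np.int64)


def _grid_origin(spectra) -> float:
    return min(s.acquisition_range[0] for s in spectra)


def average_spectra(spectra: SpectrumCollection, grid_width_u: float = 0.005) -> Spectrum:
    """Average centroided replicate spectra on a common m/z grid.

    Peaks from all spectra are pooled into half-open bins of width
    ``grid_width_u``; the per-bin intensity is the arithmetic mean over the
    input spectra (a spectrum with no peak in a bin contributes zero) and
    the per-bin m/z is the intensity-weighted mean of the pooled peaks.
    """
    if len(spectra) == 0:
        raise EmptyInputError("cannot average an empty spectrum collection")
    for s in spectra:
        if s.mode is not Mode.CENTROID:
            raise DataError("average_spectra requires centroided spectra")
    if grid_width_u <= 0:
        raise DataError("grid_width_u must be positive")
    lo = _grid_origin(spectra)
    n = len(spectra)
    sums: dict[int, float] = {}
    wmz: dict[int, float] = {}
    for s in spectra:
        if len(s) == 0:
            continue
        idx = _bin_index(s.mz, lo, grid_width_u)
        for k, m, i in zip(idx, s.mz, s.intensity):
            k = int(k)
            sums[k] = sums.get(k, 0.0) + i
            wmz[k] = wmz.get(k, 0.0) + i * m
    keys = sorted(k for k in sums if sums[k] > 0)
    mz_out = np.array([wmz[k] / sums[k] for k in keys])
    int_out = np.array([sums[k] / n for k in keys])
    ref = spectra[0]
    meta = {"acquisition_range": ref.acquisition_range, "n_averaged": n}
    return Spectrum(mz_out, int_out, Mode.CENTROID, ref.polarity, meta)


def subtract_background(
    s: Spectrum, bg: Spectrum, grid_width_u: float = 0.005
) -> Spectrum:
    """Subtract a background spectrum bin-wise, clamping at zero.

    Both spectra are binned on the shared grid; the output intensity per
    bin is ``max(0, s_bin - bg_bin)`` and empty bins are dropped.  The
    output m/z of a surviving bin is the intensity-weighted mean of the
    sample's peaks in that bin.
    """
    if s.mode is not Mode.CENTROID or bg.mode is not Mode.CENTROID:
        raise DataError("subtract_background requires centroided spectra")
    if grid_width_u <= 0:
        raise DataError("grid_width_u must be positive")
    lo = min(s.acquisition_range[0], bg.acquisition_range[0])

    def _bin(spec):
        sums, wmz = {}, {}
        if len(spec):
            idx = _bin_index(spec.mz, lo, grid_width_u)
            for k, m, i in zip(idx, spec.mz, spec.intensity):
                k = int(k)
                sums[k] = sums.get(k, 0.0) + i
                wmz[k] = wmz.get(k, 0.0) + i * m
        return sums, wmz

    s_sum, s_wmz = _bin(s)
    bg_sum, _ = _bin(bg)
    keys = sorted(s_sum)
    mz_out, int_out = [], []
    for k in keys:
        val = s_sum[k] - bg_sum.get(k, 0.0)
        if val > 0:
            mz_out.append(s_wmz[k] / s_sum[k])
            int_out.append(val)
    return s.with_peaks(np.array(mz_out), np.array(int_out))


def normalize_base_peak(s: Spectrum) -> Spectrum:
    """Rescale intensities so the base peak reads 100 (relative %)."""
    if len(s) == 0 or s.base_peak_intensity <= 0:
        raise NormalizationError(
            "cannot base-peak normalize a spectrum with no positive intensity"
        )
    return s.with_peaks(s.mz, s.intensity * (100.0 / s.base_peak_intensity))
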