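"""Analysis-ready representations of preprocessed spectra.

Two views of a set of spectra feed the downstream statistics:

* the *fingerprint matrix* (the "heat map"): samples x m/z-bin relative
  abundances over the full spectrum, the input to unsupervised clustering;
* the *feature table*: samples x selected target masses, the input to
  supervised classification.

Within-bin and within-window aggregation is the maximum peak intensity:
spectra are centroided, so one chemotype ion is expected per window and a
sum would double-count split centroids.

The fingerprint matrix exports to (and re-imports from) the tab-delimited
dialect of the Cluster 3.0 program, with a ``UNIQID`` leading column and
one row per sample, so heat maps can flow into external clustering tools
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, DataError, EmptyInputError, FormatError
from .preprocess import _bin_index, _grid_origin
from .spectra_io import Mode, SpectrumCollection

#: Default heat-map bin width (u).  Integer-mass binning absorbs ppm-level
#: mass error (5 ppm at m/z 1000 is 0.005 u, far below 1 u), so replicate
#: peaks of one compound always share a bin, and yields variable counts of
#: the order of a few hundred on chemotype-rich spectra over m/z 60-1000.
DEFAULT_BIN_WIDTH_U = 1.0

#: Default retention threshold: a bin is kept if any sample reaches this
#: relative abundance (%).
DEFAULT_MIN_REL_ABUNDANCE_PCT = 1.0

#: Default feature-window half-width (u), mid-range of the 0.005-0.015 u
#: windows typical for high-resolution TOF data.
DEFAULT_FEATURE_TOL_U = 0.01


@dataclass
class FingerprintMatrix:
    """Samples x m/z-bin relative-abundance matrix (the heat map)."""

    values: np.ndarray
    bin_centers: np.ndarray
    bin_width_u: float
    sample_ids: list[str]
    labels: Optional[list[str]] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        if self.values.ndim != 2:
            raise DataError("fingerprint values must be 2-D (samples x bins)")
        if self.values.shape[1] != len(self.bin_centers):
            raise DataError("column count must equal number of bin centers")
        if len(self.sample_ids) != self.values.shape[0]:
            raise DataError("sample_ids length must equal row count")
        if self.labels is not None and len(self.labels) != self.values.shape[0]:
            raise DataError("labels length must equal row count")
        if self.values.size and (
            self.values.min() < 0 or self.values.max() > 100 + 1e-9
        ):
            raise DataError("relative abundances must lie in [0, 100]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureTable:
    """Samples x target-mass abundance matrix for supervised analysis."""

    values: np.ndarray
    target_mz: np.ndarray
    tolerance_u: float
    sample_ids: list[str]
    labels: Optional[list[str]] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.target_mz = np.asarray(self.target_mz, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.target_mz):
            raise DataError("values must be samples x targets")
        if np.any(np.diff(self.target_mz) <= 0):
            raise DataError("target masses must be unique and ascending")
        if not (0.001 <= self.tolerance_u <= 0.05):
            raise ConfigError(
                f"tolerance_u {self.tolerance_u} outside supported [0.001, 0.05]"
            )
        if self.values.size and self.values.min() < 0:
            raise DataError("feature abundances must be non-negative")
        if len(self.sample_ids) != self.values.shape[0]:
            raise DataError("sample_ids length must equal row count")
        if self.labels is not None and len(self.labels) != self.values.shape[0]:
            raise DataError("labels length must equal row count")


def _sample_ids(spectra: SpectrumCollection) -> list[str]:
    ids = []
    for i, s in enumerate(spectra):
        ids.append(str(s.meta.get("sample_id", f"sample_{i}")))
    return ids


def build_fingerprint_matrix(
    spectra: SpectrumCollection,
    bin_width_u: float = DEFAULT_BIN_WIDTH_U,
    min_rel_abundance_pct: float = DEFAULT_MIN_REL_ABUNDANCE_PCT,
) -> FingerprintMatrix:
    """Bin base-peak-normalized centroid spectra into the heat-map matrix.

    Each spectrum is distributed over half-open bins of ``bin_width_u``
    anchored at the acquisition-range lower bound, keeping the maximum
    intensity per bin.  Bins in which no sample reaches
    ``min_rel_abundance_pct`` are dropped; rows keep their per-sample
    base-peak scale (max 100 before bin filtering).
    """
    if len(spectra) == 0:
        raise EmptyInputError("cannot fingerprint an empty collection")
    if bin_width_u <= 0:
        raise ConfigError("bin_width_u must be positive")
    for s in spectra:
        if s.mode is not Mode.CENTROID:
            raise DataError("fingerprinting requires centroided spectra")
        if len(s) and s.intensity.max() > 100 + 1e-9:
            raise DataError(
                "spectra must be base-peak normalized (max intensity 100)"
            )
    lo = _grid_origin(spectra)
    per_sample: list[dict[int, float]] = []
    all_bins: set[int] = set()
    for s in spectra:
        d: dict[int, float] = {}
        if len(s):
            idx = _bin_index(s.mz, lo, bin_width_u)
            for k, i in zip(idx, s.intensity):
                k = int(k)
                if i > d.get(k, -1.0):
                    d[k] = float(i)
        per_sample.append(d)
        all_bins.update(d)
    kept = sorted(
        k for k in all_bins
        if any(d.get(k, 0.0) >= min_rel_abundance_pct for d in per_sample)
    )
    values = np.zeros((len(spectra), len(kept)))
    col = {k: j for j, k in enumerate(kept)}
    for i, d in enumerate(per_sample):
        for k, v in d.items():
            if k in col:
                values[i, col[k]] = v
    centers = lo + (np.array(kept, dtype=float) + 0.5) * bin_width_u
    return FingerprintMatrix(
        values, centers, bin_width_u, _sample_ids(spectra),
        list(spectra.labels) if spectra.labels is not None else None,
    )


def extract_features(
    spectra: SpectrumCollection,
    target_mz: Sequence[float],
    tolerance_u: float = DEFAULT_FEATURE_TOL_U,
) -> FeatureTable:
    """Pick the maximum peak intensity within each target mass window.

    A cell is the largest peak intensity in ``[target - tol, target + tol]``
    for that sample, or 0 when no peak falls inside.  Windows must be
    pairwise disjoint at the given tolerance.
    """
    targets = np.sort(np.asarray(target_mz, dtype=float))
    if len(targets) == 0:
        raise ConfigError("target_mz list is empty")
    if len(np.unique(targets)) != len(targets):
        raise ConfigError("target masses must be unique")
    if not (0.001 <= tolerance_u <= 0.05):
        raise ConfigError(
            f"tolerance_u {tolerance_u} outside supported [0.001, 0.05]"
        )
    gaps = np.diff(targets)
    bad = np.flatnonzero(gaps <= 2 * tolerance_u)
    if len(bad):
        j = bad[0]
        raise ConfigError(
            f"feature windows overlap: targets {targets[j]:.6f} and "
            f"{targets[j + 1]:.6f} are closer than 2 x {tolerance_u} u"
        )
    if len(spectra) == 0:
        raise EmptyInputError("cannot extract features from an empty collection")
    values = np.zeros((len(spectra), len(targets)))
    for i, s in enumerate(spectra):
        if len(s) == 0:
            continue
        lo_idx = np.searchsorted(s.mz, targets - tolerance_u, side="left")
        hi_idx = np.searchsorted(s.mz, targets + tolerance_u, side="right")
        for j, (a, b) in enumerate(zip(lo_idx, hi_idx)):
            if b > a:
                values[i, j] = s.intensity[a:b].max()
    return FeatureTable(
        values, targets, tolerance_u, _sample_ids(spectra),
        list(spectra.labels) if spectra.labels is not None else None,
    )


# ---------------------------------------------------------------------------
# Cluster-3.0-dialect matrix text format
# ---------------------------------------------------------------------------

def export_cluster_matrix(m: FingerprintMatrix, path) -> None:
    """Write the heat map as a Cluster-3.0-style tab-delimited matrix.

    First header cell is ``UNIQID``, remaining header cells are bin centers
    to 4 decimals; one row per sample (samples are the clustered items).
    """
    path = Path(path)
    lines = ["\t".join(["UNIQID"] + [f"{c:.4f}" for c in m.bin_centers])]
    for sid, row in zip(m.sample_ids, m.values):
        lines.append("\t".join([sid] + [f"{v:.6g}" for v in row]))
    path.write_text("\n".join(lines) + "\n")


def import_cluster_matrix(path, bin_width_u: float = DEFAULT_BIN_WIDTH_U) -> FingerprintMatrix:
    """Read a matrix written by :func:`export_cluster_matrix`."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise EmptyInputError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    if header[0] != "UNIQID":
        raise FormatError(f"{path}: first header cell must be 'UNIQID'")
    try:
        centers = np.array([float(c) for c in header[1:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric bin center in header ({exc})")
    ids, rows = [], []
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}: row for {fields[0]!r} has {len(fields) - 1} values, "
                f"expected {len(header) - 1}"
            )
        ids.append(fields[0])
        rows.append([float(v) for v in fields[1:]])
    return FingerprintMatrix(np.array(rows), centers, bin_width_u, ids)
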