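"""Spectrum containers and peak-list / mzML input-output.

A :class:`Spectrum` is one sample's mass spectrum: parallel m/z and
intensity arrays plus acquisition metadata.  Centroided spectra (one point
per ion) are the working representation throughout the package; profile
(continuum) spectra only occur on input and are reduced by
:func:`chemoprint.preprocess.centroid_spectrum`.

Peak lists are plain delimited text in the style of supplementary data
tables: one ``m/z<sep>intensity`` row per peak, comma or tab separated,
with an optional header line.  mzML is read through :mod:`pyteomics.mzml`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

from .errors import (
    DataError,
    EmptyInputError,
    FormatError,
    PeakListParseError,
)

#: Default acquisition m/z range (u); spectra declare their own in ``meta``.
DEFAULT_ACQUISITION_RANGE = (60.0, 1000.0)


class Mode(str, enum.Enum):
    CENTROID = "centroid"
    PROFILE = "profile"


class Polarity(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class Dialect(str, enum.Enum):
    """Peak-list text dialects accepted by :func:`read_peaklist`."""

    TWO_COLUMN = "two_column"
    LABELED_CSV = "labeled_csv"


@dataclass(frozen=True)
class Spectrum:
    """One sample's m/z-intensity pairs with acquisition metadata.

    Parameters
    ----------
    mz, intensity
        Parallel arrays.  For centroid mode ``mz`` must be strictly
        increasing; for profile mode non-decreasing.  Intensities are
        non-negative (raw counts or relative %).
    mode
        ``centroid`` or ``profile``.
    polarity
        Ion polarity of the acquisition.
    meta
        Free-form mapping; recognised keys are ``sample_id``,
        ``species_label``, ``replicate_index``, ``gas_temperature_C`` and
        ``acquisition_range`` (a ``(lo, hi)`` pair of m/z bounds).
    """

    mz: np.ndarray
    intensity: np.ndarray
    mode: Mode = Mode.CENTROID
    polarity: Polarity = Polarity.POSITIVE
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        object.__setattr__(self, "mode", Mode(self.mode))
        object.__setattr__(self, "polarity", Polarity(self.polarity))
        if mz.ndim != 1 or inten.ndim != 1:
            raise DataError("mz and intensity must be one-dimensional")
        if len(mz) != len(inten):
            raise DataError(
                f"mz and intensity lengths differ ({len(mz)} vs {len(inten)})"
            )
        if len(mz):
            dmz = np.diff(mz)
            if self.mode is Mode.CENTROID and np.any(dmz <= 0):
                raise DataError("centroid spectrum m/z must be strictly increasing")
            if self.mode is Mode.PROFILE and np.any(dmz < 0):
                raise DataError("profile spectrum m/z must be non-decreasing")
            if np.any(inten < 0):
                raise DataError("intensities must be non-negative")
            lo, hi = self.acquisition_range
            if mz[0] < lo or mz[-1] > hi:
                raise DataError(
                    f"m/z values outside declared acquisition range [{lo}, {hi}]"
                )

    @property
    def acquisition_range(self) -> tuple[float, float]:
        return tuple(self.meta.get("acquisition_range", DEFAULT_ACQUISITION_RANGE))

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self.intensity) else 0.0

    def __len__(self) -> int:
        return len(self.mz)

    def with_peaks(self, mz, intensity, mode: Mode | None = None) -> "Spectrum":
        """Copy of this spectrum with replaced peak arrays (metadata kept)."""
        return replace(
            self, mz=np.asarray(mz, float), intensity=np.asarray(intensity, float),
            mode=self.mode if mode is None else mode,
        )


@dataclass
class SpectrumCollection:
    """Ordered set of spectra with optional parallel class labels."""

    spectra: list[Spectrum]
    labels: Optional[list[str]] = None

    def __post_init__(self):
        self.spectra = list(self.spectra)
        if self.labels is not None:
            self.labels = [str(x) for x in self.labels]
            if len(self.labels) != len(self.spectra):
                raise DataError(
                    f"labels length {len(self.labels)} != spectra length "
                    f"{len(self.spectra)}"
                )
        polarities = {s.polarity for s in self.spectra}
        if len(polarities) > 1:
            raise DataError("all spectra in a collection must share polarity")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i) -> Spectrum:
        return self.spectra[i]


# ---------------------------------------------------------------------------
# peak-list text format
# ---------------------------------------------------------------------------

def _merge_duplicates(mz: np.ndarray, inten: np.ndarray):
    """Sort by m/z and sum intensities of identical m/z values.

    Duplicate rows represent split centroids of one ion, so their
    intensities add.
    """
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    if len(mz) == 0:
        return mz, inten
    uniq, inverse = np.unique(mz, return_inverse=True)
    summed = np.zeros(len(uniq))
    np.add.at(summed, inverse, inten)
    return uniq, summed


def _detect_separator(line: str) -> str:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # whitespace fallback


def read_peaklist(
    path,
    dialect: Dialect | str = Dialect.TWO_COLUMN,
    polarity: Polarity | str = Polarity.POSITIVE,
    meta: Optional[dict] = None,
) -> Spectrum:
    """Read a delimited peak list into a centroid-mode :class:`Spectrum`.

    ``two_column`` rows are ``m/z<sep>intensity`` with comma or tab
    auto-detected and an optional non-numeric header line.  ``labeled_csv``
    is comma-separated with a mandatory header naming ``mz`` and
    ``intensity`` columns (extra columns ignored).  Duplicate m/z rows are
    merged by summing intensity and output is sorted ascending.
    """
    dialect = Dialect(dialect)
    path = Path(path)
    lines = path.read_text().splitlines()
    rows: list[tuple[float, float]] = []
    col_mz, col_int = 0, 1
    sep = None
    started = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if sep is None:
            sep = _detect_separator(line) if dialect is Dialect.TWO_COLUMN else ","
        fields = [f.strip() for f in line.split(sep)] if sep else line.split()
        if not started:
            started = True
            if dialect is Dialect.LABELED_CSV:
                header = [h.lower() for h in fields]
                try:
                    col_mz = header.index("mz")
                    col_int = header.index("intensity")
                except ValueError:
                    raise PeakListParseError(
                        path, lineno,
                        "labeled_csv header must contain 'mz' and 'intensity' "
                        f"columns, got {fields!r}",
                    )
                continue
            # two_column: a non-numeric first row is an optional header
            try:
                float(fields[0])
            except (ValueError, IndexError):
                continue
        if len(fields) <= max(col_mz, col_int):
            raise PeakListParseError(
                path, lineno, f"expected at least {max(col_mz, col_int) + 1} "
                f"fields, got {len(fields)}"
            )
        try:
            rows.append((float(fields[col_mz]), float(fields[col_int])))
        except ValueError as exc:
            raise PeakListParseError(path, lineno, f"non-numeric field: {exc}")
    if not rows:
        raise EmptyInputError(f"{path}: no peaks found")
    mz, inten = _merge_duplicates(
        np.array([r[0] for r in rows]), np.array([r[1] for r in rows])
    )
    full_meta = {"sample_id": path.stem}
    if meta:
        full_meta.update(meta)
    return Spectrum(mz, inten, Mode.CENTROID, polarity, full_meta)


def write_peaklist(s: Spectrum, path) -> None:
    """Write ``s`` as a two-column comma-separated peak list.

    Values are printed with 9 decimals so a read-back round-trip agrees
    within 1e-9 on both fields (sub-µu, far below the 0.005 u feature
    windows).  An empty spectrum yields a header-only file.
    """
    path = Path(path)
    lines = ["# chemoprint peak list", "mz,intensity"]
    lines += [f"{m:.9f},{i:.9f}" for m, i in zip(s.mz, s.intensity)]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

# cv accessions understood by the minimal mzML reader
_CV_MZ_ARRAY = "MS:1000514"
_CV_INTENSITY_ARRAY = "MS:1000515"
_CV_FLOAT64 = "MS:1000523"
_CV_FLOAT32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_NEGATIVE_SCAN = "MS:1000129"
_CV_MS_LEVEL = "MS:1000511"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(elem) -> np.ndarray:
    """Decode one <binaryDataArray>: base64, optional zlib, 32/64-bit float."""
    import base64
    import zlib

    accessions = set()
    payload = ""
    for child in elem:
        name = _local(child.tag)
        if name == "cvParam":
            accessions.add(child.get("accession"))
        elif name == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload)
    if _CV_ZLIB in accessions:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _CV_FLOAT32 in accessions else "<f8"
    kind = None
    if _CV_MZ_ARRAY in accessions:
        kind = "mz"
    elif _CV_INTENSITY_ARRAY in accessions:
        kind = "intensity"
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_profile_mzml(path) -> SpectrumCollection:
    """Read MS1 scans of an mzML file as profile-mode spectra.

    One :class:`Spectrum` per scan in acquisition order; scans with zero
    data points are retained as empty spectra.  This is a self-contained
    reader for the subset of mzML the package consumes — MS1 spectra with
    base64-encoded (optionally zlib-compressed) 32/64-bit float m/z and
    intensity arrays.
    """
    from lxml import etree

    path = Path(path)
    spectra = []
    try:
        tree = etree.parse(str(path))
        spec_elems = [
            el for el in tree.iter() if _local(el.tag) == "spectrum"
        ]
        if not spec_elems:
            raise FormatError(f"{path}: no <spectrum> elements found")
        for i, el in enumerate(spec_elems):
            accessions = {
                (c.get("accession"), c.get("value"))
                for c in el if _local(c.tag) == "cvParam"
            }
            ms_level = next(
                (v for a, v in accessions if a == _CV_MS_LEVEL), "1"
            )
            if ms_level not in (None, "", "1"):
                continue
            polarity = (
                Polarity.NEGATIVE
                if any(a == _CV_NEGATIVE_SCAN for a, _ in accessions)
                else Polarity.POSITIVE
            )
            arrays = {"mz": np.array([]), "intensity": np.array([])}
            for bda in el.iter():
                if _local(bda.tag) == "binaryDataArray":
                    kind, values = _decode_binary_array(bda)
                    if kind:
                        arrays[kind] = values
            mz, inten = arrays["mz"], arrays["intensity"]
            meta = {"sample_id": el.get("id", f"scan={i}")}
            if len(mz):
                lo, hi = DEFAULT_ACQUISITION_RANGE
                meta["acquisition_range"] = (
                    min(lo, float(mz.min())), max(hi, float(mz.max()))
                )
            spectra.append(Spectrum(mz, inten, Mode.PROFILE, polarity, meta))
    except (DataError, FormatError):
        raise
    except Exception as exc:
        raise FormatError(f"{path}: not a readable mzML file ({exc})")
    return SpectrumCollection(spectra)


def read_reference_masses(path) -> np.ndarray:
    """Read a calibrant reference mass list: one m/z per line, '#' comments."""
    values = []
    path = Path(path)
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            values.append(float(line))
        except ValueError:
            raise PeakListParseError(path, lineno, f"non-numeric mass {line!r}")
    if not values:
        raise EmptyInputError(f"{path}: no reference masses")
    arr = np.array(values)
    if np.any(np.diff(arr) <= 0):
        raise DataError(f"{path}: reference masses must be strictly increasing")
    return arr
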