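"""Shared fixtures: synthetic mzML writing and canonical datasets."""

import base64
import struct
import zlib
from pathlib import Path

import numpy as np
import pytest

import chemoprint as cp

CANONICAL_SEED = 42


def _encode_array(values) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(zlib.compress(raw)).decode()


def write_synthetic_mzml(path, scans):
    """Write a minimal synthetic mzML file readable by pyteomics.

    ``scans`` is a sequence of (mz_array, intensity_array) pairs.  The
    document is hand-assembled for test purposes only (no mzML writer is
    part of the package); it carries the required CV params for m/z and
    intensity binary arrays, 64-bit floats, zlib compressed.
    """
    spectra_xml = []
    for i, (mz, inten) in enumerate(scans):
        mz = list(map(float, mz))
        inten = list(map(float, inten))
        arrays = []
        for acc, name, data in [
            ("MS:1000514", "m/z array", mz),
            ("MS:1000515", "intensity array", inten),
        ]:
            b64 = _encode_array(data)
            arrays.append(f"""
        <binaryDataArray encodedLength="{len(b64)}">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
          <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression"/>
          <cvParam cvRef="MS" accession="{acc}" name="{name}"/>
          <binary>{b64}</binary>
        </binaryDataArray>""")
        spectra_xml.append(f"""
      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(mz)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum"/>
        <cvParam cvRef="MS" accession="MS:1000130" name="positive scan"/>
        <binaryDataArrayList count="2">{''.join(arrays)}
        </binaryDataArrayList>
      </spectrum>""")
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="synthetic_run">
    <spectrumList count="{len(scans)}" defaultDataProcessingRef="dp">
{''.join(spectra_xml)}
    </spectrumList>
  </run>
</mzML>
"""
    Path(path).write_text(doc)


@pytest.fixture
def mzml_writer():
    return write_synthetic_mzml


@pytest.fixture(scope="session")
def study_profiles():
    """Five well-separated species profiles at the study conditions."""
    return cp.make_species_profiles(
        5, 25, shared_fraction=0.5, separation=1.0,
        seed=CANONICAL_SEED, abundance_cv=0.1,
    )


@pytest.fixture(scope="session")
def study_noise():
    return cp.NoiseModel(mass_error_ppm_sd=5.0, dropout_probability=0.02,
                         baseline_peak_rate=5.0, baseline_rel_intensity_max=2.0)


@pytest.fixture(scope="session")
def study_dataset(study_profiles, study_noise):
    coll, labels = cp.simulate_dataset(
        study_profiles, 5, study_noise, seed=CANONICAL_SEED
    )
    return coll, labels
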