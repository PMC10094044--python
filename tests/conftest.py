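import base64
import struct

import numpy as np
import pytest

from sdms import Scan, ScanSeries


def _b64(values) -> str:
    return base64.b64encode(struct.pack("<%dd" % len(values), *values)).decode()


def _spectrum(i: int, t_min: float, mzs, ints) -> str:
    return f"""
  <spectrum index="{i}" id="scan={i}" defaultArrayLength="{len(mzs)}">
    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
    <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    <scanList count="1"><scan>
      <cvParam cvRef="MS" accession="MS:1000016" name="scan start time"
               value="{t_min}" unitName="minute"/>
    </scan></scanList>
    <binaryDataArrayList count="2">
      <binaryDataArray encodedLength="0">
        <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
        <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
        <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
        <binary>{_b64(mzs)}</binary>
      </binaryDataArray>
      <binaryDataArray encodedLength="0">
        <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
        <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
        <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
        <binary>{_b64(ints)}</binary>
      </binaryDataArray>
    </binaryDataArrayList>
  </spectrum>"""


@pytest.fixture
def mzml_factory(tmp_path):
    """Write a minimal centroided mzML document from (time, mzs, ints) triples."""

    def build(spectra, name="fixture.mzml"):
        parts = [
            _spectrum(i, t, list(mzs), list(ints))
            for i, (t, mzs, ints) in enumerate(spectra)
        ]
        doc = (
            '<?xml version="1.0" encoding="utf-8"?>\n'
            '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
            f'<run id="r"><spectrumList count="{len(parts)}">{"".join(parts)}\n'
            "</spectrumList></run></mzML>\n"
        )
        path = tmp_path / name
        path.write_text(doc)
        return path

    return build


@pytest.fixture
def random_series_factory():
    """Seeded random ScanSeries for round-trip property checks."""

    def build(seed: int, n_scans: int = 5, max_peaks: int = 4) -> ScanSeries:
        rng = np.random.default_rng(seed)
        scans = []
        for i in range(n_scans):
            k = rng.integers(1, max_peaks + 1)
            mzs = np.round(rng.uniform(100, 500, k), 6)
            ints = np.round(rng.uniform(0, 1e6, k), 6)
            scans.append(Scan(index=i, time=round(i * 0.01, 6), peaks=tuple(zip(mzs, ints))))
        return ScanSeries(scans=scans, segment_label=f"rt{seed}")

    return build
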