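"""Shared fixtures: trace factories and a programmatic mzML writer."""

from __future__ import annotations

import base64
import struct

import numpy as np
import pytest

from mrmflow import Chromatogram, TransitionKey


@pytest.fixture
def key():
    return TransitionKey(468.3, 184.1, "positive")


@pytest.fixture
def gaussian_trace(key):
    """Factory: Gaussian peak(s) on a uniform grid, optional sloped baseline."""

    def make(
        centers=(10.0,),
        heights=(1000.0,),
        sd=0.2,
        t_start=0.0,
        t_end=20.0,
        dt=0.05,
        baseline_slope=0.0,
        sample_id=None,
        transition=key,
    ):
        t = t_start + dt * np.arange(int(round((t_end - t_start) / dt)) + 1)
        y = baseline_slope * (t - t_start)
        for c, h in zip(centers, heights):
            y = y + h * np.exp(-0.5 * ((t - c) / sd) ** 2)
        return Chromatogram(transition=transition, times=t, intensities=y, sample_id=sample_id)

    return make


def _b64(arr) -> str:
    return base64.b64encode(struct.pack(f"<{len(arr)}d", *arr)).decode()


def _binary_xml(arr, accession, name, unit_attr="") -> str:
    payload = _b64(arr)
    return (
        f'<binaryDataArray encodedLength="{len(payload)}">'
        '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
        f'<cvParam cvRef="MS" accession="{accession}" name="{name}" value=""{unit_attr}/>'
        f"<binary>{payload}</binary></binaryDataArray>"
    )


def srm_chromatogram_xml(
    index,
    chrom_id,
    precursor,
    product,
    times,
    intensities,
    polarity="positive",
    time_unit="minute",
    omit_product=False,
):
    unit_attr = (
        ' unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"'
        if time_unit == "minute"
        else ' unitCvRef="UO" unitAccession="UO:0000010" unitName="second"'
    )
    pol_acc, pol_name = (
        ("MS:1000130", "positive scan") if polarity == "positive" else ("MS:1000129", "negative scan")
    )
    product_xml = (
        ""
        if omit_product
        else (
            "<product><isolationWindow>"
            f'<cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{product}"/>'
            "</isolationWindow></product>"
        )
    )
    return (
        f'<chromatogram id="{chrom_id}" index="{index}" defaultArrayLength="{len(times)}">'
        '<cvParam cvRef="MS" accession="MS:1001473" name="selected reaction monitoring chromatogram" value=""/>'
        f'<cvParam cvRef="MS" accession="{pol_acc}" name="{pol_name}" value=""/>'
        "<precursor><isolationWindow>"
        f'<cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{precursor}"/>'
        "</isolationWindow></precursor>"
        f"{product_xml}<binaryDataArrayList count=\"2\">"
        f'{_binary_xml(times, "MS:1000595", "time array", unit_attr)}'
        f'{_binary_xml(intensities, "MS:1000515", "intensity array")}'
        "</binaryDataArrayList></chromatogram>"
    )


def tic_chromatogram_xml(index, times, intensities):
    minute_unit = ' unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"'
    return (
        f'<chromatogram id="TIC" index="{index}" defaultArrayLength="{len(times)}">'
        '<cvParam cvRef="MS" accession="MS:1000235" name="total ion current chromatogram" value=""/>'
        '<binaryDataArrayList count="2">'
        f'{_binary_xml(times, "MS:1000595", "time array", minute_unit)}'
        f'{_binary_xml(intensities, "MS:1000515", "intensity array")}'
        "</binaryDataArrayList></chromatogram>"
    )


def write_mzml(path, chromatogram_xml_blocks):
    blocks = "\n".join(chromatogram_xml_blocks)
    doc = (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        '<cvList count="2"><cv id="MS" fullName="PSI-MS" URI="x"/><cv id="UO" fullName="UO" URI="y"/></cvList>\n'
        f'<run id="r1"><chromatogramList count="{len(chromatogram_xml_blocks)}" '
        'defaultDataProcessingRef="dp1">\n'
        f"{blocks}\n"
        "</chromatogramList></run></mzML>\n"
    )
    path.write_text(doc)
    return path
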