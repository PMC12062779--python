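"""mzML reading/writing, the spectrum data model, and TIC/XIC chronograms.

Both directions are implemented on lxml directly: a namespace-aware
reader for MS1 centroid spectra (64/32-bit float arrays, zlib or no
compression, indexed or plain mzML) and a compact mzML 1.1.0 writer
limited to what the platform produces — centroid MS1 spectra with scan
start times and uncompressed 64-bit float arrays.  Round trips are tested
against the Bioconductor ``mzR`` reader as an independent check.
"""

from __future__ import annotations

import base64
import csv
import io
import logging
import struct
import zlib
from dataclasses import dataclass

import numpy as np
from lxml import etree

__all__ = [
    "Spectrum",
    "Chronogram",
    "read_mzml",
    "write_mzml",
    "tic",
    "xic",
    "chronogram_csv",
    "DEFAULT_TIC_RANGE",
]

log = logging.getLogger(__name__)

#: m/z window used for TIC traces when none is given (small-molecule scans).
DEFAULT_TIC_RANGE = (150.0, 500.0)

_NS = "http://psi.hupo.org/ms/mzml"


@dataclass(frozen=True)
class Spectrum:
    """One time-stamped centroid mass spectrum.

    ``mz`` is strictly increasing and the same length as ``intensity``;
    intensities are non-negative.  ``scan_time`` is seconds since the
    start of the acquisition.
    """

    scan_time: float
    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "positive"
    ms_level: int = 1
    id: str = ""

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-d arrays of equal length")
        if mz.size > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError("mz must be strictly increasing")
        if inten.size and float(inten.min()) < 0:
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class Chronogram:
    """Intensity versus scan time: TIC or XIC of a spectrum list."""

    times: np.ndarray
    values: np.ndarray
    kind: str  # "TIC" | "XIC"
    mz_range: tuple[float, float]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape:
            raise ValueError("times and values must have equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")


# ---------------------------------------------------------------------------
# mzML

def _q(tag: str) -> str:
    return f"{{{_NS}}}{tag}"


def _decode_binary_array(bda) -> np.ndarray:
    accs = {cv.get("accession") for cv in bda.iter(_q("cvParam"))}
    binary = bda.find(_q("binary"))
    raw = base64.b64decode(binary.text or "")
    if "MS:1000574" in accs:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(el, index: int) -> Spectrum | None:
    cvs = {cv.get("accession"): cv for cv in el.iter(_q("cvParam"))}
    level = int(cvs["MS:1000511"].get("value")) if "MS:1000511" in cvs else 1
    if level != 1:
        log.warning("skipping MS%s scan %s (only MS1 supported)", level, index)
        return None
    t_cv = cvs.get("MS:1000016")
    if t_cv is None:
        raise ValueError(f"spectrum index {index}: missing scan start time")
    t = float(t_cv.get("value"))
    if t_cv.get("unitName", "").startswith("minute") or \
            t_cv.get("unitAccession") == "UO:0000031":
        t *= 60.0
    polarity = "negative" if "MS:1000129" in cvs else "positive"
    mz = inten = None
    for bda in el.iter(_q("binaryDataArray")):
        accs = {cv.get("accession") for cv in bda.iter(_q("cvParam"))}
        if "MS:1000514" in accs:
            mz = _decode_binary_array(bda)
        elif "MS:1000515" in accs:
            inten = _decode_binary_array(bda)
    if mz is None or inten is None:
        raise ValueError(f"spectrum index {index}: missing m/z or intensity array")
    return Spectrum(scan_time=t, mz=mz, intensity=inten, polarity=polarity,
                    id=el.get("id", f"scan={index}"))


def read_mzml(source) -> list[Spectrum]:
    """Read an mzML file into a time-sorted list of MS1 spectra.

    Handles plain and indexed mzML, 32/64-bit float arrays, zlib or no
    compression.  Polarity is recorded but never filtered on; MSn scans
    are skipped with a log warning.  A spectrum without a scan start time
    is an error naming the scan index; a truncated file is a parse error.
    """
    spectra: list[Spectrum] = []
    i = 0
    for _, el in etree.iterparse(source, events=("end",), tag=_q("spectrum")):
        sp = _parse_spectrum(el, i)
        if sp is not None:
            spectra.append(sp)
        i += 1
        el.clear(keep_tail=True)
    spectra.sort(key=lambda s: s.scan_time)
    return spectra


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{arr.size}d", *arr)).decode("ascii")


def _cv(parent, accession: str, name: str, value: str = "", **extra) -> None:
    etree.SubElement(
        parent, "cvParam",
        cvRef="MS", accession=accession, name=name, value=value, **extra,
    )


def write_mzml(spectra: list[Spectrum], path) -> None:
    """Write centroid MS1 spectra as mzML 1.1.0 (uncompressed 64-bit floats)."""
    root = etree.Element("mzML", xmlns=_NS, version="1.1.0")
    cv_list = etree.SubElement(root, "cvList", count="2")
    etree.SubElement(
        cv_list, "cv", id="MS", fullName="PSI-MS controlled vocabulary",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    etree.SubElement(
        cv_list, "cv", id="UO", fullName="Unit Ontology",
        URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo",
    )
    fdl = etree.SubElement(root, "fileDescription")
    fc = etree.SubElement(fdl, "fileContent")
    _cv(fc, "MS:1000579", "MS1 spectrum")
    _cv(fc, "MS:1000127", "centroid spectrum")
    sw_list = etree.SubElement(root, "softwareList", count="1")
    etree.SubElement(sw_list, "software", id="probemap", version="0.1.0")
    ic_list = etree.SubElement(root, "instrumentConfigurationList", count="1")
    etree.SubElement(ic_list, "instrumentConfiguration", id="IC1")
    dp_list = etree.SubElement(root, "dataProcessingList", count="1")
    dp = etree.SubElement(dp_list, "dataProcessing", id="DP1")
    pm = etree.SubElement(dp, "processingMethod", order="1", softwareRef="probemap")
    _cv(pm, "MS:1000544", "Conversion to mzML")
    run = etree.SubElement(root, "run", id="run1",
                           defaultInstrumentConfigurationRef="IC1")
    sl = etree.SubElement(run, "spectrumList", count=str(len(spectra)),
                          defaultDataProcessingRef="DP1")
    for i, sp in enumerate(spectra):
        el = etree.SubElement(
            sl, "spectrum", index=str(i),
            id=sp.id or f"scan={i}", defaultArrayLength=str(sp.mz.size),
        )
        _cv(el, "MS:1000579", "MS1 spectrum")
        _cv(el, "MS:1000511", "ms level", "1")
        _cv(el, "MS:1000127", "centroid spectrum")
        if sp.polarity == "negative":
            _cv(el, "MS:1000129", "negative scan")
        else:
            _cv(el, "MS:1000130", "positive scan")
        scan_list = etree.SubElement(el, "scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan = etree.SubElement(scan_list, "scan")
        _cv(scan, "MS:1000016", "scan start time", repr(float(sp.scan_time)),
            unitCvRef="UO", unitAccession="UO:0000010", unitName="second")
        bal = etree.SubElement(el, "binaryDataArrayList", count="2")
        for arr, acc, name in (
            (sp.mz, "MS:1000514", "m/z array"),
            (sp.intensity, "MS:1000515", "intensity array"),
        ):
            payload = _b64(np.asarray(arr, dtype=float))
            bda = etree.SubElement(bal, "binaryDataArray",
                                   encodedLength=str(len(payload)))
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000576", "no compression")
            _cv(bda, acc, name)
            etree.SubElement(bda, "binary").text = payload
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8",
               pretty_print=True)


# ---------------------------------------------------------------------------
# Chronograms

def tic(spectra: list[Spectrum],
        mz_range: tuple[float, float] = DEFAULT_TIC_RANGE) -> Chronogram:
    """Total ion current per spectrum, restricted to an inclusive m/z range."""
    lo, hi = mz_range
    if lo > hi:
        raise ValueError("mz_range must satisfy lo <= hi")
    times = np.array([s.scan_time for s in spectra])
    values = np.empty(len(spectra))
    for i, s in enumerate(spectra):
        a = np.searchsorted(s.mz, lo, side="left")
        b = np.searchsorted(s.mz, hi, side="right")
        values[i] = s.intensity[a:b].sum()
    return Chronogram(times, values, "TIC", (lo, hi))


def xic(spectra: list[Spectrum], center: float, tol: float) -> Chronogram:
    """Extracted ion current: summed intensity with |m/z - center| <= tol."""
    if tol < 0:
        raise ValueError("tol must be >= 0")
    chron = tic(spectra, (center - tol, center + tol))
    return Chronogram(chron.times, chron.values, "XIC",
                      (center - tol, center + tol))


def chronogram_csv(chron: Chronogram, path_or_buf=None) -> str | None:
    """Export as two-column CSV (time_s, value)."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["time_s", "value"])
    for t, v in zip(chron.times, chron.values):
        w.writerow([repr(float(t)), repr(float(v))])
    text = buf.getvalue()
    if path_or_buf is None:
        return text
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)
    return None
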