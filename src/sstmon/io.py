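"""Profile-mode acquisition I/O.

An acquisition is an ordered list of profile spectra (m/z + intensity arrays)
recorded during one QC injection; mzML 1.1 is the single interchange format.
Vendor raw files must be converted upstream. The reader and writer here cover
the subset of mzML needed for full-scan MS1 profile data: 64-bit uncompressed
binary arrays, scan start times, polarity and profile/centroid mode flags.
"""

from __future__ import annotations

import base64
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
from lxml import etree

from .errors import EmptyInputError, FormatError, ModeError

_NS = "http://psi.hupo.org/ms/mzml"

# PSI-MS controlled-vocabulary accessions used by the writer/reader.
_CV_MS_LEVEL = "MS:1000511"
_CV_PROFILE = "MS:1000128"
_CV_CENTROID = "MS:1000127"
_CV_NEGATIVE = "MS:1000129"
_CV_SCAN_START = "MS:1000016"
_CV_F64 = "MS:1000523"
_CV_NO_COMPRESSION = "MS:1000576"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INTENSITY_ARRAY = "MS:1000515"


@dataclass
class ProfileSpectrum:
    """One scan's continuous intensity trace over m/z.

    Parameters
    ----------
    scan_index : int
        0-based ordinal of the scan within the acquisition.
    mz : ndarray
        Strictly increasing m/z values in Thomson.
    intensity : ndarray
        Non-negative detector counts, same length as ``mz``.
    is_profile : bool
        True for profile (continuum) data; False marks centroided scans.
    scan_time : float
        Scan start time in seconds from the beginning of the run.
    """

    scan_index: int
    mz: np.ndarray
    intensity: np.ndarray
    is_profile: bool = True
    scan_time: float = 0.0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz values must be strictly increasing")
        if self.intensity.size and float(self.intensity.min()) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def tic(self) -> float:
        """Total ion current of the scan (sum of all intensities)."""
        return float(self.intensity.sum())


@dataclass
class Acquisition:
    """An ordered collection of profile spectra from one QC injection."""

    spectra: list[ProfileSpectrum]
    run_id: str = "run"
    acquired_at: datetime | None = None
    mz_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for i, s in enumerate(self.spectra):
            if s.scan_index != i:
                raise ValueError("scan_index must be contiguous from 0")
        if self.mz_range is not None:
            lo, hi = self.mz_range
            for s in self.spectra:
                if s.mz.size and (s.mz[0] < lo - 1e-9 or s.mz[-1] > hi + 1e-9):
                    raise ValueError(
                        f"spectrum {s.scan_index} exceeds mz_range ({lo}, {hi})"
                    )

    def __len__(self) -> int:
        return len(self.spectra)

    def __getitem__(self, i: int) -> ProfileSpectrum:
        return self.spectra[i]


def total_ion_chronogram(acq: Acquisition) -> np.ndarray:
    """Per-scan total ion current; the chronogram that locates the QC bolus.

    Returns an array of shape (n_scans, 2) with columns (scan_index, tic).
    """
    if len(acq) == 0:
        raise EmptyInputError("acquisition contains no spectra")
    idx = np.arange(len(acq), dtype=np.float64)
    tic = np.array([s.tic for s in acq.spectra])
    return np.column_stack([idx, tic])


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


def _cv(parent: etree._Element, accession: str, name: str, value: str = "", **extra: str) -> None:
    etree.SubElement(
        parent, "cvParam", cvRef="MS", accession=accession, name=name, value=value, **extra
    )


def write_acquisition(acq: Acquisition, path: str | Path) -> Path:
    """Serialize an acquisition to a standard mzML 1.1 document.

    Profile/centroid mode, negative polarity, scan times and the run's
    ``startTimeStamp`` are preserved; binary arrays are 64-bit, uncompressed.
    """
    path = Path(path)
    root = etree.Element("mzML", nsmap={None: _NS}, version="1.1.0")
    cvl = etree.SubElement(root, "cvList", count="1")
    etree.SubElement(
        cvl, "cv", id="MS", fullName="PSI-MS",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    _cv(fcontent, _CV_PROFILE, "profile spectrum")
    swl = etree.SubElement(root, "softwareList", count="1")
    sw = etree.SubElement(swl, "software", id="sstmon", version="0.1")
    _cv(sw, "MS:1000799", "custom unreleased software tool", "sstmon")
    icl = etree.SubElement(root, "instrumentConfigurationList", count="1")
    ic = etree.SubElement(icl, "instrumentConfiguration", id="IC1")
    _cv(ic, "MS:1000031", "instrument model")
    dpl = etree.SubElement(root, "dataProcessingList", count="1")
    dp = etree.SubElement(dpl, "dataProcessing", id="dp1")
    pm = etree.SubElement(dp, "processingMethod", order="0", softwareRef="sstmon")
    _cv(pm, "MS:1000544", "Conversion to mzML")

    run_attrib = {"id": acq.run_id, "defaultInstrumentConfigurationRef": "IC1"}
    if acq.acquired_at is not None:
        ts = acq.acquired_at
        if ts.tzinfo is None:
            ts = ts.replace(tzinfo=timezone.utc)
        run_attrib["startTimeStamp"] = ts.astimezone(timezone.utc).strftime(
            "%Y-%m-%dT%H:%M:%SZ"
        )
    run = etree.SubElement(root, "run", **run_attrib)
    slist = etree.SubElement(
        run, "spectrumList", count=str(len(acq)), defaultDataProcessingRef="dp1"
    )
    for s in acq.spectra:
        sp = etree.SubElement(
            slist, "spectrum",
            index=str(s.scan_index),
            id=f"scan={s.scan_index + 1}",
            defaultArrayLength=str(s.mz.size),
        )
        _cv(sp, _CV_MS_LEVEL, "ms level", "1")
        if s.is_profile:
            _cv(sp, _CV_PROFILE, "profile spectrum")
        else:
            _cv(sp, _CV_CENTROID, "centroid spectrum")
        _cv(sp, _CV_NEGATIVE, "negative scan")
        scl = etree.SubElement(sp, "scanList", count="1")
        _cv(scl, "MS:1000795", "no combination")
        scan = etree.SubElement(scl, "scan")
        _cv(
            scan, _CV_SCAN_START, "scan start time", repr(float(s.scan_time)),
            unitCvRef="UO", unitAccession="UO:0000010", unitName="second",
        )
        bdal = etree.SubElement(sp, "binaryDataArrayList", count="2")
        for accession, name, unit, arr in (
            (_CV_MZ_ARRAY, "m/z array", ("MS:1000040", "m/z"), s.mz),
            (_CV_INTENSITY_ARRAY, "intensity array",
             ("MS:1000131", "number of detector counts"), s.intensity),
        ):
            payload = _b64(arr)
            bda = etree.SubElement(bdal, "binaryDataArray", encodedLength=str(len(payload)))
            _cv(bda, _CV_F64, "64-bit float")
            _cv(bda, _CV_NO_COMPRESSION, "no compression")
            _cv(bda, accession, name, unitCvRef="MS",
                unitAccession=unit[0], unitName=unit[1])
            etree.SubElement(bda, "binary").text = payload
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=False)
    return path


def _decode_binary_array(bda: etree._Element) -> tuple[str | None, np.ndarray]:
    kind = None
    compressed = False
    for cv in bda.iter(f"{{{_NS}}}cvParam"):
        acc = cv.get("accession")
        if acc == _CV_MZ_ARRAY:
            kind = "mz"
        elif acc == _CV_INTENSITY_ARRAY:
            kind = "intensity"
        elif acc == "MS:1000574":  # zlib compression
            compressed = True
    binary = bda.find(f"{{{_NS}}}binary")
    raw = base64.b64decode(binary.text or "")
    if compressed:
        import zlib

        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype="<f8").copy()


def read_acquisition(path: str | Path, require_profile: bool = True) -> Acquisition:
    """Read an mzML document into an :class:`Acquisition`.

    Spectra are ordered by document order (which the writer keeps equal to
    scan-time order). With ``require_profile`` any centroided spectrum raises
    :class:`~sstmon.errors.ModeError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"not a well-formed mzML document: {exc}") from exc
    root = tree.getroot()
    if etree.QName(root).localname != "mzML":
        raise FormatError(f"root element is {root.tag!r}, expected mzML")

    run = root.find(f"{{{_NS}}}run")
    if run is None:
        raise FormatError("mzML document has no <run> element")
    acquired_at = None
    stamp = run.get("startTimeStamp")
    if stamp:
        acquired_at = datetime.fromisoformat(stamp.replace("Z", "+00:00"))

    spectra: list[ProfileSpectrum] = []
    lo, hi = np.inf, -np.inf
    for i, sp in enumerate(run.iter(f"{{{_NS}}}spectrum")):
        is_profile = None
        scan_time = 0.0
        for cv in sp.iter(f"{{{_NS}}}cvParam"):
            acc = cv.get("accession")
            if acc == _CV_PROFILE:
                is_profile = True
            elif acc == _CV_CENTROID:
                is_profile = False
            elif acc == _CV_SCAN_START:
                t = float(cv.get("value"))
                unit = cv.get("unitName", "second")
                scan_time = t * 60.0 if unit == "minute" else t
        if is_profile is None:
            is_profile = True
        if require_profile and not is_profile:
            raise ModeError(
                f"spectrum {i} is centroided but profile data is required"
            )
        mz = inten = None
        for bda in sp.iter(f"{{{_NS}}}binaryDataArray"):
            kind, arr = _decode_binary_array(bda)
            if kind == "mz":
                mz = arr
            elif kind == "intensity":
                inten = arr
        if mz is None or inten is None:
            raise FormatError(f"spectrum {i} lacks m/z or intensity array")
        if mz.size:
            lo, hi = min(lo, float(mz[0])), max(hi, float(mz[-1]))
        spectra.append(
            ProfileSpectrum(
                scan_index=i, mz=mz, intensity=inten,
                is_profile=is_profile, scan_time=scan_time,
            )
        )
    mz_range = (lo, hi) if spectra and np.isfinite(lo) else None
    return Acquisition(
        spectra=spectra, run_id=run.get("id", path.stem),
        acquired_at=acquired_at, mz_range=mz_range,
    )
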