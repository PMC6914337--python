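"""Readers and writers for the pipeline's file formats.

* MS1 spectra: mzML (read and write). The reader handles centroided
  MS-level-1 spectra with 32/64-bit float arrays, zlib-compressed or
  uncompressed; retention times are normalized to seconds regardless of the
  source unit. The writer emits uncompressed 64-bit arrays and is the
  counterpart used by the synthetic-run generator.
* Peptide-spectrum matches: a documented tab-separated dialect
  (``PSM_COLUMNS``) standing in for search-engine output.
* Protein database: FASTA (via pyteomics).
* Pipeline outputs: protein- and peptide-level TSV tables with fixed,
  documented columns and deterministic row order.

Parsers reject rather than silently skip: every dropped row or scan is
either an error or a logged reason.
"""
from __future__ import annotations

import base64
import logging
import os
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pyteomics import fasta as _fasta

from .errors import FormatError, ValidationError

logger = logging.getLogger("silamq.spectra_io")

__all__ = [
    "Scan",
    "ScanSeries",
    "PSMRecord",
    "PSM_COLUMNS",
    "read_ms1",
    "write_ms1",
    "read_psm_table",
    "write_psm_table",
    "read_fasta",
    "write_fasta",
    "write_protein_table",
    "write_peptide_table",
    "PROTEIN_TABLE_COLUMNS",
    "PEPTIDE_TABLE_COLUMNS",
]


# ---------------------------------------------------------------------------
# MS1 scans
# ---------------------------------------------------------------------------

@dataclass
class Scan:
    """One centroided MS1 scan."""

    rt: float                 # retention time, seconds
    mz: np.ndarray            # centroid m/z values, ascending
    intensity: np.ndarray     # same length as mz
    native_id: str = ""       # scan id preserved verbatim from the source

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValidationError("m/z and intensity arrays differ in length")
        if self.mz.size > 1 and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]


@dataclass
class ScanSeries:
    """Retention-time-ordered MS1 scans of one LC-MS run."""

    scans: List[Scan]
    ms_level: int = 1

    def __post_init__(self):
        if any(
            self.scans[i].rt > self.scans[i + 1].rt
            for i in range(len(self.scans) - 1)
        ):
            self.scans = sorted(self.scans, key=lambda s: s.rt)

    def __len__(self) -> int:
        return len(self.scans)

    def __iter__(self):
        return iter(self.scans)

    @property
    def rts(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans])


_NS = "{http://psi.hupo.org/ms/mzml}"

# controlled-vocabulary accessions the reader understands
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NO_COMPRESSION = "MS:1000576"


def _cv_params(elem) -> Dict[str, ET.Element]:
    return {
        cv.get("accession"): cv
        for cv in elem.findall(f"{_NS}cvParam") + elem.findall("cvParam")
    }


def _decode_binary_array(bda) -> Tuple[Optional[str], np.ndarray]:
    cvs = _cv_params(bda)
    kind = None
    if _ACC_MZ_ARRAY in cvs:
        kind = "mz"
    elif _ACC_INTENSITY_ARRAY in cvs:
        kind = "intensity"
    dtype = "<f4" if _ACC_F32 in cvs else "<f8"
    binary = bda.find(f"{_NS}binary")
    if binary is None:
        binary = bda.find("binary")
    raw = base64.b64decode(binary.text or "")
    if _ACC_ZLIB in cvs:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_ms1(path: str) -> ScanSeries:
    """Read the MS1 scans of an mzML file, in retention-time order.

    Only MS-level-1 spectra are returned; centroid peak lists pass through
    unchanged. Retention times are converted to seconds (mzML may store
    minutes).

    Raises
    ------
    FileNotFoundError
        Missing file.
    FormatError
        Malformed XML, or an mzML with no MS1 scans.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise FormatError(f"malformed mzML ({path}): {exc}") from exc
    root = tree.getroot()
    scans: List[Scan] = []
    n_dropped = 0
    for spectrum in root.iter(f"{_NS}spectrum"):
        cvs = _cv_params(spectrum)
        level = cvs.get(_ACC_MS_LEVEL)
        if level is None or level.get("value") != "1":
            n_dropped += 1
            continue
        rt = 0.0
        for scan_el in spectrum.iter(f"{_NS}scan"):
            scan_cvs = _cv_params(scan_el)
            start = scan_cvs.get(_ACC_SCAN_START)
            if start is not None:
                rt = float(start.get("value"))
                unit = (start.get("unitName") or "").lower()
                if unit.startswith("min"):
                    rt *= 60.0
            break
        mz = intensity = None
        for bda in spectrum.iter(f"{_NS}binaryDataArray"):
            kind, arr = _decode_binary_array(bda)
            if kind == "mz":
                mz = arr
            elif kind == "intensity":
                intensity = arr
        if mz is None or intensity is None:
            raise FormatError(
                f"spectrum {spectrum.get('id')!r} lacks m/z or intensity array"
            )
        scans.append(Scan(rt=rt, mz=mz, intensity=intensity,
                          native_id=spectrum.get("id", "")))
    if not scans:
        raise FormatError(f"no MS1 scans in {path}")
    if n_dropped:
        logger.debug("read_ms1(%s): skipped %d non-MS1 spectra", path, n_dropped)
    return ScanSeries(scans=scans)


_SPECTRUM_TEMPLATE = """\
    <spectrum index="{index}" id="{native_id}" defaultArrayLength="{n}">
     <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
     <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
     <scanList count="1">
      <scan>
       <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt!r}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
      </scan>
     </scanList>
     <binaryDataArrayList count="2">
      <binaryDataArray encodedLength="{mz_len}">
       <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
       <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
       <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
       <binary>{mz_b64}</binary>
      </binaryDataArray>
      <binaryDataArray encodedLength="{int_len}">
       <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
       <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
       <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
       <binary>{int_b64}</binary>
      </binaryDataArray>
     </binaryDataArrayList>
    </spectrum>
"""

_MZML_HEADER = """\
<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
 <cvList count="2">
  <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  <cv id="UO" fullName="Unit Ontology" URI="http://ontologies.berkeleybop.org/uo.obo"/>
 </cvList>
 <run id="{run_id}">
  <spectrumList count="{count}">
"""

_MZML_FOOTER = """\
  </spectrumList>
 </run>
</mzML>
"""


def write_ms1(series: ScanSeries, path: str, run_id: str = "run") -> None:
    """Write MS1 scans as mzML (uncompressed 64-bit arrays).

    Output is a pure function of the scan contents, so identical input
    produces byte-identical files.
    """
    parts = [_MZML_HEADER.format(run_id=run_id, count=len(series.scans))]
    for i, scan in enumerate(series.scans):
        mz_b64 = base64.b64encode(
            np.asarray(scan.mz, dtype="<f8").tobytes()).decode()
        int_b64 = base64.b64encode(
            np.asarray(scan.intensity, dtype="<f8").tobytes()).decode()
        parts.append(_SPECTRUM_TEMPLATE.format(
            index=i,
            native_id=scan.native_id or f"scan={i + 1}",
            n=scan.mz.size,
            rt=float(scan.rt),
            mz_len=len(mz_b64), mz_b64=mz_b64,
            int_len=len(int_b64), int_b64=int_b64,
        ))
    parts.append(_MZML_FOOTER)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("".join(parts))


# ---------------------------------------------------------------------------
# PSM table
# ---------------------------------------------------------------------------

#: Column order of the package's PSM TSV dialect. ``proteins`` is
#: semicolon-separated; ``prev_aa``/``next_aa`` use ``-`` for a protein
#: terminus; ``channel`` is LIGHT/HEAVY/UNKNOWN; ``decoy`` is 0/1;
#: ``precursor_mz`` may be empty for pre-labeled inputs.
PSM_COLUMNS = [
    "scan", "sequence", "prev_aa", "next_aa", "charge", "rt_sec",
    "proteins", "precursor_mz", "score", "decoy", "channel",
]

DEFAULT_CHARGE_RANGE = (2, 6)


@dataclass
class PSMRecord:
    """One peptide-spectrum match from the identification step."""

    scan_id: str
    sequence: str
    prev_aa: str
    next_aa: str
    charge: int
    rt: float                       # seconds
    proteins: Tuple[str, ...]
    precursor_mz: Optional[float] = None
    score: float = 0.0
    decoy: bool = False
    channel: str = "UNKNOWN"        # LIGHT / HEAVY / UNKNOWN
    charge_in_range: bool = True
    ppm_error: Optional[float] = None

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValidationError("PSM with empty peptide sequence")


def read_psm_table(
    path: str,
    charge_range: Tuple[int, int] = DEFAULT_CHARGE_RANGE,
) -> List[PSMRecord]:
    """Parse the PSM TSV dialect.

    Charges outside ``charge_range`` are parsed but flagged
    (``charge_in_range=False``); they are removed later by the
    identification filters, not at parse time. A missing required column or
    an unparseable field is an error naming the column / 1-based data row.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse PSM table {path}: {exc}") from exc
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"PSM table {path} missing column(s): {', '.join(missing)}")
    lo, hi = charge_range
    records: List[PSMRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            charge = int(row.charge)
            rec = PSMRecord(
                scan_id=str(row.scan),
                sequence=row.sequence,
                prev_aa=row.prev_aa or "-",
                next_aa=row.next_aa or "-",
                charge=charge,
                rt=float(row.rt_sec),
                proteins=tuple(p for p in row.proteins.split(";") if p),
                precursor_mz=float(row.precursor_mz) if row.precursor_mz else None,
                score=float(row.score) if row.score else 0.0,
                decoy=str(row.decoy) in ("1", "True", "true"),
                channel=row.channel or "UNKNOWN",
                charge_in_range=lo <= charge <= hi,
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"PSM table {path}, data row {row_no}: {exc}") from exc
        if not rec.charge_in_range:
            logger.debug("PSM row %d: charge %d outside [%d, %d], flagged",
                         row_no, rec.charge, lo, hi)
        records.append(rec)
    return records


def write_psm_table(records: Sequence[PSMRecord], path: str) -> None:
    """Write PSMs in the package TSV dialect (columns ``PSM_COLUMNS``)."""
    rows = []
    for r in records:
        rows.append({
            "scan": r.scan_id,
            "sequence": r.sequence,
            "prev_aa": r.prev_aa,
            "next_aa": r.next_aa,
            "charge": r.charge,
            "rt_sec": repr(float(r.rt)),
            "proteins": ";".join(r.proteins),
            "precursor_mz": "" if r.precursor_mz is None else repr(float(r.precursor_mz)),
            "score": repr(float(r.score)),
            "decoy": int(r.decoy),
            "channel": r.channel,
        })
    df = pd.DataFrame(rows, columns=PSM_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> List[Tuple[str, str]]:
    """Read a protein FASTA as (accession, sequence) pairs.

    The accession is the first whitespace-delimited token of the header.
    Sequences are upper-cased and ``*`` stop characters stripped. Duplicate
    accessions are an error (the message lists them).
    """
    records: List[Tuple[str, str]] = []
    seen: Dict[str, int] = {}
    with open(path) as fh:
        for header, seq in _fasta.read(fh):
            acc = header.split()[0]
            seen[acc] = seen.get(acc, 0) + 1
            records.append((acc, seq.upper().replace("*", "")))
    dupes = sorted(acc for acc, n in seen.items() if n > 1)
    if dupes:
        raise ValidationError(f"duplicate FASTA accession(s): {', '.join(dupes)}")
    return records


def write_fasta(records: Iterable[Tuple[str, str]], path: str) -> None:
    """Write (accession, sequence) pairs as FASTA."""
    with open(path, "w", newline="\n") as fh:
        _fasta.write(((acc, seq) for acc, seq in records), fh)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

PROTEIN_TABLE_COLUMNS = [
    "accession", "tissue", "turnover_class", "ratio_14N_15N", "capped",
    "cap_lo", "cap_hi", "n_peptides_used", "n_peptides_removed",
    "n_peptides_total", "spectral_count_light", "spectral_count_heavy",
]

PEPTIDE_TABLE_COLUMNS = [
    "sequence", "charge", "proteins", "ratio_14N_15N", "correlation",
    "n_points", "light_present", "heavy_present", "light_area", "heavy_area",
    "status",
]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(int(value))
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_protein_table(records: Sequence, path: str) -> None:
    """Write protein turnover records as TSV, sorted by accession.

    Row order and float formatting are deterministic: the same records
    always produce byte-identical files.
    """
    rows = []
    for r in sorted(records, key=lambda r: (r.tissue, r.accession)):
        rows.append({
            "accession": r.accession,
            "tissue": r.tissue,
            "turnover_class": r.turnover_class,
            "ratio_14N_15N": _fmt(r.ratio),
            "capped": int(r.capped),
            "cap_lo": _fmt(r.cap_lo),
            "cap_hi": _fmt(r.cap_hi),
            "n_peptides_used": r.n_peptides_used,
            "n_peptides_removed": r.n_peptides_removed,
            "n_peptides_total": r.n_peptides_total,
            "spectral_count_light": r.spectral_count_light,
            "spectral_count_heavy": r.spectral_count_heavy,
        })
    df = pd.DataFrame(rows, columns=PROTEIN_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_peptide_table(records: Sequence, path: str) -> None:
    """Write per-peptide ratio records as TSV (deterministic order)."""
    rows = []
    key = lambda r: (r.sequence, r.charge)
    for r in sorted(records, key=key):
        rows.append({
            "sequence": r.sequence,
            "charge": r.charge,
            "proteins": ";".join(r.proteins),
            "ratio_14N_15N": _fmt(r.ratio),
            "correlation": _fmt(r.correlation),
            "n_points": r.n_points,
            "light_present": int(r.light_present),
            "heavy_present": int(r.heavy_present),
            "light_area": _fmt(r.light_area),
            "heavy_area": _fmt(r.heavy_area),
            "status": r.status,
        })
    df = pd.DataFrame(rows, columns=PEPTIDE_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
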