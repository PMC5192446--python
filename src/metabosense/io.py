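"""Reading and writing centroid runs.

Two on-disk forms are supported:

* ``run-csv`` — one UTF-8 CSV per run with header ``rt_min,mz,intensity`` and
  one row per centroid ion.  A scan that contains no ions is kept on the grid
  by a single row with empty ``mz``/``intensity`` fields, so a round trip
  preserves the scan axis exactly.
* ``mzML`` — MS-level-1 centroid spectra.  Both directions are handled by a
  small self-contained serializer/parser (controlled-vocabulary accessions for
  array type, compression, unit and scan time; 32/64-bit float and zlib
  payloads on read; 64-bit uncompressed on write).

A cohort is tied together by a manifest CSV with columns
``sample_id,group,path``.
"""

from __future__ import annotations

import base64
import csv
import os
import struct
from pathlib import Path
from typing import Iterable
from xml.sax.saxutils import escape

import numpy as np

from .synthetic import CentroidRun, Scan


class RunParseError(ValueError):
    """Malformed run file; carries the offending scan index where known."""


# ---------------------------------------------------------------- run-csv --

def write_run_csv(run: CentroidRun, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["rt_min", "mz", "intensity"])
        for scan in run.scans:
            if len(scan.mz) == 0:
                w.writerow([repr(scan.rt), "", ""])
            else:
                for m, i in zip(scan.mz, scan.intensity):
                    w.writerow([repr(scan.rt), repr(float(m)), repr(float(i))])


def read_run_csv(path, sample_id: str | None = None, group: str = "?") -> CentroidRun:
    scans: list[Scan] = []
    cur_rt = None
    cur_mz: list[float] = []
    cur_int: list[float] = []

    def flush():
        if cur_rt is not None:
            scans.append(Scan(rt=cur_rt, mz=np.array(cur_mz), intensity=np.array(cur_int)))

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != ["rt_min", "mz", "intensity"]:
            raise RunParseError(f"{path}: expected header rt_min,mz,intensity")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                rt = float(row[0])
            except ValueError as exc:
                raise RunParseError(f"{path}:{lineno}: bad rt field {row[0]!r}") from exc
            if rt != cur_rt:
                flush()
                cur_rt, cur_mz, cur_int = rt, [], []
            if len(row) >= 3 and row[1] != "":
                cur_mz.append(float(row[1]))
                cur_int.append(float(row[2]))
    flush()
    name = sample_id if sample_id is not None else Path(path).stem
    try:
        return CentroidRun(sample_id=name, group=group, scans=scans)
    except ValueError as exc:
        raise RunParseError(str(exc)) from exc


# ------------------------------------------------------------------- mzML --

def _b64(values: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{len(values)}d", *map(float, values))).decode()


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="metabosense" version="0.1.0">
      <cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="metabosense"/>
    </software>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1">
      <cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/>
    </instrumentConfiguration>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="metabosense">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
"""


def write_run_mzml(run: CentroidRun, path) -> None:
    """Write one run as an MS1 centroid mzML file."""
    parts = [_MZML_HEADER]
    parts.append(f'  <run id="{escape(run.sample_id)}" defaultInstrumentConfigurationRef="IC1">\n')
    parts.append(f'    <spectrumList count="{len(run.scans)}" defaultDataProcessingRef="DP1">\n')
    for i, scan in enumerate(run.scans):
        mz64, int64 = _b64(scan.mz), _b64(scan.intensity)
        parts.append(
            f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(scan.mz)}">\n'
            '        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>\n'
            '        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>\n'
            '        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
            '        <scanList count="1">\n'
            '          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>\n'
            '          <scan>\n'
            f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{scan.rt!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>\n'
            '          </scan>\n'
            '        </scanList>\n'
            '        <binaryDataArrayList count="2">\n'
            f'          <binaryDataArray encodedLength="{len(mz64)}">\n'
            '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
            '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
            '            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
            f'            <binary>{mz64}</binary>\n'
            '          </binaryDataArray>\n'
            f'          <binaryDataArray encodedLength="{len(int64)}">\n'
            '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
            '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
            '            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>\n'
            f'            <binary>{int64}</binary>\n'
            '          </binaryDataArray>\n'
            '        </binaryDataArrayList>\n'
            '      </spectrum>\n')
    parts.append('    </spectrumList>\n  </run>\n</mzML>\n')
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("".join(parts))


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind, values)."""
    import zlib

    dtype = "<d"
    compressed = False
    kind = None
    text = ""
    for el in bda.iter():
        t = _local(el.tag)
        if t == "cvParam":
            acc = el.get("accession", "")
            if acc == "MS:1000521":
                dtype = "<f"
            elif acc == "MS:1000523":
                dtype = "<d"
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif t == "binary":
            text = el.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_run_mzml(path, sample_id: str | None = None, group: str = "?") -> CentroidRun:
    """Read MS1 centroid spectra from an mzML file."""
    import xml.etree.ElementTree as ET

    scans: list[Scan] = []
    for idx, (_event, elem) in enumerate(_iter_spectra(path, ET)):
        ms_level = 1
        rt = None
        rt_unit = "minute"
        arrays: dict[str, np.ndarray] = {}
        for el in elem.iter():
            t = _local(el.tag)
            if t == "cvParam":
                acc = el.get("accession", "")
                if acc == "MS:1000511":
                    ms_level = int(el.get("value", "1"))
                elif acc == "MS:1000016":
                    rt = float(el.get("value"))
                    rt_unit = el.get("unitName", "minute")
            elif t == "binaryDataArray":
                kind, vals = _decode_binary_array(el)
                if kind:
                    arrays[kind] = vals
        if ms_level != 1:
            elem.clear()
            continue
        if rt is None or "mz" not in arrays or "intensity" not in arrays:
            raise RunParseError(f"{path}: scan {idx}: missing scan time or data arrays")
        if rt_unit.startswith("second"):
            rt /= 60.0
        scans.append(Scan(rt=rt, mz=arrays["mz"], intensity=arrays["intensity"]))
        elem.clear()
    for idx in range(1, len(scans)):
        if scans[idx].rt <= scans[idx - 1].rt:
            raise RunParseError(f"{path}: scan {idx}: retention time not increasing")
    name = sample_id if sample_id is not None else Path(path).stem
    return CentroidRun(sample_id=name, group=group, scans=scans)


def _iter_spectra(path, ET):
    for event, elem in ET.iterparse(str(path), events=("end",)):
        if _local(elem.tag) == "spectrum":
            yield event, elem


# --------------------------------------------------------------- manifest --

def write_runs(runs: Iterable[CentroidRun], directory, fmt: str = "run-csv") -> Path:
    """Write a cohort plus manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt not in ("run-csv", "mzML"):
        raise ValueError(f"unknown format {fmt!r}; use 'run-csv' or 'mzML'")
    ext = "csv" if fmt == "run-csv" else "mzML"
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "group", "path"])
        for run in runs:
            fname = f"{run.sample_id}.{ext}"
            if fmt == "run-csv":
                write_run_csv(run, directory / fname)
            else:
                write_run_mzml(run, directory / fname)
            w.writerow([run.sample_id, run.group, fname])
    return manifest


def read_runs(manifest_path) -> list[CentroidRun]:
    """Read a cohort back from its manifest; format inferred per file."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    runs = []
    with open(manifest_path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            path = base / row["path"]
            if path.suffix.lower() == ".mzml":
                run = read_run_mzml(path, sample_id=row["sample_id"], group=row["group"])
            else:
                run = read_run_csv(path, sample_id=row["sample_id"], group=row["group"])
            runs.append(run)
    return runs
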