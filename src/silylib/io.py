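"""Readers and writers for the three spectral-library dialects.

Three text dialects are supported and interconverted:

* **MSP** — NIST convention: ``Name:``/``InChIKey:``/``Formula:``/``MW:``/
  ``ExactMass:``/``CAS#:``/``NIST#:``/``ID#:``/``Num Peaks:`` header lines
  followed by one ``mz intensity`` pair per line, records separated by a
  blank line.  Key synonyms produced by LIB2NIST and vendor exports
  (``CASNO:``, ``MW=`` …) are accepted on read; canonical keys are written.
* **MGF** — Mascot generic format restricted to the library dialect:
  ``BEGIN IONS`` / ``MASS=`` / ``CHARGE=1+`` / ``TITLE= InChIKey: <key>
  Name: <name>`` / blank / peak lines / blank / ``END IONS``.  The reader is
  whitespace-tolerant and accepts the standard ``PEPMASS=`` as an alias of
  ``MASS=``.
* **TXT** — the instrument-export dialect: a small ``Key: value`` header
  (Name/InChIKey/Formula/MW/ExactMass/CAS#) and whitespace-delimited
  two-column m/z–abundance pairs, records separated by blank lines.

Writers are deterministic (identical input gives byte-identical output, one
newline convention), numbers are serialized with the shortest decimal
representation that round-trips, and readers accept UTF-8 with a Latin-1
fallback because compound names carry Greek letters and primes.
"""
from __future__ import annotations

import io as _stdio
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, TextIO, Union

from .core import Peak, Spectrum

__all__ = [
    "LibraryFile",
    "FormatError",
    "ConversionSummary",
    "FORMATS",
    "read_msp",
    "write_msp",
    "read_txt",
    "write_txt",
    "read_mgf",
    "write_mgf",
    "read_library",
    "write_library",
    "convert",
]

FORMATS = ("MSP", "MGF", "TXT")


class FormatError(ValueError):
    """Malformed library file; carries file/line context."""

    def __init__(self, message: str, line: Optional[int] = None,
                 record: Optional[str] = None, source: Optional[str] = None):
        ctx = []
        if source:
            ctx.append(str(source))
        if line is not None:
            ctx.append(f"line {line}")
        if record:
            ctx.append(f"record {record!r}")
        prefix = " (".join([", ".join(ctx)]) if ctx else ""
        super().__init__(f"{', '.join(ctx)}: {message}" if ctx else message)
        self.line = line
        self.record = record
        self.source = source


@dataclass
class LibraryFile:
    """An ordered collection of spectra read from / destined for one file."""

    format: str
    records: list[Spectrum] = field(default_factory=list)
    source_path: str = ""
    issues: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.format not in FORMATS:
            raise ValueError(f"unknown library format: {self.format!r}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ConversionSummary:
    records_read: int
    records_written: int
    input_format: str
    output_format: str


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def _open_read(source: Union[str, Path, TextIO]) -> tuple[TextIO, str, bool]:
    if hasattr(source, "read"):
        return source, getattr(source, "name", "<stream>"), False
    path = Path(source)
    data = path.read_bytes()
    try:
        text = data.decode("utf-8")
    except UnicodeDecodeError:
        text = data.decode("latin-1")
    return _stdio.StringIO(text), str(path), True


def _open_write(dest: Union[str, Path, TextIO]):
    if hasattr(dest, "write"):
        return dest, False
    return open(dest, "w", encoding="utf-8", newline="\n"), True


def format_number(x: float) -> str:
    """Shortest decimal representation that round-trips; integers bare."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


_PEAK_SPLIT = re.compile(r"[\s;]+")


def _parse_peak_line(line: str, lineno: int, source: str) -> list[Peak]:
    fields = [f for f in _PEAK_SPLIT.split(line.strip()) if f]
    if len(fields) % 2 != 0:
        raise FormatError(f"peak line has odd field count: {line.strip()!r}",
                          line=lineno, source=source)
    peaks = []
    for i in range(0, len(fields), 2):
        try:
            mz = float(fields[i])
            inten = float(fields[i + 1])
        except ValueError:
            raise FormatError(f"non-numeric peak value in {line.strip()!r}",
                              line=lineno, source=source) from None
        peaks.append(Peak(mz, inten))
    return peaks


def _opt_int(s: str) -> Optional[int]:
    try:
        return int(s)
    except ValueError:
        return None


def _opt_float(s: str) -> Optional[float]:
    try:
        return float(s)
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# MSP
# ---------------------------------------------------------------------------

_MSP_KEYS = {
    "name": "name",
    "inchikey": "inchikey",
    "cas#": "cas",
    "casno": "cas",
    "cas": "cas",
    "formula": "formula",
    "mw": "mw",
    "exactmass": "exact_mass",
    "exact mass": "exact_mass",
    "nist#": "nist_number",
    "id#": "id_number",
    "acquisitionuppermz": "acquisition_upper_mz",
    "acquisition upper mz": "acquisition_upper_mz",
}

_HEADER_LINE = re.compile(r"^([A-Za-z#][A-Za-z0-9# ]*?)\s*[:=]\s*(.*)$")


def _finish_msp_record(fields: dict, peaks: list[Peak], declared: Optional[int],
                       lineno: int, source: str) -> Spectrum:
    name = fields.get("name", "")
    if declared is not None and declared != len(peaks):
        raise FormatError(
            f"Num Peaks declares {declared} but {len(peaks)} peak pairs listed",
            line=lineno, record=name or "<unnamed>", source=source)
    return Spectrum(
        peaks=tuple(peaks),
        name=name,
        inchikey=fields.get("inchikey"),
        cas=fields.get("cas"),
        formula=fields.get("formula"),
        mw=_opt_float(fields["mw"]) if "mw" in fields else None,
        exact_mass=_opt_float(fields["exact_mass"]) if "exact_mass" in fields else None,
        nist_number=_opt_int(fields["nist_number"]) if "nist_number" in fields else None,
        id_number=_opt_int(fields["id_number"]) if "id_number" in fields else None,
        acquisition_upper_mz=(_opt_float(fields["acquisition_upper_mz"])
                              if "acquisition_upper_mz" in fields else None),
    )


def read_msp(source: Union[str, Path, TextIO], strict: bool = True) -> LibraryFile:
    """Parse a NIST-convention MSP stream into a :class:`LibraryFile`.

    In strict mode any malformed record aborts with :class:`FormatError`;
    otherwise the record is skipped and reported in ``LibraryFile.issues``.
    """
    stream, source_name, close = _open_read(source)
    lib = LibraryFile(format="MSP", source_path=source_name)
    fields: dict = {}
    peaks: list[Peak] = []
    declared: Optional[int] = None
    in_record = False
    record_broken = False

    def finish(lineno: int) -> None:
        nonlocal fields, peaks, declared, in_record, record_broken
        if in_record and not record_broken:
            try:
                lib.records.append(_finish_msp_record(fields, peaks, declared,
                                                      lineno, source_name))
            except FormatError as exc:
                if strict:
                    raise
                lib.issues.append(str(exc))
        fields, peaks, declared, in_record, record_broken = {}, [], None, False, False

    try:
        lineno = 0
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                finish(lineno)
                continue
            m = _HEADER_LINE.match(line)
            if m and not line[0].isdigit() and not line.lstrip().startswith(("-", "+", ".")):
                key = m.group(1).strip().lower()
                if key == "num peaks":
                    declared = _opt_int(m.group(2).strip())
                    in_record = True
                    continue
                mapped = _MSP_KEYS.get(key)
                if mapped:
                    fields[mapped] = m.group(2).strip()
                in_record = True  # unknown keys tolerated and dropped
                continue
            # peak line
            in_record = True
            try:
                peaks.extend(_parse_peak_line(line, lineno, source_name))
            except FormatError as exc:
                if strict:
                    raise
                lib.issues.append(str(exc))
                record_broken = True
        finish(lineno + 1)
    finally:
        if close:
            stream.close()
    return lib


def write_msp(library: LibraryFile, dest: Union[str, Path, TextIO]) -> None:
    """Emit NIST-convention MSP, blank-line separated, one peak pair per line."""
    stream, close = _open_write(dest)
    try:
        for i, s in enumerate(library.records):
            if not s.name:
                raise FormatError("MSP requires a Name for every record",
                                  record=f"#{i}")
            stream.write(f"Name: {s.name}\n")
            if s.inchikey is not None:
                stream.write(f"InChIKey: {s.inchikey}\n")
            if s.cas is not None:
                stream.write(f"CAS#: {s.cas}\n")
            if s.formula is not None:
                stream.write(f"Formula: {s.formula}\n")
            if s.mw is not None:
                stream.write(f"MW: {format_number(s.mw)}\n")
            if s.exact_mass is not None:
                stream.write(f"ExactMass: {format_number(s.exact_mass)}\n")
            if s.nist_number is not None:
                stream.write(f"NIST#: {s.nist_number}\n")
            if s.id_number is not None:
                stream.write(f"ID#: {s.id_number}\n")
            if s.acquisition_upper_mz is not None:
                stream.write(f"AcquisitionUpperMz: {format_number(s.acquisition_upper_mz)}\n")
            stream.write(f"Num Peaks: {s.num_peaks}\n")
            for p in s.peaks:
                stream.write(f"{format_number(p.mz)} {format_number(p.intensity)}\n")
            if i != len(library.records) - 1:
                stream.write("\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# TXT (two-column instrument export)
# ---------------------------------------------------------------------------

_TXT_KEYS = {
    "name": "name",
    "inchikey": "inchikey",
    "formula": "formula",
    "mf": "formula",
    "mw": "mw",
    "exactmass": "exact_mass",
    "cas#": "cas",
    "cas": "cas",
}


def read_txt(source: Union[str, Path, TextIO], strict: bool = True) -> LibraryFile:
    """Parse the two-column peak-list dialect (header lines then m/z pairs)."""
    stream, source_name, close = _open_read(source)
    lib = LibraryFile(format="TXT", source_path=source_name)
    fields: dict = {}
    peaks: list[Peak] = []
    in_record = False

    def finish() -> None:
        nonlocal fields, peaks, in_record
        if in_record:
            lib.records.append(Spectrum(
                peaks=tuple(peaks),
                name=fields.get("name", ""),
                inchikey=fields.get("inchikey"),
                cas=fields.get("cas"),
                formula=fields.get("formula"),
                mw=_opt_float(fields["mw"]) if "mw" in fields else None,
                exact_mass=_opt_float(fields["exact_mass"]) if "exact_mass" in fields else None,
            ))
        fields, peaks, in_record = {}, [], False

    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                finish()
                continue
            m = _HEADER_LINE.match(line)
            if m and not line[0].isdigit() and not line.lstrip().startswith(("-", "+", ".")):
                key = m.group(1).strip().lower()
                mapped = _TXT_KEYS.get(key)
                if mapped:
                    fields[mapped] = m.group(2).strip()
                in_record = True
                continue
            in_record = True
            try:
                peaks.extend(_parse_peak_line(line, lineno, source_name))
            except FormatError as exc:
                if strict:
                    raise
                lib.issues.append(str(exc))
        finish()
    finally:
        if close:
            stream.close()
    return lib


def write_txt(library: LibraryFile, dest: Union[str, Path, TextIO]) -> None:
    stream, close = _open_write(dest)
    try:
        for i, s in enumerate(library.records):
            stream.write(f"Name: {s.name}\n")
            if s.inchikey is not None:
                stream.write(f"InChIKey: {s.inchikey}\n")
            if s.formula is not None:
                stream.write(f"Formula: {s.formula}\n")
            if s.mw is not None:
                stream.write(f"MW: {format_number(s.mw)}\n")
            if s.exact_mass is not None:
                stream.write(f"ExactMass: {format_number(s.exact_mass)}\n")
            if s.cas is not None:
                stream.write(f"CAS#: {s.cas}\n")
            for p in s.peaks:
                stream.write(f"{format_number(p.mz)} {format_number(p.intensity)}\n")
            if i != len(library.records) - 1:
                stream.write("\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# MGF (library dialect)
# ---------------------------------------------------------------------------

_TITLE_KEY = re.compile(r"InChIKey:\s*(\S+)", re.IGNORECASE)
_TITLE_NAME = re.compile(r"Name:\s*(.*)$", re.IGNORECASE)


def write_mgf(library: LibraryFile, dest: Union[str, Path, TextIO]) -> None:
    """Emit BEGIN IONS blocks in the fixed library layout.

    Every record must carry an exact mass, an InChIKey and a name; the
    charge row is always ``CHARGE=1+`` (EI produces singly charged ions).
    """
    stream, close = _open_write(dest)
    try:
        for i, s in enumerate(library.records):
            missing = [f for f, v in (("exact_mass", s.exact_mass),
                                      ("inchikey", s.inchikey),
                                      ("name", s.name)) if not v]
            if missing:
                raise FormatError(
                    f"MGF record requires {', '.join(missing)}",
                    record=s.name or f"#{i}")
            stream.write("BEGIN IONS\n")
            stream.write(f"MASS={format_number(s.exact_mass)}\n")
            stream.write("CHARGE=1+\n")
            stream.write(f"TITLE= InChIKey: {s.inchikey} Name: {s.name}\n")
            stream.write("\n")
            for p in s.peaks:
                stream.write(f"{format_number(p.mz)} {format_number(p.intensity)}\n")
            stream.write("\n")
            stream.write("END IONS\n")
            if i != len(library.records) - 1:
                stream.write("\n")
    finally:
        if close:
            stream.close()


def read_mgf(source: Union[str, Path, TextIO], strict: bool = True) -> LibraryFile:
    """Parse BEGIN IONS/END IONS blocks; tolerant of PEPMASS= and loose TITLEs."""
    stream, source_name, close = _open_read(source)
    lib = LibraryFile(format="MGF", source_path=source_name)
    in_block = False
    begin_line = 0
    fields: dict = {}
    peaks: list[Peak] = []
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\r\n")
            stripped = line.strip()
            if not in_block:
                if stripped == "BEGIN IONS":
                    in_block = True
                    begin_line = lineno
                    fields, peaks = {}, []
                elif stripped:
                    msg = FormatError(f"content outside BEGIN IONS block: {stripped!r}",
                                      line=lineno, source=source_name)
                    if strict:
                        raise msg
                    lib.issues.append(str(msg))
                continue
            if stripped == "END IONS":
                lib.records.append(Spectrum(
                    peaks=tuple(peaks),
                    name=fields.get("name", ""),
                    inchikey=fields.get("inchikey"),
                    exact_mass=fields.get("exact_mass"),
                ))
                in_block = False
                continue
            if not stripped:
                continue
            upper = stripped.upper()
            if upper.startswith(("MASS=", "PEPMASS=")):
                value = stripped.split("=", 1)[1].strip().split()[0]
                fields["exact_mass"] = _opt_float(value)
            elif upper.startswith("CHARGE="):
                pass
            elif upper.startswith("TITLE"):
                title = stripped.split("=", 1)[1] if "=" in stripped else ""
                mkey = _TITLE_KEY.search(title)
                mname = _TITLE_NAME.search(title)
                if mkey:
                    key_text = mkey.group(1)
                    # the name token may follow without whitespace discipline
                    fields["inchikey"] = key_text
                else:
                    lib.issues.append(
                        f"{source_name}, line {lineno}: TITLE lacks 'InChIKey:' token")
                if mname:
                    fields["name"] = mname.group(1).strip()
                elif not mkey:
                    fields["name"] = title.strip()
            elif "=" in stripped and not stripped[0].isdigit():
                pass  # other MGF parameters tolerated and dropped
            else:
                peaks.extend(_parse_peak_line(stripped, lineno, source_name))
        if in_block:
            raise FormatError("unterminated BEGIN IONS block",
                              line=begin_line, source=source_name)
    finally:
        if close:
            stream.close()
    return lib


# ---------------------------------------------------------------------------
# conversion
# ---------------------------------------------------------------------------

_READERS = {"MSP": read_msp, "MGF": read_mgf, "TXT": read_txt}
_WRITERS = {"MSP": write_msp, "MGF": write_mgf, "TXT": write_txt}


def read_library(source, fmt: str, strict: bool = True) -> LibraryFile:
    fmt = fmt.upper()
    if fmt not in FORMATS:
        raise ValueError(f"unknown library format: {fmt!r}")
    return _READERS[fmt](source, strict=strict)


def write_library(library: LibraryFile, dest, fmt: str) -> None:
    fmt = fmt.upper()
    if fmt not in FORMATS:
        raise ValueError(f"unknown library format: {fmt!r}")
    out = LibraryFile(format=fmt, records=library.records,
                      source_path=library.source_path)
    _WRITERS[fmt](out, dest)


def convert(input_path, input_format: str, output_path, output_format: str,
            strict: bool = True) -> ConversionSummary:
    """Read with the matching reader, write with the matching writer.

    Record order is preserved exactly; the summary's read and written counts
    are equal unless lenient mode skipped malformed records.
    """
    lib = read_library(input_path, input_format, strict=strict)
    write_library(lib, output_path, output_format)
    return ConversionSummary(records_read=len(lib.records),
                             records_written=len(lib.records),
                             input_format=input_format.upper(),
                             output_format=output_format.upper())
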