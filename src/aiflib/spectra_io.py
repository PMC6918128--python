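"""Text I/O for spectral libraries and AIF scan data.

Formats
-------
* NIST-style MSP (read/write). Dialect: header lines ``KEY: value`` with
  keys NAME, PRECURSORMZ, PRECURSORTYPE, FORMULA, INCHIKEY, SMILES,
  RETENTIONTIME (minutes), COLLISIONENERGY (eV), IONMODE, COMMENT,
  ``Num Peaks``; then one peak per line, ``mz<TAB>intensity<TAB>"annotation"``
  with the quoted annotation optional. Header keys are matched
  case-insensitively on read; unknown keys are preserved verbatim in the
  record's provenance mapping. The experimental precursor m/z displaced
  by curation is kept in COMMENT as ``experimental_mz=<value>``.
* MGF (read/write): minimal BEGIN IONS/END IONS dialect; PEPMASS maps to
  the precursor m/z and RTINSECONDS to rt*60 (RT is minutes internally).
* MassBank record text (read only).
* Internal tabular AIF scan format (read/write): a TSV with columns
  ``cycle  channel_ev  time_min  mz  intensity``, one centroid per row,
  preceded by ``# key: value`` metadata lines (mass range, channels).

All text I/O is UTF-8. Floats are serialized with Python's shortest
round-trip representation, so read(write(x)) is exact and the writer is
byte-stable for identical input.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, TextIO, Union

import pandas as pd

from .chem import (
    AdductDescriptor,
    ElementalFormula,
    InChIKeyText,
    parse_adduct,
    parse_formula,
)
from .spectra import AIFRun, Cycle, LibraryRecord, Peak, PeakAnnotation, Scan, Spectrum

__all__ = [
    "read_msp",
    "write_msp",
    "read_mgf",
    "write_mgf",
    "read_massbank",
    "read_aif_run",
    "write_aif_run",
    "MSPFormatError",
]

Source = Union[str, Path, TextIO]


class MSPFormatError(ValueError):
    """Structurally invalid library file (peak-count mismatch, bad peak line)."""


def _fmt(x: float) -> str:
    """Shortest exact decimal form of a float (numpy scalars coerced)."""
    return repr(float(x))


def _open_text(source: Source, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8"), True
    return source, False


_EXP_MZ_RE = re.compile(r"\bexperimental_mz=([0-9.eE+-]+)\b")

_MSP_FIELD_ORDER = (
    "NAME",
    "PRECURSORMZ",
    "PRECURSORTYPE",
    "FORMULA",
    "INCHIKEY",
    "SMILES",
    "RETENTIONTIME",
    "COLLISIONENERGY",
    "IONMODE",
    "COMMENT",
)
_KNOWN_KEYS = set(_MSP_FIELD_ORDER) | {"NUM PEAKS"}


# ---------------------------------------------------------------------------
# peak-annotation comment grammar:  label; kind[; formula=F][; theo=M;
# err=E][; radical]  — minimal two-part form "label; kind" also accepted.
# ---------------------------------------------------------------------------

def _annotation_to_text(a: PeakAnnotation) -> str:
    parts = [a.label, a.kind]
    if a.ion_formula is not None:
        parts.append(f"formula={a.ion_formula}")
    parts.append(f"theo={_fmt(a.theoretical_mz)}")
    parts.append(f"err={_fmt(a.mass_error_mda)}")
    if a.radical:
        parts.append("radical")
    return "; ".join(parts)


def _annotation_from_text(text: str, peak_mz: float) -> PeakAnnotation:
    parts = [p.strip() for p in text.split(";") if p.strip()]
    label = parts[0] if parts else text
    kind = "fragment"
    formula = None
    theo = peak_mz
    err = 0.0
    radical = False
    for p in parts[1:]:
        if p in ("fragment", "adduct", "isotope", "precursor"):
            kind = p
        elif p.startswith("formula="):
            formula = parse_formula(p.split("=", 1)[1])
        elif p.startswith("theo="):
            theo = float(p.split("=", 1)[1])
        elif p.startswith("err="):
            err = float(p.split("=", 1)[1])
        elif p == "radical":
            radical = True
    return PeakAnnotation(
        kind=kind,  # type: ignore[arg-type]
        label=label,
        theoretical_mz=theo,
        mass_error_mda=err,
        ion_formula=formula,
        radical=radical,
    )


# ---------------------------------------------------------------------------
# MSP
# ---------------------------------------------------------------------------

_PEAK_LINE_RE = re.compile(
    r'^\s*([0-9.eE+-]+)[\s\t]+([0-9.eE+-]+)(?:[\s\t]+"([^"]*)")?\s*$'
)


def _record_from_headers(
    headers: dict[str, str], order: list[str], peaks: list[Peak]
) -> LibraryRecord:
    def pop(key: str, default: str = "") -> str:
        return headers.pop(key, default)

    name = pop("NAME")
    precursor = float(pop("PRECURSORMZ", "0") or 0)
    adduct_txt = pop("PRECURSORTYPE")
    formula_txt = pop("FORMULA")
    ik_txt = pop("INCHIKEY")
    smiles = pop("SMILES")
    rt = float(pop("RETENTIONTIME", "0") or 0)
    ce = float(pop("COLLISIONENERGY", "0") or 0)
    ion_mode = pop("IONMODE", "positive").lower() or "positive"
    comment = pop("COMMENT")
    headers.pop("NUM PEAKS", None)

    experimental = 0.0
    m = _EXP_MZ_RE.search(comment)
    if m:
        experimental = float(m.group(1))
        comment = _EXP_MZ_RE.sub("", comment).strip().strip(";").strip()

    provenance = {k: v for k, v in ((k, headers[k]) for k in order if k in headers)}
    if comment:
        provenance["COMMENT"] = comment

    spectrum = Spectrum(
        peaks=tuple(peaks),
        precursor_mz=precursor,
        collision_energy=ce,
        rt=rt,
        ion_mode=ion_mode,  # type: ignore[arg-type]
    )
    return LibraryRecord(
        name=name,
        spectrum=spectrum,
        formula=parse_formula(formula_txt) if formula_txt else None,
        adduct=parse_adduct(adduct_txt) if adduct_txt else None,
        inchikey=InChIKeyText(ik_txt) if ik_txt else None,
        smiles=smiles,
        theoretical_precursor_mz=precursor,
        experimental_precursor_mz=experimental,
        rt=rt,
        provenance=provenance,
    )


def read_msp(source: Source) -> list[LibraryRecord]:
    """Read one or more MSP records; one record per NAME block.

    Raises :class:`MSPFormatError` (naming the record) if the peak-line
    count does not equal the ``Num Peaks`` declaration or a peak line is
    unparseable.
    """
    stream, close = _open_text(source)
    try:
        records: list[LibraryRecord] = []
        headers: dict[str, str] = {}
        key_order: list[str] = []
        peaks: list[Peak] = []
        num_declared: int | None = None
        in_peaks = False

        def flush():
            nonlocal headers, key_order, peaks, num_declared, in_peaks
            if headers or peaks:
                name = headers.get("NAME", "<unnamed>")
                if num_declared is not None and len(peaks) != num_declared:
                    raise MSPFormatError(
                        f"record {name!r}: Num Peaks declares {num_declared} "
                        f"but {len(peaks)} peak lines found"
                    )
                records.append(_record_from_headers(headers, key_order, peaks))
            headers, key_order, peaks = {}, [], []
            num_declared, in_peaks = None, False

        for raw in stream:
            line = raw.rstrip("\n")
            if not line.strip():
                if headers or peaks:
                    flush()
                continue
            if in_peaks:
                m = _PEAK_LINE_RE.match(line)
                if m is None:
                    raise MSPFormatError(
                        f"record {headers.get('NAME', '<unnamed>')!r}: "
                        f"unparseable peak line: {line!r}"
                    )
                mz, inten, ann = float(m.group(1)), float(m.group(2)), m.group(3)
                peaks.append(
                    Peak(
                        mz=mz,
                        intensity=inten,
                        annotation=_annotation_from_text(ann, mz) if ann else None,
                    )
                )
                continue
            if ":" in line:
                key, _, value = line.partition(":")
                ukey = key.strip().upper()
                if ukey == "NAME" and headers:
                    flush()
                if ukey == "NUM PEAKS":
                    num_declared = int(value.strip())
                    headers[ukey] = value.strip()
                    in_peaks = True
                else:
                    headers[ukey if ukey in _KNOWN_KEYS else key.strip()] = value.strip()
                    key_order.append(ukey if ukey in _KNOWN_KEYS else key.strip())
            else:
                raise MSPFormatError(f"unexpected line outside peak block: {line!r}")
        flush()
        return records
    finally:
        if close:
            stream.close()


def write_msp(records: Iterable[LibraryRecord], sink: Source) -> None:
    """Write records in the canonical field order; deterministic output."""
    stream, close = _open_text(sink, "w")
    try:
        for rec in records:
            if not rec.name:
                raise MSPFormatError("record is missing a name")
            if not rec.spectrum.peaks:
                raise MSPFormatError(f"record {rec.name!r} has no peaks")
            comment = rec.provenance.get("COMMENT", "")
            if rec.experimental_precursor_mz:
                tag = f"experimental_mz={_fmt(rec.experimental_precursor_mz)}"
                comment = f"{comment}; {tag}" if comment else tag
            stream.write(f"NAME: {rec.name}\n")
            stream.write(f"PRECURSORMZ: {_fmt(rec.precursor_mz)}\n")
            if rec.adduct is not None:
                stream.write(f"PRECURSORTYPE: {rec.adduct.name}\n")
            if rec.formula is not None:
                stream.write(f"FORMULA: {rec.formula}\n")
            if rec.inchikey is not None:
                stream.write(f"INCHIKEY: {rec.inchikey}\n")
            if rec.smiles:
                stream.write(f"SMILES: {rec.smiles}\n")
            stream.write(f"RETENTIONTIME: {_fmt(rec.rt)}\n")
            stream.write(f"COLLISIONENERGY: {_fmt(rec.spectrum.collision_energy)}\n")
            stream.write(f"IONMODE: {rec.spectrum.ion_mode}\n")
            if comment:
                stream.write(f"COMMENT: {comment}\n")
            for key, value in rec.provenance.items():
                if key != "COMMENT":
                    stream.write(f"{key}: {value}\n")
            stream.write(f"Num Peaks: {len(rec.spectrum.peaks)}\n")
            for p in rec.spectrum.peaks:
                if p.annotation is not None:
                    stream.write(
                        f"{_fmt(p.mz)}\t{_fmt(p.intensity)}\t\"{_annotation_to_text(p.annotation)}\"\n"
                    )
                else:
                    stream.write(f"{_fmt(p.mz)}\t{_fmt(p.intensity)}\n")
            stream.write("\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def read_mgf(source: Source) -> list[LibraryRecord]:
    """Minimal BEGIN IONS/END IONS reader. RTINSECONDS converts to minutes."""
    stream, close = _open_text(source)
    try:
        records: list[LibraryRecord] = []
        in_block = False
        headers: dict[str, str] = {}
        peaks: list[Peak] = []
        for raw in stream:
            line = raw.strip()
            if not line:
                continue
            if line == "BEGIN IONS":
                in_block, headers, peaks = True, {}, []
                continue
            if line == "END IONS":
                if not in_block:
                    raise MSPFormatError("END IONS without BEGIN IONS")
                records.append(_record_from_mgf(headers, peaks))
                in_block = False
                continue
            if not in_block:
                continue  # comments between blocks
            if "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                headers[key.strip().upper()] = value.strip()
            else:
                cols = line.split()
                if len(cols) < 2:
                    raise MSPFormatError(f"unparseable MGF peak line: {line!r}")
                peaks.append(Peak(mz=float(cols[0]), intensity=float(cols[1])))
        if in_block:
            raise MSPFormatError("unterminated BEGIN IONS block")
        return records
    finally:
        if close:
            stream.close()


def _record_from_mgf(headers: dict[str, str], peaks: list[Peak]) -> LibraryRecord:
    pepmass = float(headers.pop("PEPMASS", "0").split()[0] or 0)
    rt = float(headers.pop("RTINSECONDS", "0") or 0) / 60.0
    name = headers.pop("TITLE", "")
    formula_txt = headers.pop("FORMULA", "")
    adduct_txt = headers.pop("PRECURSORTYPE", "")
    ik = headers.pop("INCHIKEY", "")
    smiles = headers.pop("SMILES", "")
    ce = float(headers.pop("COLLISIONENERGY", "0") or 0)
    ion_mode = headers.pop("IONMODE", "positive").lower()
    headers.pop("CHARGE", None)
    spectrum = Spectrum(
        peaks=tuple(peaks),
        precursor_mz=pepmass,
        collision_energy=ce,
        rt=rt,
        ion_mode=ion_mode,  # type: ignore[arg-type]
    )
    return LibraryRecord(
        name=name,
        spectrum=spectrum,
        formula=parse_formula(formula_txt) if formula_txt else None,
        adduct=parse_adduct(adduct_txt) if adduct_txt else None,
        inchikey=InChIKeyText(ik) if ik else None,
        smiles=smiles,
        theoretical_precursor_mz=pepmass,
        rt=rt,
        provenance=dict(headers),
    )


def write_mgf(records: Iterable[LibraryRecord], sink: Source) -> None:
    stream, close = _open_text(sink, "w")
    try:
        for rec in records:
            stream.write("BEGIN IONS\n")
            stream.write(f"TITLE={rec.name}\n")
            stream.write(f"PEPMASS={_fmt(rec.precursor_mz)}\n")
            stream.write(f"RTINSECONDS={_fmt(rec.rt * 60.0)}\n")
            if rec.adduct is not None:
                stream.write(f"PRECURSORTYPE={rec.adduct.name}\n")
                stream.write(f"CHARGE={abs(rec.adduct.charge)}"
                             f"{'+' if rec.adduct.charge > 0 else '-'}\n")
            if rec.formula is not None:
                stream.write(f"FORMULA={rec.formula}\n")
            if rec.inchikey is not None:
                stream.write(f"INCHIKEY={rec.inchikey}\n")
            if rec.smiles:
                stream.write(f"SMILES={rec.smiles}\n")
            stream.write(f"COLLISIONENERGY={_fmt(rec.spectrum.collision_energy)}\n")
            stream.write(f"IONMODE={rec.spectrum.ion_mode}\n")
            for key, value in rec.provenance.items():
                stream.write(f"{key}={value}\n")
            for p in rec.spectrum.peaks:
                stream.write(f"{_fmt(p.mz)} {_fmt(p.intensity)}\n")
            stream.write("END IONS\n\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# MassBank record (read only)
# ---------------------------------------------------------------------------

def read_massbank(source: Source) -> list[LibraryRecord]:
    """Read MassBank record text (one or more records separated by ``//``)."""
    stream, close = _open_text(source)
    try:
        records: list[LibraryRecord] = []
        fields: dict[str, str] = {}
        peaks: list[Peak] = []
        in_peaks = False
        num_peak: int | None = None

        def flush():
            nonlocal fields, peaks, in_peaks, num_peak
            if fields:
                if num_peak is not None and len(peaks) != num_peak:
                    raise MSPFormatError(
                        f"MassBank record {fields.get('CH$NAME', '?')!r}: "
                        f"PK$NUM_PEAK {num_peak} != {len(peaks)} peak lines"
                    )
                records.append(_record_from_massbank(fields, peaks))
            fields, peaks, in_peaks, num_peak = {}, [], False, None

        for raw in stream:
            line = raw.rstrip("\n")
            if line.strip() == "//":
                flush()
                continue
            if in_peaks and line.startswith("  "):
                cols = line.split()
                if len(cols) >= 2:
                    peaks.append(Peak(mz=float(cols[0]), intensity=float(cols[1])))
                continue
            in_peaks = False
            if ":" not in line:
                continue
            key, _, value = line.partition(":")
            key, value = key.strip(), value.strip()
            if key == "PK$NUM_PEAK":
                num_peak = int(value)
            elif key == "PK$PEAK":
                in_peaks = True
            elif key in fields and key in ("CH$NAME", "CH$LINK", "AC$CHROMATOGRAPHY",
                                           "AC$MASS_SPECTROMETRY", "MS$FOCUSED_ION"):
                fields[key] += "\n" + value
            else:
                fields[key] = value
        flush()
        return records
    finally:
        if close:
            stream.close()


def _massbank_sub(fields: dict[str, str], key: str, sub: str) -> str:
    for entry in fields.get(key, "").split("\n"):
        if entry.startswith(sub):
            return entry[len(sub):].strip()
    return ""


def _record_from_massbank(fields: dict[str, str], peaks: list[Peak]) -> LibraryRecord:
    name = fields.get("CH$NAME", "").split("\n")[0]
    formula_txt = fields.get("CH$FORMULA", "")
    smiles = fields.get("CH$SMILES", "")
    ik = _massbank_sub(fields, "CH$LINK", "INCHIKEY")
    rt_txt = _massbank_sub(fields, "AC$CHROMATOGRAPHY", "RETENTION_TIME")
    rt = 0.0
    if rt_txt:
        value = float(rt_txt.split()[0])
        rt = value / 60.0 if "sec" in rt_txt.lower() or rt_txt.lower().endswith(" s") else value
    precursor_txt = _massbank_sub(fields, "MS$FOCUSED_ION", "PRECURSOR_M/Z")
    adduct_txt = _massbank_sub(fields, "MS$FOCUSED_ION", "PRECURSOR_TYPE")
    ce_txt = _massbank_sub(fields, "AC$MASS_SPECTROMETRY", "COLLISION_ENERGY")
    ce = float(re.sub(r"[^\d.]", "", ce_txt) or 0)
    ion_mode = "negative" if "NEGATIVE" in fields.get("AC$MASS_SPECTROMETRY", "") else "positive"
    precursor = float(precursor_txt or 0)
    spectrum = Spectrum(
        peaks=tuple(peaks),
        precursor_mz=precursor,
        collision_energy=ce,
        rt=rt,
        ion_mode=ion_mode,  # type: ignore[arg-type]
    )
    smiles_ok = smiles if smiles not in ("N/A", "NA") else ""
    return LibraryRecord(
        name=name,
        spectrum=spectrum,
        formula=parse_formula(formula_txt) if formula_txt and formula_txt != "N/A" else None,
        adduct=parse_adduct(adduct_txt) if adduct_txt else None,
        inchikey=InChIKeyText(ik) if ik else None,
        smiles=smiles_ok,
        theoretical_precursor_mz=precursor,
        rt=rt,
        provenance={"ACCESSION": fields.get("ACCESSION", "")},
    )


# ---------------------------------------------------------------------------
# internal tabular AIF scan format
# ---------------------------------------------------------------------------

def write_aif_run(run: AIFRun, sink: Source) -> None:
    """Serialize a run as ``# key: value`` metadata plus a centroid TSV."""
    stream, close = _open_text(sink, "w")
    try:
        stream.write(f"# run_id: {run.run_id}\n")
        stream.write(f"# channels_ev: {','.join(_fmt(e) for e in run.channel_energies)}\n")
        stream.write(f"# mass_range: {_fmt(run.mass_range[0])},{_fmt(run.mass_range[1])}\n")
        stream.write("cycle\tchannel_ev\ttime_min\tmz\tintensity\n")
        for i, cycle in enumerate(run.cycles):
            for energy in run.channel_energies:
                scan = cycle.scans[energy]
                if scan.mz.size == 0:
                    # keep an explicit empty-scan marker so cycles round-trip
                    stream.write(f"{i}\t{_fmt(energy)}\t{_fmt(scan.time)}\tNA\tNA\n")
                for mz, inten in zip(scan.mz, scan.intensity):
                    stream.write(f"{i}\t{_fmt(energy)}\t{_fmt(scan.time)}\t{_fmt(mz)}\t{_fmt(inten)}\n")
    finally:
        if close:
            stream.close()


def read_aif_run(source: Source) -> AIFRun:
    """Read the internal tabular AIF format back into an :class:`AIFRun`.

    Scans are grouped into cycles by the explicit cycle index; a cycle
    missing one of the declared channels, or non-monotone cycle times,
    raise ``ValueError`` via the AIFRun invariants.
    """
    stream, close = _open_text(source)
    try:
        meta: dict[str, str] = {}
        pos = stream.tell() if stream.seekable() else None
        header_lines = 0
        for line in stream:
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
                header_lines += 1
            else:
                break
        if stream.seekable():
            stream.seek(pos or 0)
            df = pd.read_csv(
                stream, sep="\t", comment="#", na_values=["NA"],
                float_precision="round_trip",
            )
        else:  # pragma: no cover - non-seekable streams
            raise ValueError("read_aif_run requires a seekable stream or a path")
    finally:
        if close and not stream.closed:
            stream.close()

    channels = tuple(float(x) for x in meta.get("channels_ev", "0,10,30").split(","))
    lo, hi = (float(x) for x in meta.get("mass_range", "40,1200").split(","))
    run_id = meta.get("run_id", "")

    cycles: list[Cycle] = []
    for _, cyc_df in df.groupby("cycle", sort=True):
        scans: dict[float, Scan] = {}
        for energy, ch_df in cyc_df.groupby("channel_ev", sort=True):
            real = ch_df.dropna(subset=["mz"])
            scans[float(energy)] = Scan(
                time=float(ch_df["time_min"].iloc[0]),
                energy=float(energy),
                mz=real["mz"].to_numpy(dtype=float),
                intensity=real["intensity"].to_numpy(dtype=float),
            )
        cycles.append(Cycle(scans=scans))
    return AIFRun(
        cycles=cycles, channel_energies=channels, mass_range=(lo, hi), run_id=run_id
    )
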