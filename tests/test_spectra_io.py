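"""Library and scan-data text formats: MSP, MGF, MassBank, tabular AIF."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aiflib import spectra_io, synthgen
from aiflib.chem import InChIKeyText, parse_adduct, parse_formula
from aiflib.spectra import AIFRun, Cycle, LibraryRecord, Peak, PeakAnnotation, Scan, Spectrum
from aiflib.spectra_io import MSPFormatError, read_mgf, read_msp, write_mgf, write_msp


def make_record(name="trigonelline", n_peaks=3, rt=7.46, annotate=False):
    peaks = []
    for i in range(n_peaks):
        ann = None
        if annotate:
            ann = PeakAnnotation(
                kind="fragment",
                label=f"C{i + 2}H{i + 4}N+",
                theoretical_mz=50.0 + 10 * i,
                mass_error_mda=0.5,
                ion_formula=parse_formula(f"C{i + 2}H{i + 4}N"),
            )
        peaks.append(Peak(mz=50.0 + 10 * i, intensity=100.0 - i, annotation=ann))
    return LibraryRecord(
        name=name,
        spectrum=Spectrum(
            peaks=tuple(peaks), precursor_mz=138.055, collision_energy=30.0, rt=rt
        ),
        formula=parse_formula("C7H7NO2"),
        adduct=parse_adduct("[M+H]+"),
        inchikey=InChIKeyText(synthgen.synthetic_inchikey(name)),
        smiles="C[n+]1cccc(c1)C(=O)[O-]",
        theoretical_precursor_mz=138.055,
        experimental_precursor_mz=138.0561,
        rt=rt,
        provenance={"INSTRUMENT": "synthetic Q-TOF", "AUTHORS": "aiflib tests"},
    )


# --- MSP -------------------------------------------------------------------

def test_msp_roundtrip_identity():
    records = [make_record(), make_record("probe-2", n_peaks=5, annotate=True)]
    buf = io.StringIO()
    write_msp(records, buf)
    back = read_msp(io.StringIO(buf.getvalue()))
    assert len(back) == 2
    for orig, rt in zip(records, back):
        assert rt.name == orig.name
        assert rt.formula == orig.formula
        assert rt.adduct == orig.adduct
        assert rt.inchikey == orig.inchikey
        assert rt.smiles == orig.smiles
        assert rt.theoretical_precursor_mz == orig.theoretical_precursor_mz
        assert rt.experimental_precursor_mz == orig.experimental_precursor_mz
        assert rt.rt == orig.rt
        assert rt.provenance == orig.provenance
        assert rt.spectrum.peaks == orig.spectrum.peaks


def test_msp_writer_byte_stable():
    records = [make_record(annotate=True)]
    a, b = io.StringIO(), io.StringIO()
    write_msp(records, a)
    write_msp(records, b)
    assert a.getvalue() == b.getvalue()


def test_msp_num_peaks_mismatch_names_record():
    text = "NAME: broken\nPRECURSORMZ: 100.0\nNum Peaks: 3\n100.0\t10\n101.0\t20\n\n"
    with pytest.raises(MSPFormatError, match="broken"):
        read_msp(io.StringIO(text))


def test_msp_unparseable_peak_line():
    text = "NAME: bad\nNum Peaks: 1\nnot-a-peak\n"
    with pytest.raises(MSPFormatError):
        read_msp(io.StringIO(text))


def test_msp_peak_annotation_dialect():
    text = 'NAME: t\nNum Peaks: 1\n94.0651\t999\t"C6H8N+; fragment"\n'
    (rec,) = read_msp(io.StringIO(text))
    peak = rec.spectrum.peaks[0]
    assert peak.annotation is not None
    assert peak.annotation.label == "C6H8N+"
    assert peak.annotation.kind == "fragment"


def test_msp_headers_case_insensitive_and_unknown_preserved():
    text = (
        "Name: x\nPrecursorMz: 100.5\nRetentionTime: 2.5\n"
        "MYCUSTOMKEY: kept verbatim\nNum Peaks: 1\n100.0\t1\n"
    )
    (rec,) = read_msp(io.StringIO(text))
    assert rec.name == "x"
    assert rec.theoretical_precursor_mz == 100.5
    assert rec.rt == 2.5
    assert rec.provenance["MYCUSTOMKEY"] == "kept verbatim"


def test_msp_write_requires_name_and_peaks():
    rec = make_record()
    rec.name = ""
    with pytest.raises(MSPFormatError):
        write_msp([rec], io.StringIO())
    rec2 = make_record()
    rec2.spectrum = Spectrum(peaks=())
    with pytest.raises(MSPFormatError):
        write_msp([rec2], io.StringIO())


# --- MGF -------------------------------------------------------------------

def test_mgf_rtinseconds_converts_to_minutes():
    text = "BEGIN IONS\nTITLE=t\nPEPMASS=138.055\nRTINSECONDS=447.6\n100.0 5\nEND IONS\n"
    (rec,) = read_mgf(io.StringIO(text))
    assert rec.rt == pytest.approx(7.46, abs=1e-9)


def test_mgf_empty_stream():
    assert read_mgf(io.StringIO("")) == []


def test_mgf_unterminated_block():
    with pytest.raises(MSPFormatError):
        read_mgf(io.StringIO("BEGIN IONS\nPEPMASS=1\n100.0 1\n"))


def test_mgf_roundtrip():
    records = [make_record(), make_record("probe-2", n_peaks=4)]
    buf = io.StringIO()
    write_mgf(records, buf)
    back = read_mgf(io.StringIO(buf.getvalue()))
    assert len(back) == 2
    for orig, rt in zip(records, back):
        assert rt.name == orig.name
        assert rt.formula == orig.formula
        assert rt.adduct == orig.adduct
        assert rt.inchikey == orig.inchikey
        assert rt.rt == pytest.approx(orig.rt, abs=1e-12)
        assert [p.mz for p in rt.spectrum.peaks] == [p.mz for p in orig.spectrum.peaks]
        assert [p.intensity for p in rt.spectrum.peaks] == [
            p.intensity for p in orig.spectrum.peaks
        ]


# --- MassBank (read only) --------------------------------------------------

MASSBANK_TEXT = """ACCESSION: SYNTH00001
CH$NAME: trigonelline
CH$FORMULA: C7H7NO2
CH$SMILES: C[n+]1cccc(c1)C(=O)[O-]
CH$LINK: INCHIKEY AAAAAAAAAAAAAA-UHFFFAOYSA-N
AC$MASS_SPECTROMETRY: MS_TYPE MS2
AC$MASS_SPECTROMETRY: ION_MODE POSITIVE
AC$MASS_SPECTROMETRY: COLLISION_ENERGY 30 eV
AC$CHROMATOGRAPHY: RETENTION_TIME 7.46 min
MS$FOCUSED_ION: PRECURSOR_M/Z 138.055
MS$FOCUSED_ION: PRECURSOR_TYPE [M+H]+
PK$NUM_PEAK: 2
PK$PEAK: m/z int. rel.int.
  94.0651 999 999
  138.055 200 200
//
"""


def test_massbank_reader():
    (rec,) = spectra_io.read_massbank(io.StringIO(MASSBANK_TEXT))
    assert rec.name == "trigonelline"
    assert rec.formula == parse_formula("C7H7NO2")
    assert rec.inchikey.first_block == "AAAAAAAAAAAAAA"
    assert rec.rt == pytest.approx(7.46)
    assert rec.precursor_mz == pytest.approx(138.055)
    assert rec.adduct.name == "[M+H]+"
    assert rec.spectrum.collision_energy == 30.0
    assert len(rec.spectrum.peaks) == 2


def test_massbank_peak_count_mismatch():
    broken = MASSBANK_TEXT.replace("PK$NUM_PEAK: 2", "PK$NUM_PEAK: 5")
    with pytest.raises(MSPFormatError):
        spectra_io.read_massbank(io.StringIO(broken))


# --- tabular AIF format ----------------------------------------------------

def test_aif_run_roundtrip(tiny_run, tmp_path):
    run, _, _ = tiny_run
    path = tmp_path / "run.aif.tsv"
    spectra_io.write_aif_run(run, path)
    back = spectra_io.read_aif_run(path)
    assert len(back) == len(run)
    assert back.channel_energies == run.channel_energies
    assert back.mass_range == run.mass_range
    assert back.run_id == run.run_id
    for c_orig, c_back in zip(run.cycles, back.cycles):
        for energy in run.channel_energies:
            s_o, s_b = c_orig.scans[energy], c_back.scans[energy]
            assert s_b.time == s_o.time
            np.testing.assert_array_equal(s_b.mz, s_o.mz)
            np.testing.assert_array_equal(s_b.intensity, s_o.intensity)


def test_scan_rate_gives_two_cycles_per_second(tiny_run):
    # 6 scans/s across 3 alternating channels = 2 cycles per second
    run, _, _ = tiny_run
    times = run.channel_times(0.0)
    dt_s = np.diff(times).mean() * 60.0
    assert dt_s == pytest.approx(0.5, rel=1e-6)
    assert len(run) == 240  # 2-minute gradient at 2 cycles/s


def test_missing_channel_in_cycle_rejected():
    scan0 = Scan(time=0.0, energy=0.0, mz=np.array([100.0]), intensity=np.array([1.0]))
    scan10 = Scan(time=0.001, energy=10.0, mz=np.array([]), intensity=np.array([]))
    good = Cycle(scans={0.0: scan0, 10.0: scan10, 30.0: scan10})
    bad = Cycle(scans={0.0: scan0, 10.0: scan10})  # 30 eV channel missing
    with pytest.raises(ValueError, match="missing channel"):
        AIFRun(cycles=[good, bad])


def test_non_monotone_cycle_times_rejected():
    def cyc(t):
        s = Scan(time=t, energy=0.0, mz=np.array([]), intensity=np.array([]))
        return Cycle(scans={0.0: s, 10.0: s, 30.0: s})

    with pytest.raises(ValueError, match="not strictly increasing"):
        AIFRun(cycles=[cyc(0.0), cyc(0.5), cyc(0.4)])


# --- property: random-record roundtrip --------------------------------------

peak_st = st.builds(
    Peak,
    mz=st.floats(min_value=40.0, max_value=1200.0, allow_nan=False),
    intensity=st.floats(min_value=0.0, max_value=1e7, allow_nan=False),
)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    st.lists(peak_st, min_size=1, max_size=8, unique_by=lambda p: p.mz),
    st.floats(min_value=0.1, max_value=15.0, allow_nan=False),
)
def test_msp_roundtrip_random_records(peaks, rt):
    rec = LibraryRecord(
        name="random",
        spectrum=Spectrum(peaks=tuple(peaks), precursor_mz=100.0, rt=rt),
        theoretical_precursor_mz=100.0,
        rt=rt,
    )
    buf = io.StringIO()
    write_msp([rec], buf)
    (back,) = read_msp(io.StringIO(buf.getvalue()))
    assert back.rt == rt
    assert back.spectrum.peaks == rec.spectrum.peaks
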