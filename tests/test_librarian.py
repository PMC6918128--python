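"""Curation engine: similarity, grouping, consistency, consensus, diffing."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aiflib import synthgen
from aiflib.annotate import annotate_fragments, strip_unannotated
from aiflib.chem import InChIKeyText, parse_adduct, parse_formula
from aiflib.deconv import filter_relative_intensity
from aiflib.librarian import (
    check_group_consistency,
    compare_libraries,
    consensus_spectrum,
    dot_product,
    group_records,
    product_ion_frequency,
    replace_precursor_mz,
)
from aiflib.spectra import LibraryRecord, Peak, Spectrum


def spectrum_of(*pairs, ce=30.0):
    return Spectrum(
        peaks=tuple(Peak(mz=m, intensity=i) for m, i in pairs), collision_energy=ce
    )


def record_of(name, spectrum, key=None, formula="C7H7NO2", rt=7.46):
    return LibraryRecord(
        name=name,
        spectrum=spectrum,
        formula=parse_formula(formula) if formula else None,
        adduct=parse_adduct("[M+H]+"),
        inchikey=InChIKeyText(key) if key else InChIKeyText(
            synthgen.synthetic_inchikey(name)
        ),
        theoretical_precursor_mz=spectrum.precursor_mz or 138.055,
        rt=rt,
    )


# --- dot product -------------------------------------------------------------

def test_dot_product_identical_is_100():
    s = spectrum_of((100, 100.0), (110, 50.0))
    assert dot_product(s, s, 0.01) == pytest.approx(100.0)


def test_dot_product_disjoint_is_0():
    a = spectrum_of((100, 100.0))
    b = spectrum_of((200, 100.0))
    assert dot_product(a, b, 0.01) == 0.0


def test_dot_product_hand_value():
    # cosine^2 = (100*50 + 50*100)^2 / ((100^2+50^2)(50^2+100^2)) = 0.64
    a = spectrum_of((100, 100.0), (110, 50.0))
    b = spectrum_of((100, 50.0), (110, 100.0))
    assert dot_product(a, b, 0.01) == pytest.approx(64.0)


def test_dot_product_empty_warns_and_returns_zero(caplog):
    with caplog.at_level("WARNING"):
        assert dot_product(Spectrum(peaks=()), spectrum_of((100, 1.0)), 0.01) == 0.0
    assert caplog.records


spectra_st = st.lists(
    st.tuples(
        st.floats(min_value=50, max_value=500, allow_nan=False),
        st.floats(min_value=1, max_value=1e6, allow_nan=False),
    ),
    min_size=1,
    max_size=10,
    unique_by=lambda t: round(t[0], 1),
)


@settings(max_examples=100, derandomize=True)
@given(spectra_st, spectra_st)
def test_dot_product_symmetric_and_bounded(pa, pb):
    a, b = spectrum_of(*pa), spectrum_of(*pb)
    ab = dot_product(a, b, 0.02)
    ba = dot_product(b, a, 0.02)
    assert ab == pytest.approx(ba, abs=1e-6)
    assert 0.0 <= ab <= 100.0 + 1e-9


# --- grouping ----------------------------------------------------------------

def test_group_same_first_block_different_suffix():
    s = spectrum_of((100, 1.0))
    r1 = record_of("a", s, key="AAAAAAAAAAAAAA-UHFFFAOYSA-N")
    r2 = record_of("b", s, key="AAAAAAAAAAAAAA-ZZZZZZZZSA-N")
    groups = group_records([r1, r2])
    assert len(groups) == 1 and len(groups[0].records) == 2


def test_group_full_key_mode_separates():
    s = spectrum_of((100, 1.0))
    r1 = record_of("a", s, key="AAAAAAAAAAAAAA-UHFFFAOYSA-N")
    r2 = record_of("b", s, key="AAAAAAAAAAAAAA-ZZZZZZZZSA-N")
    assert len(group_records([r1, r2], use_full_key=True)) == 2


def test_group_missing_key_flagged_singleton():
    s = spectrum_of((100, 1.0))
    r = record_of("a", s)
    r.inchikey = None
    (g,) = group_records([r])
    assert g.missing_key and len(g.records) == 1


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.sampled_from(["compound-a", "compound-b", "compound-c"]), max_size=12))
def test_grouping_is_a_partition(names):
    s = spectrum_of((100, 1.0))
    records = [record_of(n, s) for n in names]
    groups = group_records(records)
    assert sum(len(g.records) for g in groups) == len(records)
    seen = [id(r) for g in groups for r in g.records]
    assert len(seen) == len(set(seen))  # disjoint


# --- consistency -------------------------------------------------------------

def test_rt_spread_within_window_not_flagged():
    s = spectrum_of((100, 1.0))
    g = group_records(
        [record_of("a", s, rt=7.41), record_of("a", s, rt=7.46)]
    )[0]
    assert not g.rt_spread_exceeded


def test_rt_spread_beyond_window_flagged():
    s = spectrum_of((100, 1.0))
    g = group_records([record_of("a", s, rt=6.0), record_of("a", s, rt=7.5)])[0]
    check_group_consistency(g, rt_window=1.0)
    assert g.rt_spread_exceeded


def test_identical_formulas_not_flagged():
    s = spectrum_of((100, 1.0))
    g = group_records([record_of("a", s), record_of("a", s)])[0]
    assert not g.formula_mismatch


def test_formula_mismatch_flagged():
    s = spectrum_of((100, 1.0))
    g = group_records(
        [record_of("a", s, formula="C7H7NO2"), record_of("a", s, formula="C5H11NO2")]
    )[0]
    assert g.formula_mismatch


# --- precursor replacement ---------------------------------------------------

def test_replace_precursor_mz():
    s = spectrum_of((100, 1.0))
    rec = record_of("trigonelline", s)
    rec.theoretical_precursor_mz = 138.0561  # experimental reading pre-curation
    out = replace_precursor_mz(rec)
    assert out.theoretical_precursor_mz == pytest.approx(138.05495, abs=5e-5)
    assert out.experimental_precursor_mz == 138.0561


def test_replace_precursor_mz_idempotent():
    s = spectrum_of((100, 1.0))
    rec = record_of("trigonelline", s)
    rec.theoretical_precursor_mz = 138.0561
    once = replace_precursor_mz(rec)
    twice = replace_precursor_mz(once)
    assert twice == once


def test_replace_precursor_requires_formula():
    s = spectrum_of((100, 1.0))
    rec = record_of("x", s)
    rec.formula = None
    with pytest.raises(ValueError):
        replace_precursor_mz(rec)


# --- consensus ---------------------------------------------------------------

def test_consensus_single_spectrum_normalized():
    s = spectrum_of((100, 50.0), (110, 25.0))
    c = consensus_spectrum([s], 0.01)
    assert [p.intensity for p in c.peaks] == [pytest.approx(100.0), pytest.approx(50.0)]


def test_consensus_idempotent_on_copies():
    s = spectrum_of((100, 50.0), (110, 25.0))
    c1 = consensus_spectrum([s, s, s], 0.01)
    c2 = consensus_spectrum([c1], 0.01)
    assert [(round(p.mz, 6), round(p.intensity, 9)) for p in c1.peaks] == [
        (round(p.mz, 6), round(p.intensity, 9)) for p in c2.peaks
    ]


def test_consensus_drops_rare_peak():
    common = [(100, 100.0), (110, 40.0)]
    with_extra = spectrum_of(*common, (300, 30.0))
    others = [spectrum_of(*common), spectrum_of(*common)]
    c = consensus_spectrum([with_extra, *others], 0.01, min_fraction=0.5)
    assert not [p for p in c.peaks if abs(p.mz - 300) < 0.01]


def test_consensus_rejects_mixed_energies():
    with pytest.raises(ValueError, match="mixed"):
        consensus_spectrum([spectrum_of((100, 1.0), ce=10.0), spectrum_of((100, 1.0), ce=30.0)])


# --- product-ion frequency ---------------------------------------------------

def test_frequency_single_record():
    s = spectrum_of((100, 1.0), (110, 2.0), (120, 3.0))
    table = product_ion_frequency([record_of("a", s)])
    assert len(table) == 3
    assert set(table["record_count"]) == {1}


def test_frequency_shared_ion_counts_records_once():
    r1 = record_of("a", spectrum_of((94.065, 1.0), (94.067, 2.0)))  # same bin twice
    r2 = record_of("b", spectrum_of((94.065, 5.0)))
    table = product_ion_frequency([r1, r2], bin_tol=0.01)
    assert len(table) == 1
    assert int(table["record_count"].iloc[0]) == 2


def test_frequency_empty_library():
    assert product_ion_frequency([]).empty


# --- library comparison ------------------------------------------------------

def test_compare_identical_libraries_all_100():
    lib = [
        record_of("a", spectrum_of((100, 10.0), (110, 5.0))),
        record_of("b", spectrum_of((200, 10.0))),
    ]
    table = compare_libraries(lib, lib)
    assert len(table) == 2
    assert table["similarity"].tolist() == pytest.approx([100.0, 100.0])
    assert table["rt_diff"].tolist() == [0.0, 0.0]


def test_compare_disjoint_keys_empty():
    a = [record_of("a", spectrum_of((100, 10.0)))]
    b = [record_of("b", spectrum_of((100, 10.0)))]
    assert compare_libraries(a, b).empty


def test_compare_perturbed_copy_similarity_floor():
    base = spectrum_of((100, 100.0), (110, 50.0), (120, 25.0))
    perturbed = spectrum_of((100, 90.0), (110, 55.0), (120, 27.0))
    a = [record_of("a", base)]
    b = [record_of("a", perturbed)]
    (row,) = compare_libraries(a, b).itertuples(index=False)
    assert 90.0 <= row.similarity < 100.0


# --- curation pipeline idempotence -------------------------------------------

def test_curation_chain_idempotent():
    trig = parse_formula("C7H7NO2")
    mh = parse_adduct("[M+H]+")
    raw = Spectrum(
        peaks=(
            Peak(mz=94.0651, intensity=1000.0),
            Peak(mz=80.0497, intensity=450.0),
            Peak(mz=149.0233, intensity=300.0),  # contaminant, unannotatable
            Peak(mz=138.0552, intensity=200.0),
            Peak(mz=300.0, intensity=5.0),  # <1% of base
        ),
        precursor_mz=138.0552,
        collision_energy=30.0,
        rt=7.46,
    )

    def curate(spec):
        s = filter_relative_intensity(spec, 1.0)
        s = strip_unannotated(annotate_fragments(s, trig, mh, 0.01))
        rec = record_of("trigonelline", s)
        rec.theoretical_precursor_mz = 138.0552
        return replace_precursor_mz(rec)

    once = curate(raw)
    twice_rec = curate(once.spectrum)
    assert [p.mz for p in twice_rec.spectrum.peaks] == [
        p.mz for p in once.spectrum.peaks
    ]
    assert twice_rec.theoretical_precursor_mz == once.theoretical_precursor_mz
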