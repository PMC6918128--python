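"""Library curation: grouping, consistency checks, precursor replacement,
consensus spectra, product-ion frequency and spectral similarity.

Records of the same compound — recognized by the InChIKey or its first
14 characters (the molecular-skeleton block) — are grouped so formula
and RT agreement can be checked across them. Spectral similarity is the
squared-cosine "dot product" on greedily matched peak pairs, reported
as a percentage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import adduct_mz
from .spectra import LibraryRecord, Peak, Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundGroup",
    "dot_product",
    "match_peaks",
    "group_records",
    "check_group_consistency",
    "replace_precursor_mz",
    "consensus_spectrum",
    "product_ion_frequency",
    "compare_libraries",
]


@dataclass
class CompoundGroup:
    """Records sharing one compound key (InChIKey or its first block)."""

    key: str
    records: list[LibraryRecord] = field(default_factory=list)
    formula_mismatch: bool = False
    rt_spread_exceeded: bool = False
    missing_key: bool = False


def match_peaks(
    a: Spectrum, b: Spectrum, bin_tol: float
) -> list[tuple[Optional[Peak], Optional[Peak]]]:
    """Greedy nearest-m/z pairing within ``bin_tol``; each peak used once.

    Candidate pairs are taken in order of increasing m/z distance, ties
    broken toward the lower m/z. Unmatched peaks are paired with None.
    """
    candidates = []
    for i, pa in enumerate(a.peaks):
        for j, pb in enumerate(b.peaks):
            d = abs(pa.mz - pb.mz)
            if d <= bin_tol:
                candidates.append((d, min(pa.mz, pb.mz), i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[Optional[Peak], Optional[Peak]]] = []
    for _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((a.peaks[i], b.peaks[j]))
    for i, pa in enumerate(a.peaks):
        if i not in used_a:
            pairs.append((pa, None))
    for j, pb in enumerate(b.peaks):
        if j not in used_b:
            pairs.append((None, pb))
    return pairs


def dot_product(a: Spectrum, b: Spectrum, bin_tol: float = 0.01) -> float:
    """Squared-cosine spectral similarity in percent (0..100).

    similarity = 100 * (Σ x_i·y_i)² / (Σ x_i² · Σ y_i²) over the
    matched-plus-unmatched intensity vectors. Symmetric; 0 (with a
    warning) when either spectrum is empty.
    """
    if bin_tol <= 0:
        raise ValueError("bin_tol must be > 0")
    if not a.peaks or not b.peaks:
        logger.warning("dot_product on an empty spectrum -> 0")
        return 0.0
    pairs = match_peaks(a, b, bin_tol)
    x = np.array([p.intensity if p is not None else 0.0 for p, _ in pairs])
    y = np.array([q.intensity if q is not None else 0.0 for _, q in pairs])
    denom = float(np.sum(x * x) * np.sum(y * y))
    if denom == 0:
        return 0.0
    return float(100.0 * np.sum(x * y) ** 2 / denom)


def group_records(
    records: Sequence[LibraryRecord], *, use_full_key: bool = False
) -> list[CompoundGroup]:
    """Partition records by InChIKey first block (or full key).

    A record without an InChIKey becomes its own flagged singleton group.
    """
    groups: dict[str, CompoundGroup] = {}
    singletons: list[CompoundGroup] = []
    for i, rec in enumerate(records):
        if rec.inchikey is None:
            g = CompoundGroup(key=f"<no-inchikey:{i}:{rec.name}>", missing_key=True)
            g.records.append(rec)
            singletons.append(g)
            continue
        key = str(rec.inchikey) if use_full_key else rec.inchikey.first_block
        groups.setdefault(key, CompoundGroup(key=key)).records.append(rec)
    out = list(groups.values()) + singletons
    for g in out:
        check_group_consistency(g)
    return out


def check_group_consistency(g: CompoundGroup, rt_window: float = 1.0) -> CompoundGroup:
    """Recompute the formula-mismatch and RT-spread flags in place.

    The RT flag is set when max(RT) - min(RT) >= rt_window (default
    1 minute — records farther apart likely come from different
    chromatographic methods).
    """
    if not g.records:
        raise ValueError("empty compound group")
    formulas = {str(r.formula) for r in g.records if r.formula is not None}
    g.formula_mismatch = len(formulas) > 1
    rts = [r.rt for r in g.records if r.rt > 0]
    g.rt_spread_exceeded = bool(rts) and (max(rts) - min(rts)) >= rt_window
    return g


def replace_precursor_mz(r: LibraryRecord) -> LibraryRecord:
    """Replace the experimental precursor m/z with the theoretical one.

    The experimental reading moves to ``experimental_precursor_mz``
    (serialized into COMMENT); idempotent. Requires formula and adduct.
    """
    if r.formula is None or r.adduct is None:
        raise ValueError(
            f"record {r.name!r}: formula and adduct are required to "
            "compute the theoretical precursor m/z"
        )
    theo = adduct_mz(r.formula, r.adduct)
    if abs(r.theoretical_precursor_mz - theo) < 1e-12 and (
        r.experimental_precursor_mz or not r.theoretical_precursor_mz
    ):
        return r  # already curated
    experimental = r.experimental_precursor_mz or r.theoretical_precursor_mz or 0.0
    spectrum = replace(r.spectrum, precursor_mz=theo)
    return replace_fields(
        r,
        theoretical_precursor_mz=theo,
        experimental_precursor_mz=experimental,
        spectrum=spectrum,
    )


def replace_fields(r: LibraryRecord, **kwargs) -> LibraryRecord:
    from dataclasses import replace as _rep

    return _rep(r, **kwargs)


def consensus_spectrum(
    spectra: Sequence[Spectrum], bin_tol: float = 0.01, min_fraction: float = 0.5
) -> Spectrum:
    """Merge replicate spectra of one compound at one collision energy.

    Peaks are clustered across spectra within ``bin_tol``; clusters seen
    in >= ``min_fraction`` of the spectra are kept with
    intensity-weighted mean m/z and median (per-spectrum normalized)
    intensity; the result is normalized to base peak 100.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    energies = {s.collision_energy for s in spectra}
    if len(energies) > 1:
        raise ValueError(f"mixed collision energies: {sorted(energies)}")
    n = len(spectra)
    normed = [s.normalized() for s in spectra]
    entries = []  # (mz, norm_intensity, spectrum_index)
    for i, s in enumerate(normed):
        for p in s.peaks:
            entries.append((p.mz, p.intensity, i))
    if not entries:
        return Spectrum(peaks=(), collision_energy=spectra[0].collision_energy)
    entries.sort()
    clusters: list[list[tuple[float, float, int]]] = [[entries[0]]]
    for e in entries[1:]:
        if e[0] - clusters[-1][-1][0] <= bin_tol:
            clusters[-1].append(e)
        else:
            clusters.append([e])
    peaks = []
    for cl in clusters:
        members = {i for _, _, i in cl}
        if len(members) / n < min_fraction:
            continue
        mzs = np.array([m for m, _, _ in cl])
        ints = np.array([v for _, v, _ in cl])
        mz = float(np.average(mzs, weights=ints)) if ints.sum() > 0 else float(mzs.mean())
        peaks.append(Peak(mz=mz, intensity=float(np.median(ints))))
    ref = normed[0]
    out = Spectrum(
        peaks=tuple(peaks),
        precursor_mz=ref.precursor_mz,
        collision_energy=ref.collision_energy,
        rt=float(np.median([s.rt for s in spectra])),
        ion_mode=ref.ion_mode,
    )
    return out.normalized()


def product_ion_frequency(
    lib: Sequence[LibraryRecord], bin_tol: float = 0.01
) -> pd.DataFrame:
    """How many records contain an ion in each m/z bin.

    Each record is counted at most once per bin. Returns a DataFrame
    with columns ``mz`` (bin center) and ``record_count``.
    """
    entries = []  # (mz, record index)
    for i, rec in enumerate(lib):
        for p in rec.spectrum.peaks:
            entries.append((p.mz, i))
    if not entries:
        return pd.DataFrame(columns=["mz", "record_count"])
    entries.sort()
    clusters: list[list[tuple[float, int]]] = [[entries[0]]]
    for e in entries[1:]:
        if e[0] - clusters[-1][-1][0] <= bin_tol:
            clusters[-1].append(e)
        else:
            clusters.append([e])
    rows = [
        (float(np.mean([m for m, _ in cl])), len({i for _, i in cl})) for cl in clusters
    ]
    return pd.DataFrame(rows, columns=["mz", "record_count"])


def compare_libraries(
    a: Sequence[LibraryRecord],
    b: Sequence[LibraryRecord],
    bin_tol: float = 0.01,
    rt_window: float | None = None,
) -> pd.DataFrame:
    """Match records across two libraries by InChIKey first block.

    For every key present in both, reports one row per shared collision
    energy: similarity (dot product), RT difference, and the record
    names. ``rt_window``, when given, drops pairs with a larger RT gap.
    """
    def by_key(lib):
        out: dict[str, list[LibraryRecord]] = {}
        for rec in lib:
            if rec.inchikey is not None:
                out.setdefault(rec.inchikey.first_block, []).append(rec)
        return out

    a_keys, b_keys = by_key(a), by_key(b)
    rows = []
    for key in sorted(set(a_keys) & set(b_keys)):
        for ra in a_keys[key]:
            for rb in b_keys[key]:
                if ra.collision_energy != rb.collision_energy:
                    continue
                rt_diff = ra.rt - rb.rt
                if rt_window is not None and abs(rt_diff) > rt_window:
                    continue
                rows.append(
                    {
                        "inchikey_block": key,
                        "name_a": ra.name,
                        "name_b": rb.name,
                        "collision_energy": ra.collision_energy,
                        "similarity": dot_product(ra.spectrum, rb.spectrum, bin_tol),
                        "rt_diff": rt_diff,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "inchikey_block",
            "name_a",
            "name_b",
            "collision_energy",
            "similarity",
            "rt_diff",
        ],
    )
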