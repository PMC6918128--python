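"""Formula-based annotation of deconvoluted MS2 peaks.

Because AIF spectra of a characterized standard may contain the
precursor's adducts, in-source water losses and carbon-13 isotopologues
alongside genuine fragments, every peak is tested against (a) all
subformulas of the ionized precursor's atom multiset (bounded search
with chemical constraints) and (b) an enumerated candidate-ion table of
adducts × water losses × isotopes. Peaks with no interpretation within
tolerance stay unannotated and are removed before library export.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

from .chem import (
    C13_C12_DELTA,
    ELECTRON_MASS,
    AdductDescriptor,
    AdductError,
    ElementalFormula,
    adduct_mz,
    monoisotopic_mass,
    parse_adduct,
    parse_formula,
)
from .spectra import Peak, PeakAnnotation, Spectrum

__all__ = [
    "enumerate_candidate_ions",
    "annotate_fragments",
    "strip_unannotated",
    "subformula_matches",
]

_WATER = parse_formula("H2O")
DEFAULT_ADDUCTS = ("[M+H]+", "[M+Na]+", "[M+K]+")


def _with_extra_water_loss(a: AdductDescriptor, n_waters: int) -> AdductDescriptor:
    """Derive an adduct with ``n_waters`` additional neutral water losses."""
    if n_waters == 0:
        return a
    body = a.name[2 : a.name.index("]")]  # groups between "[M" and "]"
    count = "" if n_waters == 1 else str(n_waters)
    name = f"[M{body}-{count}H2O]{'+' if a.charge > 0 else '-'}"
    return AdductDescriptor(
        name=name,
        charge=a.charge,
        gained=a.gained,
        lost=a.lost + _WATER * n_waters,
    )


def enumerate_candidate_ions(
    f: ElementalFormula,
    adducts: Sequence[AdductDescriptor | str],
    max_water_losses: int = 0,
    max_isotope: int = 0,
) -> list[tuple[str, float]]:
    """Cross product adducts × water losses × isotopes as (label, m/z).

    Infeasible losses (more water than the molecule can give up) are
    skipped; duplicates are removed by label.
    """
    if not adducts:
        raise ValueError("adduct list must be nonempty")
    out: list[tuple[str, float]] = []
    seen: set[str] = set()
    for a in adducts:
        base = parse_adduct(a) if isinstance(a, str) else a
        for w in range(max_water_losses + 1):
            try:
                variant = _with_extra_water_loss(base, w)
                mz0 = adduct_mz(f, variant)
            except AdductError:
                continue  # loss exceeds available atoms — skip, not fatal
            for n in range(max_isotope + 1):
                label = variant.name if n == 0 else f"{variant.name} [13C{n}]"
                if label in seen:
                    continue
                seen.add(label)
                out.append((label, mz0 + n * C13_C12_DELTA / abs(base.charge)))
    return out


def _rdbe(g: ElementalFormula) -> float:
    """Ring-plus-double-bond equivalents of an ion composition.

    Monovalent Na/K/Cl count with hydrogen; N and P are trivalent.
    """
    h_like = g.get("H") + g.get("Na") + g.get("K") + g.get("Cl")
    return g.get("C") - h_like / 2.0 + (g.get("N") + g.get("P")) / 2.0 + 1.0


def _hydrogen_rule(g: ElementalFormula) -> bool:
    return g.get("H") <= 2 * g.get("C") + g.get("N") + 2


def subformula_matches(
    ion_atoms: ElementalFormula, target_mz: float, tol: float, charge: int = 1
) -> list[tuple[ElementalFormula, float, bool]]:
    """All subformulas of ``ion_atoms`` whose singly-charged ion m/z lies
    within ``tol`` of ``target_mz``, as (formula, theoretical m/z, radical).

    Constraints: RDBE >= 0 and H <= 2C+N+2. A composition whose RDBE is
    an integer corresponds to an odd-electron (radical) cation.
    """
    elements = sorted(ion_atoms.counts)
    masses = {e: monoisotopic_mass(ElementalFormula({e: 1})) for e in elements}
    e_shift = -charge * ELECTRON_MASS
    lo = target_mz * abs(charge) - tol - e_shift
    hi = target_mz * abs(charge) + tol - e_shift

    results: list[tuple[ElementalFormula, float, bool]] = []

    def rec(i: int, counts: dict[str, int], mass: float, remaining_max: float) -> None:
        if mass > hi:
            return
        if i == len(elements):
            if mass < lo:
                return
            g = ElementalFormula(dict(counts))
            if g.atom_count < 1:
                return
            rd = _rdbe(g)
            if rd < 0 or not _hydrogen_rule(g):
                return
            mz = (mass + e_shift) / abs(charge)
            results.append((g, mz, float(rd).is_integer()))
            return
        # prune: even taking all remaining atoms cannot reach the window
        if mass + remaining_max < lo:
            return
        e = elements[i]
        tail_max = remaining_max - ion_atoms.get(e) * masses[e]
        for n in range(ion_atoms.get(e) + 1):
            counts[e] = n
            rec(i + 1, counts, mass + n * masses[e], tail_max)
        del counts[e]

    total_max = sum(ion_atoms.get(e) * masses[e] for e in elements)
    rec(0, {}, 0.0, total_max)
    return results


def annotate_fragments(
    s: Spectrum,
    f: ElementalFormula,
    a: AdductDescriptor,
    tol: float = 0.01,
    *,
    adducts: Sequence[str] = DEFAULT_ADDUCTS,
    max_water_losses: int = 3,
    max_isotope: int = 2,
) -> Spectrum:
    """Attach the best annotation (lowest |mass error|) to every peak.

    Candidates are fragment subformulas of the ionized precursor plus
    the precursor's own adduct/isotope ions. Ties break toward
    even-electron ions, then fewer atoms. Peaks with no candidate within
    ``tol`` are left unannotated.
    """
    if tol <= 0:
        raise ValueError("annotation tolerance must be > 0")
    ion_atoms = (f + a.gained) - a.lost
    candidate_ions = enumerate_candidate_ions(
        f, list(dict.fromkeys([a.name, *adducts])), max_water_losses, max_isotope
    )
    precursor_mz_theo = adduct_mz(f, a)

    annotated: list[Peak] = []
    for peak in s.peaks:
        options: list[tuple[float, int, int, PeakAnnotation]] = []
        # (a) fragment subformulas
        for g, mz, radical in subformula_matches(ion_atoms, peak.mz, tol, a.charge):
            kind = "precursor" if g == ion_atoms else "fragment"
            ann = PeakAnnotation(
                kind=kind,
                label=f"{g}{'+' if a.charge > 0 else '-'}",
                theoretical_mz=mz,
                mass_error_mda=(peak.mz - mz) * 1000.0,
                ion_formula=g,
                radical=radical,
            )
            options.append((abs(peak.mz - mz), int(radical), g.atom_count, ann))
        # (b) adduct / isotope ions of the intact molecule
        for label, mz in candidate_ions:
            if abs(peak.mz - mz) > tol:
                continue
            if "[13C" in label:
                kind = "isotope"
            elif abs(mz - precursor_mz_theo) < 1e-9:
                kind = "precursor"
            else:
                kind = "adduct"
            ann = PeakAnnotation(
                kind=kind,
                label=label,
                theoretical_mz=mz,
                mass_error_mda=(peak.mz - mz) * 1000.0,
                ion_formula=None,
            )
            options.append((abs(peak.mz - mz), 0, f.atom_count, ann))
        if options:
            options.sort(key=lambda t: (round(t[0], 9), t[1], t[2], t[3].label))
            annotated.append(replace(peak, annotation=options[0][3]))
        else:
            annotated.append(replace(peak, annotation=None))
    return s.with_peaks(annotated)


def strip_unannotated(s: Spectrum) -> Spectrum:
    """Keep exactly the annotated peaks, preserving order."""
    return s.with_peaks(p for p in s.peaks if p.annotation is not None)
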