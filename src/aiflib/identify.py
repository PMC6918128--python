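"""AMRT+MS2 identification of query features against a curated library.

A feature matches a record when both the accurate mass (default ±0.01 Th)
and the corrected retention time (default ±0.7 min) agree; the MS2 dot
product over shared collision energies then decides between a full
AMRT+MS2 identification and an AMRT-only candidate. Confidence labels
follow the Metabolomics Standards Initiative convention: level 1 only
when the standards were analyzed in the same analytical batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .librarian import dot_product
from .spectra import LibraryRecord, Spectrum

__all__ = [
    "QueryFeature",
    "MatchResult",
    "find_amrt_matches",
    "score_matches",
    "assign_level",
    "results_table",
]

#: (accepted, same_batch) -> label; override via assign_level's policy arg.
DEFAULT_LEVEL_POLICY: dict[tuple[bool, bool], str] = {
    (True, True): "level-1",
    (True, False): "level-2 (AMRT+MS2)",
    (False, True): "level-2 (AMRT)",
    (False, False): "level-2 (AMRT)",
}


@dataclass
class QueryFeature:
    """A detected feature in a query run, with deconvoluted MS2 per channel."""

    feature_id: str
    mz: float
    rt: float  # corrected, minutes
    height: float
    ms2: Mapping[float, Spectrum] = field(default_factory=dict)


@dataclass
class MatchResult:
    feature: QueryFeature
    record: LibraryRecord
    mass_error_mda: float
    rt_error: float
    similarities: dict[float, float] = field(default_factory=dict)
    accepted: bool = False
    reason: str = ""
    level: str = ""
    best: bool = False

    @property
    def max_similarity(self) -> float:
        return max(self.similarities.values(), default=0.0)


def find_amrt_matches(
    features: Sequence[QueryFeature],
    lib: Sequence[LibraryRecord],
    mz_tol: float = 0.01,
    rt_tol: float = 0.7,
) -> list[MatchResult]:
    """All (feature, record) pairs inside both the m/z and RT windows.

    No bijection is forced: one feature may match several records and a
    record several features; MS2 scoring disambiguates afterwards.
    """
    if mz_tol <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be > 0")
    out: list[MatchResult] = []
    for f in features:
        for rec in lib:
            d_mz = f.mz - rec.precursor_mz
            d_rt = f.rt - rec.rt
            if abs(d_mz) <= mz_tol and abs(d_rt) <= rt_tol:
                out.append(
                    MatchResult(
                        feature=f,
                        record=rec,
                        mass_error_mda=d_mz * 1000.0,
                        rt_error=d_rt,
                    )
                )
    return out


def score_matches(
    candidates: Sequence[MatchResult],
    bin_tol: float = 0.01,
    ms2_threshold: float = 70.0,
) -> list[MatchResult]:
    """Score AMRT candidates by MS2 similarity per shared collision energy.

    A candidate is accepted when its best per-energy dot product reaches
    ``ms2_threshold`` percent; rejected candidates are retained with
    reason "AMRT-only" (including features with no query MS2 at all).
    Among several accepted records for one feature the best —
    (similarity, -|rt error|, -|mass error|) — is flagged.
    """
    scored: list[MatchResult] = []
    for m in candidates:
        sims: dict[float, float] = {}
        rec_ce = m.record.collision_energy
        for energy, spec in m.feature.ms2.items():
            if energy == rec_ce and len(spec) and len(m.record.spectrum):
                sims[energy] = dot_product(spec, m.record.spectrum, bin_tol)
        m.similarities = sims
        if sims and max(sims.values()) >= ms2_threshold:
            m.accepted = True
            m.reason = "AMRT+MS2"
        else:
            m.accepted = False
            # no scorable query MS2 at all -> low-confidence AMRT-only
            m.reason = "AMRT-only" if sims else "AMRT-only (no MS2)"
        scored.append(m)
    # flag the best accepted record per feature
    by_feature: dict[str, list[MatchResult]] = {}
    for m in scored:
        by_feature.setdefault(m.feature.feature_id, []).append(m)
    for group in by_feature.values():
        accepted = [m for m in group if m.accepted]
        if accepted:
            best = max(
                accepted,
                key=lambda m: (m.max_similarity, -abs(m.rt_error), -abs(m.mass_error_mda)),
            )
            best.best = True
    return scored


def assign_level(
    m: MatchResult,
    same_batch: bool,
    policy: Mapping[tuple[bool, bool], str] = DEFAULT_LEVEL_POLICY,
) -> str:
    """MSI-style confidence label for a scored match (policy overridable)."""
    m.level = policy[(m.accepted, same_batch)]
    return m.level


def results_table(matches: Sequence[MatchResult]) -> pd.DataFrame:
    """Flatten match results into the delimited annotation table."""
    rows = []
    for m in matches:
        rows.append(
            {
                "feature_id": m.feature.feature_id,
                "feature_mz": m.feature.mz,
                "feature_rt": m.feature.rt,
                "compound": m.record.name,
                "adduct": m.record.adduct.name if m.record.adduct else "",
                "collision_energy": m.record.collision_energy,
                "mass_error_mda": m.mass_error_mda,
                "rt_error_min": m.rt_error,
                "max_similarity": m.max_similarity,
                "accepted": m.accepted,
                "reason": m.reason,
                "level": m.level,
                "best": m.best,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id",
            "feature_mz",
            "feature_rt",
            "compound",
            "adduct",
            "collision_energy",
            "mass_error_mda",
            "rt_error_min",
            "max_similarity",
            "accepted",
            "reason",
            "level",
            "best",
        ],
    )
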