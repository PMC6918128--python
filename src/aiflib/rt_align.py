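"""Retention-time correction anchored on technical internal standards (tIS).

HILIC retention times drift between injections; a handful of standards
spiked into every sample pin the observed gradient to a reference one.
The correction is piecewise linear between consecutive anchors and a
constant offset beyond the first/last anchor — deliberately coarse, so
an anchor lost to ion suppression degrades gracefully.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .chem import AdductDescriptor, ElementalFormula, adduct_mz

logger = logging.getLogger(__name__)

__all__ = ["TISAnchor", "RTMap", "build_rt_map", "correct_rt", "rt_deviation_stats",
           "locate_anchors"]


@dataclass(frozen=True)
class TISAnchor:
    """A tIS compound with its reference RT and (optionally) the RT
    observed in a particular run. ``observed_rt`` None means the anchor
    was not detected there (e.g. suppressed by a coeluting analyte)."""

    name: str
    reference_rt: float
    formula: Optional[ElementalFormula] = None
    adduct: Optional[AdductDescriptor] = None
    observed_rt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.reference_rt <= 0:
            raise ValueError(f"anchor {self.name!r}: reference RT must be > 0")

    @property
    def mz(self) -> float:
        if self.formula is None or self.adduct is None:
            raise ValueError(f"anchor {self.name!r} has no formula/adduct")
        return adduct_mz(self.formula, self.adduct)


@dataclass(frozen=True)
class RTMap:
    """Monotone observed→reference RT map over matched anchor pairs."""

    observed: tuple[float, ...]
    reference: tuple[float, ...]

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, float)
        ref = np.asarray(self.reference, float)
        if obs.size != ref.size or obs.size < 2:
            raise ValueError("RTMap needs >= 2 matched anchor pairs")
        if np.any(np.diff(obs) <= 0):
            raise ValueError("observed anchor RTs must be strictly increasing")
        if np.any(np.diff(ref) <= 0):
            raise ValueError("reference anchor RTs must be strictly increasing")

    def __len__(self) -> int:
        return len(self.observed)


def build_rt_map(
    reference: Sequence[TISAnchor], observed: Sequence[TISAnchor]
) -> RTMap:
    """Pair reference and observed anchors by compound name.

    Anchors missing from the observed list (or without an observed RT —
    ion suppression) are dropped with a warning. Fewer than two usable
    pairs, or a non-monotone observed sequence, is an error naming the
    offending anchors.
    """
    obs_by_name = {a.name: a for a in observed}
    pairs: list[tuple[float, float, str]] = []
    for ref in sorted(reference, key=lambda a: a.reference_rt):
        obs = obs_by_name.get(ref.name)
        if obs is None or obs.observed_rt is None:
            logger.warning(
                "tIS anchor %r has no observed detection; dropped from RT map",
                ref.name,
            )
            continue
        pairs.append((obs.observed_rt, ref.reference_rt, ref.name))
    if len(pairs) < 2:
        raise ValueError(
            f"need >= 2 usable tIS anchors to build an RT map, got {len(pairs)}"
        )
    obs_rts = [p[0] for p in pairs]
    if any(b <= a for a, b in zip(obs_rts, obs_rts[1:])):
        bad = [
            f"{pairs[i][2]}({pairs[i][0]:.2f}) >= {pairs[i + 1][2]}({pairs[i + 1][0]:.2f})"
            for i in range(len(pairs) - 1)
            if pairs[i + 1][0] <= pairs[i][0]
        ]
        raise ValueError(
            "observed anchor RTs are not monotone in reference order: " + "; ".join(bad)
        )
    return RTMap(
        observed=tuple(p[0] for p in pairs), reference=tuple(p[1] for p in pairs)
    )


def correct_rt(m: RTMap, rt: float) -> float:
    """Map an observed RT onto the reference time axis.

    Exact at anchors, linear between them, constant offset of the nearest
    anchor outside the span. Monotone non-decreasing pointwise.
    """
    if np.ndim(rt) == 0 and rt < 0:
        raise ValueError(f"retention time must be >= 0, got {rt}")
    obs = np.asarray(m.observed)
    ref = np.asarray(m.reference)
    if rt <= obs[0]:
        return float(rt + (ref[0] - obs[0]))
    if rt >= obs[-1]:
        return float(rt + (ref[-1] - obs[-1]))
    return float(np.interp(rt, obs, ref))


def rt_deviation_stats(rts: Sequence[float]) -> tuple[float, float, float]:
    """Cross-run RT spread: (mean, max |rt - mean|, CV%).

    CV% uses the sample (n-1) standard deviation, appropriate for the
    handful of injections a characterization campaign produces.
    """
    arr = np.asarray(rts, float)
    if arr.size < 2:
        raise ValueError("need at least 2 retention times")
    mean = float(arr.mean())
    max_dev = float(np.max(np.abs(arr - mean)))
    cv = float(100.0 * arr.std(ddof=1) / mean) if mean != 0 else float("nan")
    return mean, max_dev, cv


def locate_anchors(run, anchors: Sequence[TISAnchor], *, mz_tol: float = 0.01,
                   search_window: float = 1.5, min_height: float = 0.0,
                   channel: float = 0.0) -> list[TISAnchor]:
    """Find each tIS in a run: apex of the most intense EIC peak within
    ``search_window`` minutes of its reference RT (full-scan channel).

    Returns new anchors with ``observed_rt`` filled (None if undetected).
    """
    from .deconv import detect_peaks, extract_eic  # local import: avoid cycle

    located: list[TISAnchor] = []
    for a in anchors:
        eic = extract_eic(run, channel, a.mz, mz_tol)
        peaks = [
            p
            for p in detect_peaks(eic, min_height)
            if abs(p.apex_rt - a.reference_rt) <= search_window
        ]
        best = max(peaks, key=lambda p: p.height, default=None)
        located.append(
            TISAnchor(
                name=a.name,
                reference_rt=a.reference_rt,
                formula=a.formula,
                adduct=a.adduct,
                observed_rt=None if best is None else best.apex_rt,
            )
        )
    return located
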