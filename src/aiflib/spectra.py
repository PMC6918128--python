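"""In-memory containers: peaks, spectra, library records and AIF scan cycles.

Retention times are minutes everywhere; m/z is in Th; intensities are
arbitrary detector units. An AIF run is a sequence of cycles, each cycle
holding one centroided scan per collision-energy channel (full scan,
10 eV, 30 eV by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np

from .chem import AdductDescriptor, ElementalFormula, InChIKeyText

__all__ = [
    "PeakAnnotation",
    "Peak",
    "Spectrum",
    "LibraryRecord",
    "Scan",
    "Cycle",
    "AIFRun",
]

AnnotationKind = Literal["fragment", "adduct", "isotope", "precursor"]


@dataclass(frozen=True)
class PeakAnnotation:
    """Interpretation of one MS2 peak as a fragment, adduct or isotope ion.

    ``mass_error_mda`` is (observed - theoretical) in millidaltons.
    ``radical`` marks odd-electron fragment ions (penalized on ties).
    """

    kind: AnnotationKind
    label: str
    theoretical_mz: float
    mass_error_mda: float
    ion_formula: Optional[ElementalFormula] = None
    radical: bool = False

    def comment_text(self) -> str:
        """Compact text form stored in the MSP peak-comment column."""
        parts = [self.label, self.kind]
        if self.radical:
            parts.append("radical")
        return "; ".join(parts)


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    annotation: Optional[PeakAnnotation] = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class Spectrum:
    """An ordered (ascending m/z) centroid peak list with acquisition context."""

    peaks: tuple[Peak, ...]
    precursor_mz: float = 0.0
    collision_energy: float = 0.0
    rt: float = 0.0
    ion_mode: Literal["positive", "negative"] = "positive"

    def __post_init__(self) -> None:
        pk = tuple(sorted(self.peaks, key=lambda p: p.mz))
        object.__setattr__(self, "peaks", pk)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    @property
    def base_peak(self) -> Optional[Peak]:
        if not self.peaks:
            return None
        return max(self.peaks, key=lambda p: p.intensity)

    def normalized(self, base: float = 100.0) -> "Spectrum":
        """Rescale so the base peak equals ``base`` (no-op on empty input)."""
        bp = self.base_peak
        if bp is None or bp.intensity == 0:
            return self
        k = base / bp.intensity
        return replace(
            self,
            peaks=tuple(replace(p, intensity=p.intensity * k) for p in self.peaks),
        )

    def with_peaks(self, peaks: Iterable[Peak]) -> "Spectrum":
        return replace(self, peaks=tuple(peaks))


@dataclass
class LibraryRecord:
    """One MSP record: a spectrum plus accurate-mass / RT / identity metadata.

    After curation ``theoretical_precursor_mz`` equals adduct_mz(formula,
    adduct) and the original experimental reading is retained in
    ``experimental_precursor_mz`` (serialized into the COMMENT field).
    """

    name: str
    spectrum: Spectrum
    formula: Optional[ElementalFormula] = None
    adduct: Optional[AdductDescriptor] = None
    inchikey: Optional[InChIKeyText] = None
    smiles: str = ""
    theoretical_precursor_mz: float = 0.0
    experimental_precursor_mz: float = 0.0
    rt: float = 0.0
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def precursor_mz(self) -> float:
        return self.theoretical_precursor_mz or self.experimental_precursor_mz

    @property
    def collision_energy(self) -> float:
        return self.spectrum.collision_energy


@dataclass(frozen=True)
class Scan:
    """One centroided scan: arrays of m/z and intensity at one time point."""

    time: float  # minutes
    energy: float  # collision energy, eV
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError("mz and intensity arrays differ in length")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])


@dataclass(frozen=True)
class Cycle:
    """One acquisition cycle: one scan per collision-energy channel."""

    scans: Mapping[float, Scan]

    @property
    def time(self) -> float:
        """Cycle time = time of its earliest scan."""
        return min(s.time for s in self.scans.values())


@dataclass
class AIFRun:
    """A full AIF acquisition: ordered cycles over fixed energy channels."""

    cycles: list[Cycle]
    channel_energies: tuple[float, ...] = (0.0, 10.0, 30.0)
    mass_range: tuple[float, float] = (40.0, 1200.0)
    run_id: str = ""

    def __post_init__(self) -> None:
        chans = set(self.channel_energies)
        prev = -np.inf
        for i, c in enumerate(self.cycles):
            missing = chans - set(c.scans)
            if missing:
                raise ValueError(
                    f"cycle {i} is missing channel(s) {sorted(missing)}"
                )
            if c.time <= prev:
                raise ValueError(f"cycle times not strictly increasing at cycle {i}")
            prev = c.time

    def __len__(self) -> int:
        return len(self.cycles)

    def channel_times(self, energy: float) -> np.ndarray:
        """Scan times (minutes) of one channel across all cycles."""
        self._check_channel(energy)
        return np.array([c.scans[energy].time for c in self.cycles])

    def channel_scans(self, energy: float) -> list[Scan]:
        self._check_channel(energy)
        return [c.scans[energy] for c in self.cycles]

    def channel_index(self, energy: float):
        """Cached flat view of one channel: (sorted m/z, intensities,
        scan row per centroid, scan times). Built once per channel; used
        for fast EIC extraction. The run must not be mutated afterwards."""
        cache = self.__dict__.setdefault("_channel_index_cache", {})
        if energy not in cache:
            scans = self.channel_scans(energy)
            parts_mz = [s.mz for s in scans if s.mz.size]
            if parts_mz:
                mz = np.concatenate(parts_mz)
                inten = np.concatenate([s.intensity for s in scans if s.mz.size])
                rows = np.concatenate(
                    [np.full(s.mz.size, i, dtype=np.int64)
                     for i, s in enumerate(scans) if s.mz.size]
                )
            else:
                mz = np.array([])
                inten = np.array([])
                rows = np.array([], dtype=np.int64)
            order = np.argsort(mz, kind="stable")
            times = np.array([s.time for s in scans])
            cache[energy] = (mz[order], inten[order], rows[order], times)
        return cache[energy]

    def _check_channel(self, energy: float) -> None:
        if energy not in self.channel_energies:
            raise KeyError(
                f"no channel at {energy} eV; available: {self.channel_energies}"
            )
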