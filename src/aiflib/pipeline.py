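"""End-to-end chains: characterize a campaign into a library, curate a
library, and identify features in a query run.

The characterization chain per compound series: locate tIS anchors and
build the RT correction, pick a representative non-saturated run (apex
in the 1e4–1e6 counts window), deconvolute with both the least-squares
and the correlation method at every collision energy, drop sub-1%%
peaks, annotate against the known formula, strip unannotated peaks, and
replace the experimental precursor m/z with the theoretical value.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import annotate as ann
from . import deconv, librarian
from .chem import adduct_mz, parse_adduct, InChIKeyText
from .identify import MatchResult, QueryFeature, assign_level, find_amrt_matches, score_matches
from .rt_align import RTMap, TISAnchor, build_rt_map, correct_rt, locate_anchors
from .spectra import AIFRun, LibraryRecord, Spectrum
from .synthgen import Campaign, SyntheticCompound

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "characterize_campaign", "curate_library", "identify_run"]


@dataclass
class PipelineConfig:
    """Every numeric knob of the pipeline, with the defaults used
    throughout: ±0.01 Th mass windows, ±0.7 min identification RT window,
    1-minute grouping RT window, a 4-sample minimum for correlation
    deconvolution, and a 1%% relative-intensity floor."""

    mz_tol: float = 0.01            # Th; EIC extraction and AMRT matching
    bin_tol: float = 0.01           # Th; fragment binning and spectral matching
    rt_tol: float = 0.7             # min; AMRT identification window
    group_rt_window: float = 1.0    # min; library-group RT consistency
    anchor_search_window: float = 1.5  # min; tIS location around reference RT
    min_samples: int = 4            # runs above noise required by corrdec
    r_threshold: float = 0.90       # Pearson r to keep a corrdec fragment
    noise_level: float = 1000.0     # units; corrdec precursor noise floor
    ms2_threshold: float = 70.0     # %; dot product to accept AMRT+MS2
    annotation_tol: float = 0.01    # Th; fragment-annotation window
    relative_intensity_threshold: float = 1.0  # %; small-peak removal
    feature_min_height: float = 2000.0  # units; query feature detection
    representative_window: tuple[float, float] = (1.0e4, 1.0e6)
    collision_energies: tuple[float, ...] = (0.0, 10.0, 30.0)
    same_batch: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mz_tol", "bin_tol", "rt_tol", "group_rt_window",
                     "annotation_tol", "anchor_search_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_samples < 2:
            raise ValueError("min_samples must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        for key in ("representative_window", "collision_energies"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["representative_window"] = list(self.representative_window)
        data["collision_energies"] = list(self.collision_energies)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _rt_map_for_run(
    run: AIFRun, anchors: Sequence[TISAnchor], config: PipelineConfig
) -> RTMap:
    observed = locate_anchors(
        run,
        anchors,
        mz_tol=config.mz_tol,
        search_window=config.anchor_search_window,
    )
    return build_rt_map(anchors, observed)


def _pick_representative(
    runs: Sequence[AIFRun], heights: Sequence[float], window: tuple[float, float]
) -> int:
    """Index of the run whose precursor apex is highest inside the
    non-saturated window; falls back to the highest apex overall."""
    best, best_h = -1, -1.0
    for i, h in enumerate(heights):
        if window[0] <= h <= window[1] and h > best_h:
            best, best_h = i, h
    if best >= 0:
        return best
    return int(np.argmax(heights))


def _finish_record(
    spec: Spectrum,
    comp: SyntheticCompound,
    method: str,
    rt: float,
    config: PipelineConfig,
    counts: dict,
) -> Optional[LibraryRecord]:
    adduct = parse_adduct(comp.primary_adduct)
    filtered = deconv.filter_relative_intensity(
        spec, config.relative_intensity_threshold
    )
    annotated = ann.annotate_fragments(
        filtered, comp.formula, adduct, config.annotation_tol
    )
    stripped = ann.strip_unannotated(annotated)
    counts["raw"] = len(spec)
    counts["filtered"] = len(filtered)
    counts["stripped"] = len(stripped)
    if not stripped.peaks:
        return None
    # observed precursor reading, if the precursor ion survived curation
    experimental = 0.0
    for p in stripped.peaks:
        if p.annotation is not None and p.annotation.kind == "precursor":
            experimental = p.mz
            break
    observed_precursor = experimental or adduct_mz(comp.formula, adduct)
    record = LibraryRecord(
        name=comp.name,
        # pre-curation, the precursor slot holds the observed reading;
        # replace_precursor_mz moves it aside and installs the theoretical value
        spectrum=Spectrum(
            peaks=stripped.normalized().peaks,
            precursor_mz=observed_precursor,
            collision_energy=spec.collision_energy,
            rt=rt,
            ion_mode="positive",
        ),
        formula=comp.formula,
        adduct=adduct,
        inchikey=InChIKeyText(comp.inchikey),
        smiles=comp.smiles,
        theoretical_precursor_mz=observed_precursor,
        rt=rt,
        provenance={"METHOD": method},
    )
    return librarian.replace_precursor_mz(record)


def characterize_campaign(
    campaign: Campaign, config: PipelineConfig
) -> tuple[list[LibraryRecord], list[dict]]:
    """Build library records from a characterization campaign.

    Returns (records, stage log). One record per compound × method ×
    collision energy; the correlation method is skipped (and logged) for
    series with fewer than ``min_samples`` above-noise runs.
    """
    records: list[LibraryRecord] = []
    log: list[dict] = []
    for name, runs in campaign.series.items():
        comp = campaign.compounds[name]
        precursor_mz = comp.precursor_mz
        maps = [_rt_map_for_run(run, campaign.tis, config) for run in runs]

        peaks_per_run = []
        heights = []
        for run in runs:
            eic = deconv.extract_eic(run, 0.0, precursor_mz, config.mz_tol)
            det = deconv.detect_peaks(eic)
            best = max(det, key=lambda p: p.height, default=None)
            peaks_per_run.append(best)
            heights.append(best.height if best is not None else 0.0)
        if all(h == 0 for h in heights):
            log.append({"compound": name, "stage": "precursor", "error": "not detected"})
            logger.warning("%s: precursor %0.4f never detected", name, precursor_mz)
            continue

        rep = _pick_representative(runs, heights, config.representative_window)
        rep_peak = peaks_per_run[rep]
        rep_rt = correct_rt(maps[rep], rep_peak.apex_rt)

        for energy in config.collision_energies:
            entry = {
                "compound": name,
                "energy": energy,
                "representative_run": runs[rep].run_id,
                "rt": rep_rt,
            }
            # within-run least squares on the representative run
            ms2dec_spec = deconv.ms2dec(
                runs[rep], precursor_mz, rep_peak, energy, mz_tol=config.bin_tol
            )
            counts: dict = {}
            rec = _finish_record(ms2dec_spec, comp, "ms2dec", rep_rt, config, counts)
            entry["ms2dec_peaks"] = counts
            if rec is not None:
                records.append(rec)
            # cross-sample correlation over the dilution series
            corr_spec = deconv.corrdec(
                runs,
                precursor_mz,
                energy,
                config.noise_level,
                min_samples=config.min_samples,
                r_threshold=config.r_threshold,
                mz_tol=config.bin_tol,
            )
            if corr_spec is None:
                entry["corrdec"] = "declined (<{} above-noise runs)".format(
                    config.min_samples
                )
                logger.info("%s @%g eV: corrdec declined", name, energy)
            else:
                counts = {}
                rec = _finish_record(corr_spec, comp, "corrdec", rep_rt, config, counts)
                entry["corrdec_peaks"] = counts
                if rec is not None:
                    records.append(rec)
            log.append(entry)
    return records, log


def curate_library(
    records: Sequence[LibraryRecord], config: PipelineConfig
) -> tuple[list[LibraryRecord], list[dict]]:
    """Batch curation: precursor m/z replacement plus group consistency flags."""
    curated = []
    for rec in records:
        if rec.formula is not None and rec.adduct is not None:
            curated.append(librarian.replace_precursor_mz(rec))
        else:
            curated.append(rec)
    report = []
    for g in librarian.group_records(curated):
        librarian.check_group_consistency(g, config.group_rt_window)
        if g.formula_mismatch or g.rt_spread_exceeded or g.missing_key:
            report.append(
                {
                    "key": g.key,
                    "n_records": len(g.records),
                    "formula_mismatch": g.formula_mismatch,
                    "rt_spread_exceeded": g.rt_spread_exceeded,
                    "missing_inchikey": g.missing_key,
                }
            )
    return curated, report


def identify_run(
    run: AIFRun,
    library: Sequence[LibraryRecord],
    config: PipelineConfig,
    tis_anchors: Sequence[TISAnchor] = (),
) -> tuple[list[QueryFeature], list[MatchResult]]:
    """Targeted AMRT+MS2 identification against the library precursors.

    Features are chromatographic peaks in the EIC of each distinct
    library precursor m/z; their retention times are corrected with the
    supplied tIS anchors before matching.
    """
    rt_map = _rt_map_for_run(run, tis_anchors, config) if len(tis_anchors) >= 2 else None

    # distinct precursor targets
    targets: list[float] = []
    for rec in library:
        mz = rec.precursor_mz
        if not any(abs(mz - t) <= config.mz_tol for t in targets):
            targets.append(mz)

    features: list[QueryFeature] = []
    ms2_channels = [e for e in config.collision_energies if e != 0.0]
    for mz in targets:
        eic = deconv.extract_eic(run, 0.0, mz, config.mz_tol)
        for peak in deconv.detect_peaks(eic, config.feature_min_height):
            ms2 = {}
            for energy in ms2_channels:
                spec = deconv.ms2dec(run, mz, peak, energy, mz_tol=config.bin_tol)
                ms2[energy] = deconv.filter_relative_intensity(
                    spec, config.relative_intensity_threshold
                )
            rt = correct_rt(rt_map, peak.apex_rt) if rt_map is not None else peak.apex_rt
            features.append(
                QueryFeature(
                    feature_id=f"mz{mz:.4f}@{rt:.2f}",
                    mz=mz,
                    rt=rt,
                    height=peak.height,
                    ms2=ms2,
                )
            )

    candidates = find_amrt_matches(features, library, config.mz_tol, config.rt_tol)
    results = score_matches(candidates, config.bin_tol, config.ms2_threshold)
    for m in results:
        assign_level(m, config.same_batch)
    return features, results
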