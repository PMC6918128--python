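"""MS2 spectral deconvolution for all-ion-fragmentation data.

AIF fragments every precursor at once, so a raw MS2 scan is a cumulative
spectrum of everything eluting at that moment. Two complementary
strategies assign fragments to their precursor:

* within-run least squares (:func:`ms2dec`): each fragment bin's
  chromatogram inside the precursor's elution window is fitted as a
  non-negative combination of the precursor's elution profile,
  profiles of interfering peaks with different apexes, and a constant
  baseline — the coefficient on the precursor profile is the
  deconvoluted intensity;
* cross-sample correlation (:func:`corrdec`): over a dilution series,
  true fragments scale with the precursor's apex height across samples
  (Pearson r), while contaminants present at constant intensity do not.
  Requires at least ``min_samples`` samples above the noise level
  (default 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import nnls
from scipy.signal import find_peaks

from .spectra import AIFRun, Peak, Spectrum

__all__ = [
    "EIC",
    "DetectedPeak",
    "DeconvolutedSpectrum",
    "extract_eic",
    "detect_peaks",
    "ms2dec",
    "corrdec",
    "average_raw_ms2",
    "filter_relative_intensity",
]


@dataclass(frozen=True)
class EIC:
    """Extracted ion chromatogram: intensity vs time at target_mz ± tolerance."""

    target_mz: float
    tolerance: float
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        y = np.asarray(self.intensities, float)
        if t.shape != y.shape:
            raise ValueError("times and intensities differ in length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("EIC times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class DetectedPeak:
    """A chromatographic peak: apex, height, area and integration bounds."""

    apex_rt: float
    height: float
    area: float
    left: float
    right: float
    apex_index: int = 0

    def __post_init__(self) -> None:
        if not (self.left < self.apex_rt < self.right):
            raise ValueError(
                f"peak bounds must bracket the apex: {self.left} < {self.apex_rt} < {self.right}"
            )
        if self.height <= 0:
            raise ValueError("peak height must be > 0")


@dataclass(frozen=True)
class DeconvolutedSpectrum(Spectrum):
    """A deconvoluted MS2 spectrum with per-peak quality diagnostics.

    ``qualities`` aligns with ``peaks``: for the least-squares method it
    is the fraction of the bin's signal explained by the precursor
    component (0..1); for the correlation method it is Pearson r (-1..1).
    """

    method: str = "least-squares"
    qualities: tuple[float, ...] = ()
    apex_rt: float = 0.0

    def with_peaks(self, peaks):
        from dataclasses import replace

        peaks = tuple(peaks)
        qmap = {p.mz: q for p, q in zip(self.peaks, self.qualities)}
        return replace(
            self, peaks=peaks, qualities=tuple(qmap.get(p.mz, 0.0) for p in peaks)
        )


def extract_eic(run: AIFRun, channel: float, mz: float, tol: float) -> EIC:
    """Per-scan summed centroid intensity within ``mz ± tol`` in one channel."""
    if tol <= 0:
        raise ValueError(f"EIC tolerance must be > 0, got {tol}")
    mz_all, in_all, rows, times = run.channel_index(channel)  # KeyError if absent
    a = np.searchsorted(mz_all, mz - tol, side="left")
    b = np.searchsorted(mz_all, mz + tol, side="right")
    inten = np.zeros(times.size)
    if b > a:
        np.add.at(inten, rows[a:b], in_all[a:b])
    return EIC(target_mz=mz, tolerance=tol, times=times, intensities=inten)


def _smooth3(y: np.ndarray) -> np.ndarray:
    """3-point moving average with edge preservation."""
    if y.size < 3:
        return y.copy()
    out = y.copy()
    out[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    return out


def detect_peaks(e: EIC, min_height: float = 0.0) -> list[DetectedPeak]:
    """Local maxima of the lightly smoothed trace, with valley/baseline bounds.

    Peaks narrower than 3 scans or below ``min_height`` (raw apex
    intensity) are excluded.
    """
    if min_height < 0:
        raise ValueError("min_height must be >= 0")
    y = np.asarray(e.intensities, float)
    if y.size < 3 or not np.any(y > 0):
        return []
    ys = _smooth3(y)
    idx, _ = find_peaks(ys, height=max(min_height * 0.5, np.max(ys) * 1e-6))
    out: list[DetectedPeak] = []
    for i in idx:
        # refine apex on the raw trace near the smoothed maximum
        lo_i = max(i - 1, 0)
        hi_i = min(i + 2, y.size)
        apex = lo_i + int(np.argmax(y[lo_i:hi_i]))
        height = float(y[apex])
        if height < min_height or height <= 0:
            continue
        baseline = 0.02 * height
        left = apex
        while left > 0 and ys[left - 1] < ys[left] and y[left - 1] > baseline:
            left -= 1
        right = apex
        while right < y.size - 1 and ys[right + 1] < ys[right] and y[right + 1] > baseline:
            right += 1
        if left > 0:
            left -= 1  # include the valley/baseline point itself
        if right < y.size - 1:
            right += 1
        if right - left + 1 < 3:
            continue
        area = float(np.trapezoid(y[left : right + 1], e.times[left : right + 1]))
        out.append(
            DetectedPeak(
                apex_rt=float(e.times[apex]),
                height=height,
                area=area,
                left=float(e.times[left]),
                right=float(e.times[right]),
                apex_index=apex,
            )
        )
    # deduplicate plateaus: keep the taller of peaks closer than 3 scans
    out.sort(key=lambda p: p.apex_index)
    dedup: list[DetectedPeak] = []
    for p in out:
        if dedup and p.apex_index - dedup[-1].apex_index < 3:
            if p.height > dedup[-1].height:
                dedup[-1] = p
        else:
            dedup.append(p)
    return dedup


def _cluster_mz(
    mzs: np.ndarray, weights: np.ndarray, tol: float
) -> list[float]:
    """Cluster sorted m/z values into bins split at gaps > tol; returns
    intensity-weighted bin centers."""
    if mzs.size == 0:
        return []
    order = np.argsort(mzs)
    mz_s, w_s = mzs[order], weights[order]
    splits = np.nonzero(np.diff(mz_s) > tol)[0] + 1
    centers = []
    for seg_mz, seg_w in zip(np.split(mz_s, splits), np.split(w_s, splits)):
        wsum = seg_w.sum()
        centers.append(float(np.average(seg_mz, weights=seg_w) if wsum > 0 else seg_mz.mean()))
    return centers


def _is_saturated(profile: np.ndarray) -> bool:
    """Detect hard clipping: >= 3 consecutive samples at the maximum."""
    if profile.size < 3 or profile.max() <= 0:
        return False
    at_max = profile >= profile.max() * (1 - 1e-9)
    run = best = 0
    for flag in at_max:
        run = run + 1 if flag else 0
        best = max(best, run)
    return best >= 3


def _gaussian_profile(times: np.ndarray, apex_rt: float, left: float, right: float) -> np.ndarray:
    sigma = max((right - left) / 4.0, 1e-6)
    return np.exp(-0.5 * ((times - apex_rt) / sigma) ** 2)


def ms2dec(
    run: AIFRun,
    precursor_mz: float,
    precursor: DetectedPeak,
    channel: float,
    *,
    precursor_channel: float = 0.0,
    mz_tol: float = 0.01,
    min_apex_sep_scans: int = 3,
) -> DeconvolutedSpectrum:
    """Within-run least-squares deconvolution at one collision energy.

    For every fragment m/z bin with signal inside the precursor's
    boundaries, the bin's chromatogram segment is fitted (non-negative
    least squares) as precursor profile + interferent profiles + constant
    baseline. Interferents are peaks detected in the bin's own full EIC
    whose apex differs from the precursor apex by at least
    ``min_apex_sep_scans`` scans; overlapping interferents are merged,
    keeping the taller. Bins with a zero precursor coefficient are
    omitted. The precursor profile falls back to a Gaussian when the
    full-scan EIC is saturated (clipped flat top).
    """
    pre_eic = extract_eic(run, precursor_channel, precursor_mz, mz_tol)
    times = pre_eic.times
    in_win = (times >= precursor.left) & (times <= precursor.right)
    win_idx = np.nonzero(in_win)[0]
    if win_idx.size == 0:
        raise ValueError("precursor boundaries contain no scans")

    profile = pre_eic.intensities[win_idx].astype(float)
    if _is_saturated(profile):
        profile = _gaussian_profile(times[win_idx], precursor.apex_rt,
                                    precursor.left, precursor.right)
    if profile.max() <= 0:
        raise ValueError("precursor has no signal inside its boundaries")
    profile = profile / profile.max()

    # collect fragment bins present in the MS2 channel inside the window
    chan_scans = run.channel_scans(channel)
    frag_scans = [chan_scans[i] for i in win_idx]
    all_mz = np.concatenate([s.mz for s in frag_scans]) if frag_scans else np.array([])
    all_w = np.concatenate([s.intensity for s in frag_scans]) if frag_scans else np.array([])
    bins = _cluster_mz(all_mz, all_w, mz_tol)

    peaks: list[Peak] = []
    qualities: list[float] = []
    scan_dt = float(np.median(np.diff(times))) if times.size > 1 else 0.0
    for bin_mz in bins:
        frag_eic = extract_eic(run, channel, bin_mz, mz_tol)
        y = frag_eic.intensities[win_idx]
        if not np.any(y > 0):
            continue
        columns = [profile]
        interferents = [
            p
            for p in detect_peaks(frag_eic)
            if abs(p.apex_rt - precursor.apex_rt) > min_apex_sep_scans * scan_dt
        ]
        # merge interferents whose apexes nearly coincide; keep the taller
        interferents.sort(key=lambda p: p.apex_rt)
        merged: list[DetectedPeak] = []
        for p in interferents:
            if merged and (p.apex_rt - merged[-1].apex_rt) <= min_apex_sep_scans * scan_dt:
                if p.height > merged[-1].height:
                    merged[-1] = p
            else:
                merged.append(p)
        for p in merged:
            columns.append(_gaussian_profile(times[win_idx], p.apex_rt, p.left, p.right))
        columns.append(np.ones_like(profile))  # constant baseline
        A = np.column_stack(columns)
        coef, _ = nnls(A, y)
        intensity = float(coef[0])  # profile is unit-height, so coef = apex share
        if intensity <= 0:
            continue
        explained = coef[0] * profile
        total = float(np.sum(y))
        quality = float(np.clip(np.sum(explained) / total, 0.0, 1.0)) if total > 0 else 0.0
        peaks.append(Peak(mz=bin_mz, intensity=intensity))
        qualities.append(quality)

    order = np.argsort([p.mz for p in peaks]) if peaks else []
    return DeconvolutedSpectrum(
        peaks=tuple(peaks[i] for i in order),
        precursor_mz=precursor_mz,
        collision_energy=channel,
        rt=precursor.apex_rt,
        method="least-squares",
        qualities=tuple(qualities[i] for i in order),
        apex_rt=precursor.apex_rt,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; NaN when either vector has zero variance."""
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def corrdec(
    series: Sequence[AIFRun],
    precursor_mz: float,
    channel: float,
    noise_level: float,
    *,
    min_samples: int = 4,
    r_threshold: float = 0.90,
    mz_tol: float = 0.01,
    precursor_channel: float = 0.0,
) -> Optional[DeconvolutedSpectrum]:
    """Cross-sample correlation deconvolution over a dilution series.

    Returns None (declined) when fewer than ``min_samples`` runs have the
    precursor above ``noise_level``. A fragment bin is kept when the
    Pearson correlation between its per-run apex height and the precursor
    apex height (over above-noise runs) reaches ``r_threshold``; its
    reported intensity is the through-origin regression slope, rescaled
    so the base peak is 100. Constant-intensity contaminants have zero
    variance across the series, so their correlation is undefined and
    they are excluded.
    """
    if len(series) < 2:
        raise ValueError("corrdec needs at least 2 runs")
    chans = {r.channel_energies for r in series}
    if len(chans) != 1:
        raise ValueError("runs have unequal channel structure")

    heights = np.zeros(len(series))
    windows: list[Optional[DetectedPeak]] = []
    for i, run in enumerate(series):
        eic = extract_eic(run, precursor_channel, precursor_mz, mz_tol)
        det = detect_peaks(eic)
        best = max(det, key=lambda p: p.height, default=None)
        windows.append(best)
        heights[i] = best.height if best is not None else 0.0

    above = heights > noise_level
    if int(above.sum()) < min_samples:
        return None

    # fragment bins: union of MS2 centroids inside each above-noise run's window
    mz_parts, w_parts = [], []
    for i, run in enumerate(series):
        if not above[i] or windows[i] is None:
            continue
        w = windows[i]
        chan_scans = run.channel_scans(channel)
        times = run.channel_times(channel)
        sel = (times >= w.left) & (times <= w.right)
        for j in np.nonzero(sel)[0]:
            s = chan_scans[j]
            mz_parts.append(s.mz)
            w_parts.append(s.intensity)
    if not mz_parts:
        return None
    bins = _cluster_mz(np.concatenate(mz_parts), np.concatenate(w_parts), mz_tol)

    h = heights[above]
    peaks: list[Peak] = []
    qualities: list[float] = []
    slopes: list[float] = []
    for bin_mz in bins:
        v = []
        for i, run in enumerate(series):
            if not above[i]:
                continue
            w = windows[i]
            eic = extract_eic(run, channel, bin_mz, mz_tol)
            sel = (eic.times >= w.left) & (eic.times <= w.right)
            v.append(float(eic.intensities[sel].max()) if np.any(sel) else 0.0)
        v = np.asarray(v)
        r = _pearson(v, h)
        if not np.isfinite(r) or r < r_threshold:
            continue
        slope = float(np.sum(v * h) / np.sum(h * h))
        if slope <= 0:
            continue
        peaks.append(Peak(mz=bin_mz, intensity=slope))
        qualities.append(r)
        slopes.append(slope)

    if peaks:
        base = max(slopes)
        peaks = [Peak(mz=p.mz, intensity=100.0 * p.intensity / base) for p in peaks]
    apex_rts = [w.apex_rt for w, a in zip(windows, above) if a and w is not None]
    order = np.argsort([p.mz for p in peaks]) if peaks else []
    return DeconvolutedSpectrum(
        peaks=tuple(peaks[i] for i in order),
        precursor_mz=precursor_mz,
        collision_energy=channel,
        rt=float(np.median(apex_rts)) if apex_rts else 0.0,
        method="correlation",
        qualities=tuple(qualities[i] for i in order),
        apex_rt=float(np.median(apex_rts)) if apex_rts else 0.0,
    )


def average_raw_ms2(
    run: AIFRun, channel: float, apex: float, window: float, *, mz_tol: float = 0.01
) -> Spectrum:
    """Mean centroid spectrum over scans within ``apex ± window`` minutes.

    Centroids are merged within ``mz_tol`` (intensity-weighted m/z);
    merged intensity is the summed intensity divided by the number of
    scans averaged.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    times = run.channel_times(channel)
    sel = np.nonzero(np.abs(times - apex) <= window)[0]
    if sel.size == 0:
        raise ValueError("no scans inside the averaging window")
    chan_scans = run.channel_scans(channel)
    scans = [chan_scans[i] for i in sel]
    mzs = np.concatenate([s.mz for s in scans])
    ws = np.concatenate([s.intensity for s in scans])
    if mzs.size == 0:
        return Spectrum(peaks=(), collision_energy=channel, rt=apex)
    order = np.argsort(mzs)
    mz_s, w_s = mzs[order], ws[order]
    splits = np.nonzero(np.diff(mz_s) > mz_tol)[0] + 1
    n = float(sel.size)
    peaks = []
    for seg_mz, seg_w in zip(np.split(mz_s, splits), np.split(w_s, splits)):
        total = seg_w.sum()
        if total <= 0:
            continue
        center = float(np.average(seg_mz, weights=seg_w))
        peaks.append(Peak(mz=center, intensity=float(total / n)))
    return Spectrum(peaks=tuple(peaks), collision_energy=channel, rt=apex)


def filter_relative_intensity(s: Spectrum, threshold_percent: float = 1.0) -> Spectrum:
    """Drop peaks below ``threshold_percent`` of the base peak (boundary kept)."""
    bp = s.base_peak
    if bp is None:
        return s
    cut = threshold_percent / 100.0 * bp.intensity
    kept = tuple(p for p in s.peaks if p.intensity >= cut)
    if isinstance(s, DeconvolutedSpectrum):
        q = {p.mz: q for p, q in zip(s.peaks, s.qualities)}
        return DeconvolutedSpectrum(
            peaks=kept,
            precursor_mz=s.precursor_mz,
            collision_energy=s.collision_energy,
            rt=s.rt,
            ion_mode=s.ion_mode,
            method=s.method,
            qualities=tuple(q[p.mz] for p in kept),
            apex_rt=s.apex_rt,
        )
    return s.with_peaks(kept)
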