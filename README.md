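# aiflib

Tools for building and applying **AMRT+MS2 spectral libraries** from
**all-ion-fragmentation (AIF)** LC–MS metabolomics data.

## The problem

In AIF (a data-independent acquisition mode), every ion entering the mass
spectrometer is fragmented together, so each MS2 scan is a cumulative
spectrum of everything co-eluting at that moment. That makes MS2 available
for virtually all ions — but the spectra must be *deconvoluted* before they
mean anything. On top of that, hydrophilic-interaction chromatography
(HILIC) retention times drift between injections, so a library built last
month may not match this week's run. Identifying a metabolite reliably
therefore needs three orthogonal properties — accurate mass (AM), a
drift-corrected retention time (RT), and a clean MS2 spectrum — and a
curated library that stores all three.

`aiflib` implements that workflow end to end for characterization campaigns
of chemical standards:

1. **Simulation** (`aiflib.synthgen`) — ground-truthed synthetic AIF runs:
   7-level 4-fold dilution series (4.0 → ~0.001 µM, 1–8000 fmol injected),
   three alternating collision-energy channels (full scan, 10, 30 eV) at
   6 scans/s, Gaussian elution peaks with detector saturation, multiple
   adducts with ¹³C isotopologues, a constant background contaminant ion,
   and a smooth monotone RT drift per run. Every run ships with a manifest
   written from the same source of truth.
2. **RT correction** (`aiflib.rt_align`) — technical internal standards
   (tIS) spiked into every injection anchor a piecewise-linear map from the
   observed to the reference time axis; beyond the anchor span a constant
   offset is used.
3. **Deconvolution** (`aiflib.deconv`) — two independent strategies:
   - *within-run least squares* (`ms2dec`): each fragment bin's
     chromatogram inside the precursor's elution window is fitted as a
     non-negative combination of the precursor's elution profile,
     interferent profiles with different apexes, and a constant baseline;
   - *cross-sample correlation* (`corrdec`): over the dilution series a
     true fragment's apex height is proportional to the precursor's apex
     height across samples (Pearson *r* ≥ 0.90 by default); at least
     **4** samples must carry the precursor above the noise level, and
     constant-intensity contaminants are excluded automatically.
4. **Annotation** (`aiflib.annotate`) — every deconvoluted peak is tested
   against all subformulas of the ionized precursor (RDBE ≥ 0, H ≤ 2C+N+2)
   and against enumerated adduct / water-loss / isotope candidate ions;
   unannotated peaks are removed.
5. **Curation** (`aiflib.librarian`) — records grouped by InChIKey first
   block (the molecular skeleton), formula/RT consistency checks (<1 min
   default window), experimental precursor m/z replaced by the theoretical
   value (the original reading is retained), consensus spectra,
   product-ion frequency tables and library diffing.
6. **Identification** (`aiflib.identify`) — query features matched by
   accurate mass (±0.01 Th) and corrected RT (±0.7 min), then scored with
   the spectral dot product

   ```
   similarity = 100 · (Σᵢ xᵢ yᵢ)² / (Σᵢ xᵢ² · Σᵢ yᵢ²)
   ```

   over greedily matched peak pairs; acceptance requires ≥ 70 % by
   default. Confidence labels follow the Metabolomics Standards
   Initiative convention: level 1 only when the standards were analyzed
   in the same batch, otherwise level 2.

All library I/O is plain text: NIST-style MSP (read/write, with per-peak
annotations), MGF (read/write), MassBank records (read), and a simple
tabular scan format for AIF runs.

## Worked example

```python
from aiflib.chem import parse_formula, parse_adduct, adduct_mz, monoisotopic_mass
from aiflib import synthgen, deconv
from aiflib.annotate import annotate_fragments, strip_unannotated

trig = parse_formula("C7H7NO2")
mh = parse_adduct("[M+H]+")
print(f"monoisotopic mass: {monoisotopic_mass(trig):.4f} Da")
print(f"[M+H]+ m/z:        {adduct_mz(trig, mh):.4f} Th")

comp = synthgen.default_compounds()[0]          # trigonelline, RT 7.46 min
run, truth = synthgen.simulate_run([comp, *synthgen.default_tis()],
                                   [125.0] + [500.0] * 5, seed=1)
eic = deconv.extract_eic(run, channel=0.0, mz=comp.precursor_mz, tol=0.01)
peak = max(deconv.detect_peaks(eic, min_height=1000), key=lambda p: p.height)
print(f"precursor apex:    {peak.apex_rt:.2f} min, height {peak.height:.0f}")

spec = deconv.ms2dec(run, comp.precursor_mz, peak, channel=30.0)
spec = deconv.filter_relative_intensity(spec, 1.0)   # drop peaks < 1 % of base
spec = strip_unannotated(annotate_fragments(spec, comp.formula, mh))
for p in spec.normalized().peaks:
    print(f"  {p.mz:9.4f}  {p.intensity:5.1f}  {p.annotation.label}")
```

prints

```
monoisotopic mass: 137.0477 Da
[M+H]+ m/z:        138.0550 Th
precursor apex:    7.46 min, height 699598
    54.0341   12.0  C3H4N+
    80.0497   45.0  C5H6N+
    94.0654  100.0  C6H8N+
   138.0552   20.0  [M+H]+
   139.0586    1.5  [M+H]+ [13C1]
   160.0371    3.8  [M+Na]+
   176.0111    1.3  [M+K]+
```

The 125 fmol injection gives a high but non-saturated precursor (7 × 10⁵
counts) at the expected retention time. The deconvoluted 30 eV spectrum
contains the three collision-induced fragments with their generated
relative intensities, the surviving protonated molecule with its ¹³C
isotopologue, and the sodium/potassium adducts — while the constant
background ion at 149.0233 Th and the random noise centroids have been
removed by deconvolution, the 1 % intensity floor and annotation.

## Command line

```bash
aiflib simulate campaign/ --seed 1          # synthetic campaign + query run
aiflib characterize campaign/ library.msp   # align, deconvolute, annotate, curate
aiflib curate library.msp curated.msp       # batch re-curation + consistency report
aiflib compare curated.msp other.msp        # per-compound similarity / RT diff table
aiflib identify campaign/query.aif.tsv curated.msp --tis campaign/compounds.yaml
```

Every numeric setting lives in a YAML config
(`src/aiflib/data/default_config.yaml`, overridable per key with
`-O key=value`).

## Acceptance script

`scripts/acceptance.py` re-runs the whole computation from scratch under a
given seed — simulates the default characterization campaign, builds and
curates the library, verifies the MSP round trip, and identifies the
query-run features (one true compound plus two same-m/z decoys) against
the library — then writes the results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
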