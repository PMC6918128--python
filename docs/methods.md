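# Methods

This note documents the models, numerical choices and limitations behind
`aiflib`. It states no empirical result that the test suite and
`scripts/acceptance.py` do not themselves compute.

## Exact-mass chemistry

Monoisotopic atomic masses are fixed in code (IUPAC values): H 1.0078250319,
C 12 exactly, N 14.0030740052, O 15.9949146221, Na 22.98976928,
K 38.9637064864, S 31.97207069, P 30.97376151, Cl 34.96885271; electron
0.00054858 Da. Ion m/z is

    m/z = (M + m(gained) − m(lost) − z·mₑ) / |z|

with the electron mass subtracted per positive charge; with this table the
protonated trigonelline ion computes to 138.05495 Th (printed 138.0550).
Display rounding is 4 decimals; all internal arithmetic is full precision.
Adduct names accept both the ASCII hyphen and the typographic minus
(U+2212); multipliers expand (`2H2O` = two waters). Charge magnitudes 1–2
are supported; average masses and fine isotope structure are out of scope —
carbon-13 spacing uses the single constant Δ = 1.0033548378 Da.

## Retention-time correction

Technical internal standards (tIS) are located per run as the apex of the
most intense chromatographic peak within ±1.5 min (configurable) of their
reference RT in the full-scan channel. The observed→reference map is
piecewise linear between anchors, exact at anchors, and a *constant offset*
beyond the span — slope extension was rejected because gradient extremes
would extrapolate wildly; the correction is deliberately coarse. Anchors
with no detection (e.g. ion suppression by a coeluting analyte) are dropped
with a warning; at least two usable anchors are required. RT deviation
statistics use the sample (n−1) standard deviation, appropriate for the
handful of injections in a characterization campaign.

## Deconvolution

**Least squares (within run).** Fragment centroids inside the precursor's
integration bounds are clustered into bins (gap > 0.01 Th splits a bin;
intensity-weighted centers). Each bin's chromatogram segment is fitted by
non-negative least squares (`scipy.optimize.nnls`) against: (i) the
precursor's own full-scan EIC, renormalized to unit apex (a Gaussian of the
same width substitutes when the EIC shows a clipped flat top of ≥ 3
samples); (ii) unit-height Gaussian profiles of peaks detected in the
bin's own EIC whose apex differs from the precursor apex by more than
3 scans — near-coincident interferents are merged keeping the taller, which
realizes the tie-break by the larger coefficient at the resolution the data
supports; and (iii) a constant baseline, which also absorbs
non-chromatographic background such as the constant contaminant ion. The
deconvoluted intensity is the coefficient on component (i); zero
coefficients drop the bin. The per-peak quality is the fraction of the
bin's summed signal explained by the precursor component (0–1).

**Correlation (across samples).** Over the dilution series, the precursor
apex height h_i is measured per run (0 when undetected). The method
declines unless ≥ `min_samples` (default 4) runs have h_i above the
configured noise level. For each fragment bin, v_i is the bin's apex height
inside run i's precursor window; bins are kept when Pearson r(v, h) over
the above-noise runs reaches `r_threshold` (default 0.90). The reported
intensity is the slope of the through-origin regression of v on h, rescaled
to base peak 100. A vector with zero variance (a constant-intensity
contaminant) has no defined correlation and fails the criterion — this is
the mechanism that removes chemical background. The correlation threshold,
the noise definition and the intensity estimator are not fixed by any
external reference; all three are config-exposed documented choices.

**Peak detection.** 3-point moving-average smoothing; local maxima via
`scipy.signal.find_peaks`; apex refined on the raw trace; boundaries walk
to the nearest valley or a 2 %-of-apex baseline crossing; minimum width
3 scans. Saturation is detected as ≥ 3 consecutive samples at the maximum.

## Annotation

Candidates per peak are (a) all subformulas of the ionized precursor's atom
multiset whose single-charge ion m/z lies within ±0.01 Th (depth-first
enumeration with mass-window pruning), constrained by ring-plus-double-bond
equivalents ≥ 0 (monovalent Na/K/Cl count as hydrogen; N and P are
trivalent) and the hydrogen rule H ≤ 2C + N + 2; and (b) the enumerated
adducts × water losses × ¹³C isotopologues of the intact molecule. The
lowest-|mass-error| candidate wins; ties prefer even-electron ions (a
composition with integer RDBE is an odd-electron radical cation and carries
a penalty flag), then fewer atoms, then the lexicographically smaller
label — making annotation fully deterministic. Peaks with no candidate stay
unannotated and are removed before library export. The tolerance and
element constraints are configurable; they are this package's own choices,
not a reimplementation of any specific annotation engine.

## Library curation

Records are grouped by the InChIKey first block by default (full key
optional); groups are flagged when they contain more than one distinct
formula or an RT spread ≥ 1 min. Precursor replacement stores the
experimental reading in the record's COMMENT (`experimental_mz=`) so mass
accuracy remains auditable, and is idempotent. Consensus spectra cluster
peaks across replicates within the bin tolerance, keep clusters present in
≥ 50 % of spectra, and use the intensity-weighted mean m/z with the median
of per-spectrum-normalized intensities (median resists a single outlier
replicate). The spectral dot product uses raw intensities without m/z
weighting — weighted variants exist in the field but the unweighted
squared cosine is the baseline definition; peak pairing is greedy
nearest-m/z with each peak used at most once and ties to the lower m/z.

## Identification

AMRT candidate search uses ±0.01 Th and ±0.7 min by default (both printed
acquisition-scale values); no bijection is forced between features and
records. MS2 similarity is computed per shared collision energy;
acceptance needs ≥ 70 % — the acceptance threshold is a documented choice,
config-exposed, since only a qualitative match/no-match distinction is
available as a reference point. Accepted matches are ranked by
(similarity, −|RT error|, −|mass error|) and the best is flagged. Level
labels: accepted + same batch → level-1; accepted otherwise → level-2
(AMRT+MS2); AMRT-only → level-2 (AMRT). The policy table is overridable.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the stated acquisition design: 15-minute
gradient, 40–1200 Th mass range, 6 scans/s over three alternating
collision-energy channels (⇒ 2 cycles/s, 1800 cycles per run), 7-level
4-fold dilutions from 4.0 µM (2 µL injected ⇒ 8000 fmol at the top,
~1 fmol at the bottom for 1 µL), tIS at a constant 500 fmol in every run,
and one blank between compounds. Peak shape is Gaussian with σ = 3 s (no
shape is externally specified; fronting/tailing is a known omission).
Saturation is hard clipping at 5 × 10⁶ counts, motivated by the
representative-sample rule of picking a non-saturated injection in the
10⁴–10⁶ range. Response factors span 800–7000 counts/fmol, with the
charged-nitrogen compound about an order of magnitude more responsive than
the amino acids, mirroring reported detection-limit spreads. Mass error is
a per-ion-per-run draw clipped to ±2 mDa; RT drift is linear per run
(offset ≤ 0.3 min, slope ≤ 2 %) — smooth and monotone, which a
piecewise-linear correction can remove almost exactly; real HILIC drift is
not exactly linear, so the ≥5-fold drift-reduction test establishes the
mechanism, not field performance. A constant contaminant ion is emitted in
every scan at 149.0233 Th (the ubiquitous phthalate background) plus two
random noise centroids per scan at the noise floor. Synthetic InChIKeys
have valid 14-10-1 block structure but are fabricated from a name hash and
must never be resolved against chemical databases. The built-in compound
set intentionally contains three C7H7NO2 isomers at distinct RTs so the
identification scenario has same-m/z library records near the decoy
retention times; the two decoy features share the true compound's
precursor m/z but carry disjoint fragment sets.

A green parameter-recovery test therefore establishes: RT correction to
±0.05 min under linear drift, fragment relative-intensity recovery to ±15
points by both deconvolution methods, background exclusion, and correct
accept/reject decisions in the three-candidate scenario. It does not
establish robustness to nonlinear drift, peak-shape asymmetry, electrospray
matrix effects, or isotope fine structure — none of which the generator
models.

## Numerical and degenerate-input conventions

- RT is minutes everywhere; MGF seconds convert at the boundary.
- Floats serialize with Python's shortest round-trip representation, so
  written libraries and scan tables read back bit-identically and writers
  are byte-stable (the tabular reader uses pandas'
  `float_precision="round_trip"` for the same reason).
- Intensities are stored as written; normalization is always an explicit
  operation, never implicit I/O behavior.
- Empty spectra: the dot product returns 0 with a warning; the 1 %
  relative-intensity filter passes empty input through.
- The intensity filter keeps the boundary (removal is strictly "< 1 %").
- An `AIFRun` is validated on construction (every cycle has every channel,
  cycle times strictly increasing) and indexed lazily per channel for EIC
  extraction; runs must not be mutated after first use.

## Known limitations

mzML input is not implemented (the open text scan format and the internal
tabular format cover supported inputs); profile-mode centroiding, vendor
formats, nonlinear RT warping (LOESS-style), retention-index systems,
charge > 2, MS1 isotope-pattern deconvolution, SWATH variable windows, and
full structure elucidation are out of scope. The identification stage is a
targeted re-analysis against library precursors, not untargeted feature
detection across a study.
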