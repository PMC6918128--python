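# aiflib pipeline defaults. Every value can be overridden on the command
# line with a flag of the same name.

# Mass windows (Th). 0.01 matches the extraction window used for the
# 138.055 +/- 0.01 trigonelline chromatograms.
mz_tol: 0.01          # EIC extraction and accurate-mass matching
bin_tol: 0.01         # fragment binning and spectral dot product
annotation_tol: 0.01  # fragment-formula annotation

# Retention-time windows (minutes).
rt_tol: 0.7             # AMRT identification window
group_rt_window: 1.0    # records of one compound farther apart are flagged
anchor_search_window: 1.5  # tIS apex search around its reference RT

# Correlation deconvolution over the dilution series.
min_samples: 4        # runs with the precursor above noise_level required
r_threshold: 0.90     # Pearson r to keep a fragment bin
noise_level: 1000.0   # precursor apex noise floor (detector units)

# Spectrum cleanup and identification.
relative_intensity_threshold: 1.0  # % of base peak; smaller peaks removed
ms2_threshold: 70.0   # % dot product to accept an AMRT+MS2 identification
feature_min_height: 2000.0  # query feature detection floor

# Representative-run selection: highest precursor apex inside this
# non-saturated window (detector counts).
representative_window: [10000.0, 1000000.0]

collision_energies: [0.0, 10.0, 30.0]
same_batch: false     # true only when standards ran in the same batch (level-1)
seed: 0
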