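# Versioned generator defaults: genotype presets and drug-effect multipliers.
#
# Units: mean_rr / amplitudes / noise_sd in ms; frequencies in cycles/beat;
# trend_slope in ms/beat; ectopic_rate is a per-beat probability.
#
# Calibration notes (closed form: expected SDRR = sqrt(lf^2/2 + hf^2/2 + noise^2)):
#   WT     : SDRR = sqrt(4^2/2 + 5^2/2 + 3^2)   = sqrt(29.50) ~ 5.43 ms, mean RR 100 ms (~600 bpm)
#   TGAC8  : SDRR = sqrt(1.6^2/2 + 2^2/2 + 1.2^2) = sqrt(4.72) ~ 2.17 ms, mean RR 85 ms (~706 bpm)
#   ratio WT/TGAC8 ~ 2.5 (within the two- to threefold basal contrast), TGAC8 heart rate higher.
# Beat-domain frequencies map to Hz as f/mean_rr_s: lf 0.08 -> 0.80 Hz (WT) / 0.94 Hz (TGAC8),
# hf 0.30 -> 3.0 Hz (WT) / 3.5 Hz (TGAC8): inside the 0.4-1.5 and 1.5-5.0 Hz bands.

genotype_presets:
  WT:
    mean_rr: 100.0
    lf_amp: 4.0
    hf_amp: 5.0
    lf_freq: 0.08
    hf_freq: 0.30
    noise_sd: 3.0
    ectopic_rate: 0.002
    ectopic_scale: 1.6
    trend_slope: 0.0
    n_beats: 20000
  TGAC8:
    mean_rr: 85.0
    lf_amp: 1.6
    hf_amp: 2.0
    lf_freq: 0.08
    hf_freq: 0.30
    noise_sd: 1.2
    ectopic_rate: 0.002
    ectopic_scale: 1.6
    trend_slope: 0.0
    n_beats: 20000

# Multiplicative transforms applied per drug per genotype.
# rr_scale multiplies mean_rr; lf/hf/noise scales multiply the respective
# fluctuation magnitudes. Directions mirror the in-vivo pharmacology:
#   atropine (parasympathetic blockade): shortens RR and strips HF-dominant
#     vagal modulation, much more in WT than TGAC8.
#   propranolol (sympathetic blockade): lengthens RR modestly, more in TGAC8
#     (whose rate rides on high adenylyl-cyclase drive), trims LF.
#   dual blockade: intrinsic state; rates converge and residual modulation
#     is small in both genotypes.
#   dobutamine (beta-1 agonist): shortens RR, markedly blunted in TGAC8.
drug_effects:
  atropine:
    WT:    {rr_scale: 0.82, lf_scale: 0.45, hf_scale: 0.25, noise_scale: 0.50}
    TGAC8: {rr_scale: 0.95, lf_scale: 0.75, hf_scale: 0.60, noise_scale: 0.80}
  propranolol:
    WT:    {rr_scale: 1.04, lf_scale: 0.70, hf_scale: 0.90, noise_scale: 0.90}
    TGAC8: {rr_scale: 1.10, lf_scale: 0.60, hf_scale: 0.85, noise_scale: 0.85}
  dual:
    WT:    {rr_scale: 0.90, lf_scale: 0.30, hf_scale: 0.30, noise_scale: 0.60}
    TGAC8: {rr_scale: 1.02, lf_scale: 0.50, hf_scale: 0.50, noise_scale: 0.75}
  dobutamine:
    WT:    {rr_scale: 0.85, lf_scale: 0.70, hf_scale: 0.70, noise_scale: 0.80}
    TGAC8: {rr_scale: 0.97, lf_scale: 0.90, hf_scale: 0.90, noise_scale: 0.95}
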