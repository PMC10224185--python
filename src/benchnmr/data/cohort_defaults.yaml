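# Default synthetic-cohort design: two groups (control, dss) x 3 subjects
# x days 0-5, both fields.
#
# baseline_mM: phenomenological mean concentrations in the buffered fecal
# extract (not printed in the study; realistic SCFA-dominated fecal-water
# levels). effect_fold_day5: multiplicative change in the treated (dss)
# group reached at day 5, ramping linearly from effect_onset_day; the
# directions follow the discriminating-bin interpretation of the study,
# the magnitudes are explicitly synthetic free parameters.

n_per_group: 3
days: [0, 1, 2, 3, 4, 5]
cv_biological: 0.20
effect_onset_day: 2
snr: 500
shift_jitter_ppm: 0.003

internal_standards_mM:
  tsp: 0.5
  formate: 1.0

baseline_mM:
  acetate: 10.0
  butyrate: 3.0
  propionate: 3.0
  lactate: 2.0
  glucose: 2.0
  glutamate: 2.0
  succinate: 1.0
  taurine: 1.5
  alanine: 1.5
  glycine: 1.0
  glycerol: 1.0
  aspartate: 0.8
  threonine: 0.8
  leucine: 0.8
  valine: 0.6
  isoleucine: 0.5
  creatine: 0.5
  methionine: 0.3
  phenylalanine: 0.3
  tyrosine: 0.3

effect_fold_day5:
  acetate: 2.5
  succinate: 1.3
  glucose: 1.3
  taurine: 1.3
  butyrate: 0.5
  propionate: 0.7
  isoleucine: 0.7
  valine: 0.7
  leucine: 0.7
  alanine: 0.7
  aspartate: 0.7
  glycerol: 0.7
  threonine: 0.7
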