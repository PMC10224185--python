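# 1H spin systems of the fecal metabolite panel assigned at 60 MHz
# (annotations 1-19) plus the internal standards TSP and formate, and the
# two non-panel metabolites (succinate, taurine) needed for the treated-group
# effect profile.
#
# groups: [shift_ppm, n_equivalent, label]
# couplings: [group_index_a, group_index_b, J_hz]
# source per entry: "panel" shifts/J printed in the study are marked
# source: study; all remaining values are standard aqueous-pH7 reference
# shifts (HMDB/BMRB-style) and are marked source: reference.

acetate:
  panel: true
  groups:
    - {shift_ppm: 1.92, n: 3, label: CH3, source: study}
  couplings: []

alanine:
  panel: true
  groups:
    - {shift_ppm: 1.48, n: 3, label: beta-CH3, source: study}
    - {shift_ppm: 3.78, n: 1, label: alpha-CH, source: reference}
  couplings:
    - [0, 1, 7.2]

aspartate:
  panel: true
  groups:
    - {shift_ppm: 2.68, n: 1, label: beta-CH, source: reference}
    - {shift_ppm: 2.80, n: 1, label: beta-CH', source: reference}
    - {shift_ppm: 3.89, n: 1, label: alpha-CH, source: reference}
  couplings:
    - [0, 1, 17.4]
    - [0, 2, 8.9]
    - [1, 2, 3.7]

butyrate:
  panel: true
  groups:
    - {shift_ppm: 0.90, n: 3, label: CH3, source: reference}
    - {shift_ppm: 1.56, n: 2, label: beta-CH2, source: reference}
    - {shift_ppm: 2.16, n: 2, label: alpha-CH2, source: reference}
  couplings:
    - [0, 1, 7.4]
    - [1, 2, 7.3]

creatine:
  panel: true
  groups:
    - {shift_ppm: 3.03, n: 3, label: N-CH3, source: reference}
    - {shift_ppm: 3.93, n: 2, label: CH2, source: reference}
  couplings: []

formate:
  panel: true
  internal_standard: true
  groups:
    - {shift_ppm: 8.44, n: 1, label: CH, source: reference}
  couplings: []

glucose:
  panel: true
  groups:
    - {shift_ppm: 3.22, n: 1, label: beta-C2H, source: study}
    - {shift_ppm: 3.38, n: 1, label: C4H, source: study}
    - {shift_ppm: 3.46, n: 1, label: C3H/C5H, source: study}
    - {shift_ppm: 3.72, n: 2, label: C6H2, source: reference}
    - {shift_ppm: 3.84, n: 1, label: C5H, source: reference}
    - {shift_ppm: 4.64, n: 1, label: beta-C1H, source: reference}
  couplings:
    - [0, 5, 7.9]
    - [0, 2, 9.1]
    - [1, 2, 9.4]

glutamate:
  panel: true
  groups:
    - {shift_ppm: 2.08, n: 2, label: beta-CH2, source: reference}
    - {shift_ppm: 2.34, n: 2, label: gamma-CH2, source: reference}
    - {shift_ppm: 3.75, n: 1, label: alpha-CH, source: reference}
  couplings:
    - [0, 1, 7.6]
    - [0, 2, 6.5]

glycerol:
  panel: true
  groups:
    - {shift_ppm: 3.56, n: 2, label: CH2, source: reference}
    - {shift_ppm: 3.64, n: 2, label: CH2', source: reference}
    - {shift_ppm: 3.78, n: 1, label: CH, source: reference}
  couplings:
    - [0, 2, 6.5]
    - [1, 2, 4.4]

glycine:
  panel: true
  groups:
    - {shift_ppm: 3.56, n: 2, label: CH2, source: reference}
  couplings: []

isoleucine:
  panel: true
  groups:
    - {shift_ppm: 0.93, n: 3, label: delta-CH3, source: reference}
    - {shift_ppm: 1.00, n: 3, label: gamma2-CH3, source: study}
    - {shift_ppm: 1.27, n: 2, label: gamma-CH2, source: reference}
    - {shift_ppm: 1.97, n: 1, label: beta-CH, source: reference}
    - {shift_ppm: 3.66, n: 1, label: alpha-CH, source: reference}
  couplings:
    - [0, 2, 7.4]
    - [1, 3, 7.05]
    - [2, 3, 7.0]
    - [3, 4, 4.0]

leucine:
  panel: true
  groups:
    - {shift_ppm: 0.95, n: 3, label: delta-CH3, source: reference}
    - {shift_ppm: 0.96, n: 3, label: delta-CH3', source: reference}
    - {shift_ppm: 1.70, n: 3, label: beta-CH2+gamma-CH, source: reference}
    - {shift_ppm: 3.72, n: 1, label: alpha-CH, source: reference}
  couplings:
    - [0, 2, 6.3]
    - [1, 2, 6.3]
    - [2, 3, 7.0]

lactate:
  panel: true
  groups:
    - {shift_ppm: 1.33, n: 3, label: CH3, source: reference}
    - {shift_ppm: 4.11, n: 1, label: CH, source: reference}
  couplings:
    - [0, 1, 6.9]

methionine:
  panel: true
  groups:
    - {shift_ppm: 2.13, n: 3, label: S-CH3, source: reference}
    - {shift_ppm: 2.16, n: 2, label: beta-CH2, source: reference}
    - {shift_ppm: 2.64, n: 2, label: gamma-CH2, source: reference}
    - {shift_ppm: 3.86, n: 1, label: alpha-CH, source: reference}
  couplings:
    - [1, 2, 7.5]
    - [1, 3, 6.5]

phenylalanine:
  panel: true
  groups:
    - {shift_ppm: 7.32, n: 2, label: ring-2,6-H, source: reference}
    - {shift_ppm: 7.37, n: 1, label: ring-4-H, source: reference}
    - {shift_ppm: 7.42, n: 2, label: ring-3,5-H, source: reference}
    - {shift_ppm: 3.19, n: 2, label: beta-CH2, source: reference}
    - {shift_ppm: 3.98, n: 1, label: alpha-CH, source: reference}
  couplings:
    - [0, 2, 7.5]
    - [1, 2, 7.4]
    - [3, 4, 6.5]

propionate:
  panel: true
  groups:
    - {shift_ppm: 1.05, n: 3, label: CH3, source: study}
    - {shift_ppm: 2.18, n: 2, label: CH2, source: reference}
  couplings:
    - [0, 1, 7.70]

threonine:
  panel: true
  groups:
    - {shift_ppm: 1.32, n: 3, label: gamma-CH3, source: reference}
    - {shift_ppm: 3.58, n: 1, label: alpha-CH, source: reference}
    - {shift_ppm: 4.25, n: 1, label: beta-CH, source: reference}
  couplings:
    - [0, 2, 6.6]
    - [1, 2, 4.9]

tyrosine:
  panel: true
  groups:
    - {shift_ppm: 6.90, n: 2, label: ring-3,5-H, source: reference}
    - {shift_ppm: 7.19, n: 2, label: ring-2,6-H, source: reference}
    - {shift_ppm: 3.12, n: 2, label: beta-CH2, source: reference}
    - {shift_ppm: 3.93, n: 1, label: alpha-CH, source: reference}
  couplings:
    - [0, 1, 8.5]
    - [2, 3, 6.8]

valine:
  panel: true
  groups:
    - {shift_ppm: 0.98, n: 3, label: gamma-CH3, source: reference}
    - {shift_ppm: 1.03, n: 3, label: gamma2-CH3, source: study}
    - {shift_ppm: 2.26, n: 1, label: beta-CH, source: reference}
    - {shift_ppm: 3.60, n: 1, label: alpha-CH, source: reference}
  couplings:
    - [0, 2, 7.0]
    - [1, 2, 7.05]
    - [2, 3, 4.4]

tsp:
  panel: false
  internal_standard: true
  groups:
    - {shift_ppm: 0.00, n: 9, label: Si(CH3)3, source: reference}
  couplings: []

succinate:
  panel: false
  groups:
    - {shift_ppm: 2.39, n: 4, label: CH2x2, source: reference}
  couplings: []

taurine:
  panel: false
  groups:
    - {shift_ppm: 3.26, n: 2, label: S-CH2, source: study}
    - {shift_ppm: 3.42, n: 2, label: N-CH2, source: study}
  couplings:
    - [0, 1, 6.6]
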