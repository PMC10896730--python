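# Canonical ETFDH-assisted complex III Q-cycle network (14 species, 7 reactions).
# Schema: species [{id, name, initial}], parameters [{id, value}],
# reactions [{id, k, rate_factors: [[species, exponent], ...], stoich: {species: int}}].
# k6 and k7 are part of the canonical constant table but enter no rate law.
species:
  - {id: x1, name: QH2, initial: 0.6}
  - {id: x2, name: Cytc_ox, initial: 1.1}
  - {id: x3, name: e-, initial: 4.6}
  - {id: x4, name: QHdot_CIII_Qo, initial: 0.0}
  - {id: x5, name: Cytc_red, initial: 0.0}
  - {id: x6, name: Hplus_P, initial: 0.0}
  - {id: x7, name: Q, initial: 0.5}
  - {id: x8, name: Hplus_N, initial: 0.5}
  - {id: x9, name: ETFDH_FADH2, initial: 1.0}
  - {id: x10, name: ETFDH_FADH, initial: 0.0}
  - {id: x11, name: ETFDH_FAD, initial: 0.0}
  - {id: x12, name: QHdot_CIII_Qi_1, initial: 0.0}
  - {id: x13, name: QHdot_CIII_Qi_2, initial: 0.0}
  - {id: x14, name: QHdot_ETFDH, initial: 0.0}
parameters:
  - {id: k1, value: 5.0}
  - {id: k2, value: 5.0}
  - {id: k3, value: 5.0}
  - {id: k4, value: 5.0}
  - {id: k5, value: 20.0}
  - {id: k6, value: 21.0}
  - {id: k7, value: 21.0}
reactions:
  - id: r1
    k: k1
    rate_factors: [[x1, 1], [x2, 1], [x3, 1]]
    stoich: {x1: -1, x2: -1, x3: -1, x4: 1, x5: 1, x6: 1}
  - id: r2
    k: k2
    rate_factors: [[x3, 1], [x4, 1], [x7, 1], [x8, 1]]
    stoich: {x3: -1, x4: -1, x6: 1, x8: -1, x12: 1}
  - id: r3
    k: k1
    rate_factors: [[x1, 1], [x2, 1], [x3, 1]]
    stoich: {x1: -1, x2: -1, x3: -1, x4: 1, x5: 1, x6: 1}
  - id: r4
    k: k2
    rate_factors: [[x3, 1], [x4, 1], [x7, 1], [x8, 1]]
    stoich: {x3: -1, x4: -1, x6: 1, x8: -1, x13: 1}
  - id: r5
    k: k3
    rate_factors: [[x3, 1], [x9, 1], [x12, 1]]
    stoich: {x3: -1, x8: 1, x9: -1, x10: 1, x12: -1, x14: 1}
  - id: r6
    k: k4
    rate_factors: [[x3, 1], [x10, 1], [x13, 1], [x14, 1]]
    stoich: {x1: 1, x3: -1, x7: 1, x8: 1, x10: -1, x11: 1, x13: -1, x14: -1}
  - id: r7
    k: k5
    rate_factors: [[x3, 1], [x12, 1], [x13, 1]]
    stoich: {x1: 1, x3: -1, x7: 1, x12: -1, x13: -1}
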