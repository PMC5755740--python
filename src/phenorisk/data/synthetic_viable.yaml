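# Fully SYNTHETIC phenology model fixture.
#
# Every parameter here is invented.  The model is constructed to be viable
# (positive development, immature survival and reproduction) across the
# 15-35 °C range of the constant-temperature design, with realistic
# tephritid magnitudes: ~2-12 day immature stages near the optimum,
# U-shaped immature mortality with a minimum near 23 °C, adult longevity
# of weeks to months falling with temperature, a fecundity peak of ~800
# eggs near 27 °C, and oviposition concentrated in the first third of
# normalized adult life.  It is the reference truth model for generator
# round-trips, simulation oracles and risk-index runs.
name: synthetic_viable
notes: All parameters synthetic; viable over 15-35 C by construction.
female_ratio: 0.5
adult_slope: null
stages:
  egg:
    dev_rate:
      form: briere1
      params: {a: 3.2e-4, Tmin: 9.0, Tmax: 37.5}
    devtime_slope: 8.0
    mortality:
      form: mortality_expquad
      params: {b1: 4.574, b2: -0.598, b3: 0.013}
  larva:
    dev_rate:
      form: briere1
      params: {a: 8.0e-5, Tmin: 9.0, Tmax: 38.0}
    devtime_slope: 8.0
    mortality:
      form: mortality_expquad
      params: {b1: 2.874, b2: -0.50, b3: 0.011}
  pupa:
    dev_rate:
      form: briere1
      params: {a: 6.5e-5, Tmin: 8.0, Tmax: 36.5}
    devtime_slope: 8.0
    mortality:
      form: mortality_expquad
      params: {b1: 3.4, b2: -0.54, b3: 0.0115}
senescence_female:
  form: senescence_exponential
  params: {b1: 0.0098, b2: 0.0403}
senescence_male:
  form: senescence_exponential
  params: {b1: 0.0049, b2: 0.0689}
fecundity:
  form: fecundity_gaussian
  params: {y0: 0.0, a: 800.0, b: 5.0, x0: 27.0}
oviposition:
  form: ovip_gamma
  params: {a: 4.0, b: 12.0}
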