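# "rosa-like" phenology model fixture.
#
# Immature mortality, adult senescence, lifetime fecundity and cumulative
# oviposition carry the published parameter estimates for Ceratitis rosa
# verbatim (proportion scale for mortality).  The Brière-1 development-rate
# parameters and the development-time dispersion slopes are SYNTHETIC: no
# rate parameters are published for this species in the source tables, so
# plausible values were chosen to reproduce the reported development times
# (~2.3 d egg, ~9 d larva, ~12 d pupa near 25 °C).
#
# Caution: on the proportion scale the published pupal mortality set has its
# minimum above 1, i.e. the clipped curve is 1 at every temperature.  The
# fixture keeps the printed values as an archive; use the synthetic_viable
# fixture for simulations that need a model viable over 15-35 °C.
name: rosa_like
notes: >-
  Published mortality/senescence/fecundity/oviposition parameters;
  synthetic development-rate parameters (flagged; not published).
female_ratio: 0.5
adult_slope: null
stages:
  egg:
    dev_rate:
      form: briere1
      params: {a: 3.15e-4, Tmin: 9.5, Tmax: 37.6}   # synthetic
    devtime_slope: 8.0                              # synthetic
    mortality:
      form: mortality_expquad
      params: {b1: 10.271, b2: -0.909, b3: 0.019}
      param_se: {b1: 0.002, b2: 0.0235, b3: 0.0006}
  larva:
    dev_rate:
      form: briere1
      params: {a: 8.01e-5, Tmin: 9.5, Tmax: 37.8}   # synthetic
    devtime_slope: 8.0                              # synthetic
    mortality:
      form: mortality_expquad
      params: {b1: 9.621, b2: -0.453, b3: 0.009}
      param_se: {b1: 0.0014, b2: 0.0161, b3: 0.0005}
  pupa:
    dev_rate:
      form: briere1
      params: {a: 6.2e-5, Tmin: 8.0, Tmax: 35.0}    # synthetic
    devtime_slope: 8.0                              # synthetic
    mortality:
      form: mortality_expquad
      params: {b1: 7.178, b2: -0.570, b3: 0.014}
      param_se: {b1: 0.0031, b2: 0.0332, b3: 0.0012}
senescence_female:
  form: senescence_exponential
  params: {b1: 0.0098, b2: 0.0403}
  param_se: {b1: 0.0041, b2: 0.0137}
senescence_male:
  form: senescence_exponential
  params: {b1: 0.0049, b2: 0.0689}
  param_se: {b1: 0.0039, b2: 0.0247}
fecundity:
  form: fecundity_exppoly
  params: {b1: -7.851, b2: 1.064, b3: -0.019}
  param_se: {b1: 0.0019, b2: 0.0258, b3: 0.0009}
oviposition:
  form: ovip_logistic
  params: {a: 3.94859, b: -3.43037}
  param_se: {a: 0.0933, b: 0.0778}
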