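# "quilicii-like" phenology model fixture.
#
# Immature mortality, adult senescence, lifetime fecundity (Gaussian) and
# cumulative oviposition (gamma CDF) carry the published parameter
# estimates for Ceratitis quilicii verbatim.  The Brière-1 development-rate
# parameters and development-time dispersion slopes are SYNTHETIC (not
# published), chosen to reproduce the reported development times near 25 °C.
#
# Caution: the published pupal mortality triple (b2 positive, b3 = 141.781)
# is evidently garbled in the source table; it is archived verbatim here,
# which makes the clipped curve 1 at every temperature.  Use the
# synthetic_viable fixture for simulations needing a viable model.
name: quilicii_like
notes: >-
  Published mortality/senescence/fecundity/oviposition parameters
  (pupal mortality garbled in source, archived as printed); synthetic
  development-rate parameters (flagged; not published).
female_ratio: 0.5
adult_slope: null
stages:
  egg:
    dev_rate:
      form: briere1
      params: {a: 3.06e-4, Tmin: 5.0, Tmax: 35.2}   # synthetic
    devtime_slope: 8.0                              # synthetic
    mortality:
      form: mortality_expquad
      params: {b1: 5.183, b2: -0.422, b3: 0.009}
      param_se: {b1: 0.0008, b2: 0.0086, b3: 0.0003}
  larva:
    dev_rate:
      form: briere1
      params: {a: 6.95e-5, Tmin: 5.0, Tmax: 35.1}   # synthetic
    devtime_slope: 8.0                              # synthetic
    mortality:
      form: mortality_expquad
      params: {b1: 4.812, b2: -0.290, b3: 0.007}
      param_se: {b1: 0.0012, b2: 0.0140, b3: 0.0005}
  pupa:
    dev_rate:
      form: briere1
      params: {a: 5.97e-5, Tmin: 5.9, Tmax: 33.3}   # synthetic
    devtime_slope: 8.0                              # synthetic
    mortality:
      form: mortality_expquad
      params: {b1: 5.8716, b2: 0.3892, b3: 141.781}  # as printed (garbled)
      param_se: {b1: 0.0560, b2: 0.0020, b3: 0.0054}
senescence_female:
  form: senescence_exponential
  params: {b1: 0.0061, b2: 0.056}
  param_se: {b1: 0.0029, b2: 0.0151}
senescence_male:
  form: senescence_exponential
  params: {b1: 0.0058, b2: 0.0624}
  param_se: {b1: 0.0042, b2: 0.0234}
fecundity:
  form: fecundity_gaussian
  params: {y0: -41393.36, a: 41971.86, b: 74.63, x0: 25.126}
  param_se: {y0: 3.8096, a: 29.3741, b: 19.0522, x0: 7.8725}
oviposition:
  form: ovip_gamma
  params: {a: 3.404, b: 3.906}
  param_se: {a: 0.0686, b: 0.08242}
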