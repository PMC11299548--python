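# Default registry: permittivity transforms, published calibrations and
# temperature models. Transform coefficients are manufacturer configuration
# (Teros 11/12 manual), not a fitted result of this package.
transforms:
  teros12:
    description: >
      Teros 11/12 raw-counts to permittivity polynomial from the
      manufacturer's manual; the polynomial yields sqrt(epsilon), hence
      post_square. Valid range restricted to the monotone, positive region.
    coefficients: [-43.39, 5.276e-2, -2.080e-5, 2.887e-9]
    post_square: true
    valid_range: [1800.0, 3600.0]
  identity:
    description: Identity transform (epsilon = raw counts); testing/bypass.
    coefficients: [0.0, 1.0]
    post_square: false
    valid_range: [1.0e-9, 1.0e6]

calibrations:
  TTC:
    label: tropical tree calibration (dicot trees + palms, absolute)
    slope: 0.2227
    intercept: -0.396
    slope_ci: [0.2111, 0.2344]
    mode: absolute
  OSC:
    label: one-slope calibration (first-order differenced, relative WC only)
    slope: 0.2254
    slope_ci: [0.2130, 0.2379]
    mode: relative-only
  meta-temperate-slope:
    label: meta-analysis slope, boreal/temperate/Mediterranean trees (comparison)
    slope: 0.2233
    mode: relative-only

temperature_models:
  water-bucket:
    label: water-bucket temperature experiment (default correction)
    slope_wc: -0.000974        # m3 m-3 per degC
    slope_wc_se: 7.109e-6      # derived from slope / |t|, t = -137
    slope_wc_ci: [-0.000988, -0.000960]
    slope_sqrt_eps: -0.0145    # per degC
    r2: 0.96
    n: 771
    reference_temperature: 25.0
  wood-block:
    label: wood-block temperature experiment (diagnostic; condensation noise)
    slope_wc: -0.000950
    slope_wc_se: 5.9375e-5     # slope / |t|, t = -16
    r2: 0.53
    n: 230
    reference_temperature: 25.0
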