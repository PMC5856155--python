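# Default uncertainty budgets for manual and depth-camera body measurements.
# Each source value is [low, high] over the working-distance range; "percent"
# sources resolve against the measurand length.  Distributions follow the GUM
# convention (rectangular 1/sqrt(3), triangular 1/sqrt(6), normal 1).
coverage_factor: 1.645      # 90% two-sided confidence
budgets:
  manual:
    - {name: lateral_resolution, value: [1.0, 1.0], percent: false, distribution: rectangular}
    - {name: nonlinearity, value: [0.3, 0.3], percent: true, distribution: normal}
    - {name: abbe_error, value: [1.6, 1.6], percent: true, distribution: normal, systematic: true}
    - {name: reference_point_localization, value: [4.0, 15.0], percent: false, distribution: normal}
  kinect-1:
    - {name: lateral_resolution, value: [0.65, 2.0], percent: false, distribution: rectangular}
    - {name: vertical_resolution, value: [1.1, 5.5], percent: false, distribution: rectangular}
    - {name: background_noise, value: [2.4, 2.4], percent: false, distribution: triangular}
    - {name: nonlinearity, value: [0.5, 0.5], percent: true, distribution: normal}
    - {name: abbe_error, value: [0.2, 0.2], percent: true, distribution: normal, systematic: true}
    - {name: reference_point_localization, value: [10.0, 18.0], percent: false, distribution: normal}
  kinect-10:
    - {name: lateral_resolution, value: [0.3, 0.7], percent: false, distribution: rectangular}
    - {name: vertical_resolution, value: [0.4, 1.8], percent: false, distribution: rectangular}
    - {name: background_noise, value: [0.8, 0.8], percent: false, distribution: triangular}
    - {name: nonlinearity, value: [0.2, 0.2], percent: true, distribution: normal}
    - {name: abbe_error, value: [0.2, 0.2], percent: true, distribution: normal, systematic: true}
    - {name: reference_point_localization, value: [2.0, 6.0], percent: false, distribution: normal}
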