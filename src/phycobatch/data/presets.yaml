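# Default simulation presets.
#
# Physical and observational parameters describe a one-side-illuminated
# 3 cm glass-tube multicultivator batch (30 min sampling, 72 h, n = 3
# replicates).  Scenario anchors (target_initial_rate, target_vmax, Y_true)
# are calibrated to the magnitudes printed for the corresponding published
# experiments; mu_max is resolved from each anchor at load time, so the
# generating ground truth equals the anchor exactly.  They are calibration
# anchors, not measurements.

photoautotrophic:
  base:
    mode: photoautotrophic
    L: 0.03            # light path, m
    sigma: 100.0       # attenuation, m^-1 per (g/L)  (0.1 m^2 g^-1)
    K_I: 150.0         # half-saturation irradiance, umol m^-2 s^-1
    maintenance: 0.002 # h^-1
    X0: 0.02           # inoculum, g/L (corrected OD 0.05)
    conversion_k: 0.40 # g/L per corrected-OD unit
    calibration: {a: 1.795, b: 0.934}
    noise_sd: 0.01
    n_replicates: 3
    sample_interval: 0.5
    duration: 72.0
  scenarios:
    mu_reference:      # fast strain near its optimum intensity
      I0: 500.0
      target_initial_rate: 0.15   # h^-1
    vmax_reference:    # strongest productivity case, high light
      I0: 700.0
      target_vmax: 1.8            # g L^-1 day^-1
    light_scan:        # used for the mu/V_max decoupling analysis
      I0: 300.0
      target_initial_rate_at: [0.15, 500.0]  # rate anchored at 500, I0 varied per run

heterotrophic:
  base:
    mode: heterotrophic
    mu_max: 0.10       # h^-1, fast heterotrophic strains
    K_S: 0.1           # g/L
    maintenance: 0.0
    X0: 0.08           # inoculum, g/L (corrected OD 0.2 starter)
    conversion_k: 0.40
    calibration: {a: 1.795, b: 0.934}
    noise_sd: 0.01
    n_replicates: 3
    sample_interval: 0.5
    duration: 72.0
  scenarios:
    glucose_endpoint:      # C. sorokiniana-like glucose batch
      substrate: glucose
      S0: 15.0
      Y_true: 0.55
    acetate_endpoint:      # S. vacuolatus-like acetate batch
      substrate: acetate
      S0: 2.0
      Y_true: 0.32
    acetate_consumption:   # paired biomass/substrate series, HPLC-like noise
      substrate: acetate
      S0: 2.0
      Y_true: 0.30
      noise_sd: 0.02
    weak_light_glucose:    # six-day run showing the weak-light growth effect (slow strain)
      substrate: glucose
      S0: 15.0
      Y_true: 0.50
      mu_max: 0.023
      X0: 0.015
      dark_decay_rate: 0.015
      dark_decay_onset: 50.0
      duration: 143.0
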