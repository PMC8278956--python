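# Jump-process presets parameterised by printed dwell times / occupancies.
# Rates (per ns) are constructed from these parameters by chiflip.presets.
#
# Angular emission: von Mises around the rotamer-well centres, default
# concentration kappa = 50 (about 8 degrees of spread), so the wells are
# cleanly separable by the default rotamer bins.  Distance emissions are
# synthetic stand-ins for state-conditioned loop observables.
defaults:
  kappa: 50.0

presets:
  WT-F152:
    description: Wild-type F152 chi1 two-state exchange (fast L1-coupled flips)
    kind: two_state
    states: [g-, t]
    mean_dwell_ns: {g-: 1.4, t: 1.1}
    emission:
      angle_mean_deg: {g-: 300.0, t: 200.0}
      distance:
        label: K33CA-F152CA
        mean_A: {g-: 8.0, t: 11.0}
        sd_A: {g-: 0.4, t: 0.4}

  WT-H143-fig4:
    description: Wild-type H143 chi1 two-state exchange, 11 ns lifetimes
    kind: two_state
    states: [g-, t]
    mean_dwell_ns: {g-: 11.0, t: 11.0}
    emission:
      angle_mean_deg: {g-: 300.0, t: 205.0}

  WT-H143-text:
    description: Wild-type H143 chi1 exchange, 0.020/0.024 us lifetimes
    kind: two_state
    states: [g-, t]
    mean_dwell_ns: {g-: 20.0, t: 24.0}
    emission:
      angle_mean_deg: {g-: 300.0, t: 205.0}

  S39E-H143:
    description: S39E mutant H143 chi1 exchange, 0.023/0.048 us lifetimes
    kind: two_state
    states: [g-, t]
    mean_dwell_ns: {g-: 23.0, t: 48.0}
    emission:
      angle_mean_deg: {g-: 300.0, t: 205.0}

  I19S-H143:
    description: I19S mutant H143 chi1 exchange, 0.013/0.009 us lifetimes
    kind: two_state
    states: [g-, t]
    mean_dwell_ns: {g-: 13.0, t: 9.0}
    emission:
      angle_mean_deg: {g-: 300.0, t: 205.0}

  WT-Y306:
    description: >
      Wild-type Y306 chi1 three-state exchange.  Only the g- lifetime
      (1.3 us) and the ~0.5% trans population are constrained; the trans
      dwell (10 ns) and g+ dwell (0.3 us) are synthetic choices.
    kind: star_three_state
    states: [g-, t, g+]
    hub: g-
    mean_dwell_ns: {g-: 1300.0, t: 10.0, g+: 300.0}
    occupancy: {t: 0.005}
    emission:
      angle_mean_deg: {g-: 300.0, t: 180.0, g+: 60.0}
      distance:
        label: M274CA-ZN
        mean_A: {g-: 6.2, t: 8.0, g+: 11.5}
        sd_A: {g-: 0.4, t: 0.4, g+: 0.4}

  I19S-Y306:
    description: >
      I19S mutant Y306 two-state exchange with 99.9%/0.1% occupancies;
      the g- dwell (1 us) is a synthetic choice (exchange speed unprinted).
    kind: two_state_occupancy
    states: [g-, t]
    occupancy: {g-: 0.999, t: 0.001}
    mean_dwell_ns: {g-: 1000.0}
    emission:
      angle_mean_deg: {g-: 300.0, t: 180.0}
      distance:
        label: M274CA-ZN
        mean_A: {g-: 6.2, t: 8.0}
        sd_A: {g-: 0.4, t: 0.4}

  S39E-Y306:
    description: >
      S39E mutant Y306 two-state exchange with 99.6%/0.4% occupancies;
      g- dwell (1 us) synthetic as above.
    kind: two_state_occupancy
    states: [g-, t]
    occupancy: {g-: 0.996, t: 0.004}
    mean_dwell_ns: {g-: 1000.0}
    emission:
      angle_mean_deg: {g-: 300.0, t: 180.0}

  WT-HY-composite:
    description: >
      Six-state composite H143 x Y306 process for property tests: marginal H
      kinetics near WT-H143-fig4, marginal Y kinetics near WT-Y306, with
      H(t) stabilised when Y is g+ and Y dynamics slowed when H is t.
      Qualitative coupling only; not a numeric acceptance preset.
    kind: composite_hy
    h_preset: WT-H143-fig4
    y_preset: WT-Y306
    y_slow_when_h_t: 0.05      # multiply all Y rates by this when H == t
    h_forward_boost_y_gp: 2.0  # multiply H g- -> t by this when Y == g+
    h_back_drop_y_gp: 0.25     # multiply H t -> g- by this when Y == g+
    emission:
      angle_mean_deg: {}       # composite states are not emitted directly
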