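# Example pipeline configuration.
#
# Point the *_csv keys at your own exported tables. The endmember CSV shipped
# here (endmembers_synthetic.csv) contains SYNTHETIC placeholder signatures —
# replace them with your experiment's assumed endmember values and
# uncertainties before interpreting any apportionment.

detector_csv: detector.csv        # columns: time_min, co2_ppm
trap_csv: traps.csv               # columns: t_start_min, t_end_min, mass_ugC
fraction_csv: fractions.csv       # see isoresp.isotopes.FRACTION_COLUMNS
endmember_csv: endmembers_synthetic.csv
dpcr_csv: dpcr.csv                # columns: time_h, species, replicate_id,
                                  #          copies_per_ul, dilution_factor

# vessel geometry and detector-side gas conditions
vessel_volume_L: 3.0
medium_volume_schedule: [[0.0, 2.0]]   # [time_min, volume_L] breakpoints
flow_ml_min: 100.0
temperature_K: 298.15
pressure_kPa: 101.325

# baseline anchor windows (minutes); post window defaults to the last hour
baseline_pre_window: [0.0, 30.0]
derivative_window_samples: 31

# system blank (no-op while mass is 0; fill in your blank characterization)
blank_mass_ugC: 0.0
blank_delta13C: -25.0
blank_Delta14C: -1000.0

# Monte Carlo settings
n_draws: 10000
seed: 0
sigma_delta13C: 2.0     # permil, 1-sigma measurement noise
sigma_Delta14C: 50.0    # permil

renormalize_missing: false
simplex_only: false
shared_endmember_draws: true
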