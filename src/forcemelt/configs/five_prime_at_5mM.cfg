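# 5'AT: 64 bp AT-rich duplex, one end sealed. Low-salt (5 mM NaCl) set.
# Melting force drops by ~18 pN relative to 1 M, rezip by ~4.4 pN.
# The single-strand calibration (peeled extension) is shared with the 1 M
# measurement; salt enters only through the kinetic parameter set.
construct = FIVE_PRIME_AT
salt = LOW_5MM
duplex_bp = 64
linker_config = ONE_END

force_min_pN = 2.0
force_max_pN = 60.0
trap_velocity_nm_s = 50.0
trap_stiffness_pN_nm = 0.156
sample_rate_hz = 1000.0
temperature_C = 22.8
noise_sd_pN = 0.3
handle_contour_nm = 50.0

# measured 43.6 +- 2.79 pN melt, 17.3 +- 0.98 pN rezip
melt_force_pN = 43.6
melt_x_nm = 1.88
rezip_force_pN = 17.3
rezip_x_nm = 5.3

peel_extension_nm = 14.7
peel_extension_at_pN = 61.5

# bistable intermediate persists at low salt (order-of-magnitude rates)
hop_crossing_pN = 41.0
hop_peeled_bp = 12
hop_attempt_rate_hz = 25.0

hysteretic_pathway_probability = 1.0
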