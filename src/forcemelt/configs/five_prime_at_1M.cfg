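# 5'AT: 64 bp AT-rich duplex sealed at one end by an inter-strand click-link.
# High-salt (1 M NaCl) parameter set.
#
# Transition-force targets are the measured ensemble means; zero-force rates
# are produced at run time by Bell-Evans calibration against the nominal
# 7.8 pN/s loading rate.  Transition distances (x) are set so the Bell-Evans
# rupture-force spread (pi/sqrt(6) * kBT/x) matches the measured +-1 s.d.
construct = FIVE_PRIME_AT
salt = HIGH_1M
duplex_bp = 64
linker_config = ONE_END

force_min_pN = 2.0
force_max_pN = 75.0
trap_velocity_nm_s = 50.0
trap_stiffness_pN_nm = 0.156
sample_rate_hz = 1000.0
temperature_C = 22.8
noise_sd_pN = 0.3
handle_contour_nm = 50.0

# peeling rupture (measured 61.5 +- 2.62 pN) and rezip (21.7 +- 1.27 pN)
melt_force_pN = 61.5
melt_x_nm = 2.0
rezip_force_pN = 21.7
rezip_x_nm = 4.1

# calibration constraint: peeled-minus-B extension at the mean melt force
peel_extension_nm = 14.7
peel_extension_at_pN = 61.5

# Partial-peel bistable intermediate. The experiments resolve the hopping but
# not its rate constants: crossing force, peeled length and attempt rate are
# order-of-magnitude choices.
hop_crossing_pN = 59.0
hop_peeled_bp = 12
hop_attempt_rate_hz = 25.0

hysteretic_pathway_probability = 1.0
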