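# 3'5'AT: 64 bp AT-rich duplex sealed at both ends. Low salt (5 mM NaCl).
# At low salt the internal melting is a single abrupt, hysteretic step:
# melt 61.0 +- 2.27 pN, rezip 41.1 +- 4.88 pN.
construct = THREE_FIVE_PRIME_AT
salt = LOW_5MM
duplex_bp = 64
linker_config = BOTH_ENDS

force_min_pN = 2.0
force_max_pN = 72.0
trap_velocity_nm_s = 50.0
trap_stiffness_pN_nm = 0.156
sample_rate_hz = 1000.0
temperature_C = 22.8
noise_sd_pN = 0.3
handle_contour_nm = 50.0

equilibrium_mode = false
melt_force_pN = 61.0
melt_x_nm = 2.3
rezip_force_pN = 41.1
rezip_x_nm = 1.1

# calibration constraint: melted-minus-B extension at the mean melt force
melt_extension_nm = 9.30
melt_extension_at_pN = 61.0

hysteretic_pathway_probability = 1.0
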