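# 3'5'AT: 64 bp AT-rich duplex sealed at both ends. High salt (1 M NaCl).
#
# With both ends sealed the duplex melts internally (both strands share the
# tension) as a continuous, non-cooperative equilibrium transition over a
# broad force interval with midpoint F_tr and cooperative length delta.
construct = THREE_FIVE_PRIME_AT
salt = HIGH_1M
duplex_bp = 64
linker_config = BOTH_ENDS

force_min_pN = 2.0
force_max_pN = 80.0
trap_velocity_nm_s = 50.0
trap_stiffness_pN_nm = 0.156
sample_rate_hz = 1000.0
temperature_C = 22.8
noise_sd_pN = 0.3
handle_contour_nm = 50.0

equilibrium_mode = true
f_tr_pN = 67.8
cooperative_length_nm = 2.6

# calibration constraint: melted-minus-B extension at the midpoint force
melt_extension_nm = 10.6
melt_extension_at_pN = 67.8

# 34 of 155 relax curves followed the hysteretic rehybridization pathway
hysteretic_pathway_probability = 0.2193548387096774
# The hysteretic-mode rezip force at 1 M is not quantified experimentally;
# 55 pN is an order-of-magnitude choice that yields a clear hysteresis loop.
hysteretic_rezip_force_pN = 55.0
hysteretic_rezip_x_nm = 2.5

# analysis defaults: linear branch windows below/above the transition region
branch_low_window_pN = 45.0, 60.0
branch_high_window_pN = 76.0, 79.5
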