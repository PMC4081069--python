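# ATGC composite duplex at low salt (5 mM NaCl).
#
# Four transitions during pull: the AT peel splits into two reversible
# sub-steps (a. ~45 pN, a'. ~49 pN), then the GC B-to-S (b. ~59 pN), then an
# irreversible full melt (c.) at high force with hysteretic rezip near 20 pN
# during relax. The full-melt force is not quantified experimentally
# ("high enough force"); 67 pN is a representative choice above the B-to-S.
construct = ATGC
salt = LOW_5MM
duplex_bp = 122
at_bp = 60
gc_bp = 62
linker_config = ONE_END

force_min_pN = 2.0
force_max_pN = 74.0
trap_velocity_nm_s = 50.0
trap_stiffness_pN_nm = 0.156
sample_rate_hz = 1000.0
temperature_C = 22.8
noise_sd_pN = 0.3
handle_contour_nm = 50.0

crossing_a_pN = 45.0
crossing_a2_pN = 49.0
crossing_b_pN = 59.0
half_peel_nt = 30
attempt_rate_hz = 40.0

full_melt_force_pN = 67.0
full_melt_x_nm = 2.0
rezip_force_pN = 20.0
rezip_x_nm = 4.0

# single-strand and S-form contours are calibrated against the 1 M
# measurements (salt enters only through the kinetic parameters)
peel_extension_nm = 8.0
peel_extension_at_pN = 62.1
total_extension_nm = 24.7
total_extension_at_pN = 64.3

hysteretic_pathway_probability = 1.0
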