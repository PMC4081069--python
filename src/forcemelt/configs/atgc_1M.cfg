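# ATGC: 122 bp composite duplex = 60 bp AT-rich core + 62 bp GC-rich part
# (click-linker site included in the GC count). High salt (1 M NaCl).
#
# Two reversible, bistable transitions in series: peeling of the AT part
# (intermediate state) followed by a B-to-S conversion of the GC part
# (fully stretched state). Modelled as a three-state Boltzmann ladder with
# B/I crossing at F_tr_I and I/S crossing at F_tr_II; F_tr_II is derived so
# the intermediate population peaks at the measured F_tr = 64.3 pN given
# the transition distances below.
construct = ATGC
salt = HIGH_1M
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

f_tr_I_pN = 62.1
f_tr_II_pN = 65.924
x_intermediate_nm = 8.0
x_stretched_nm = 19.9
# hopping attempt rate at the crossings (order-of-magnitude choice)
attempt_rate_hz = 40.0

# calibration constraints
peel_extension_nm = 8.0
peel_extension_at_pN = 62.1
total_extension_nm = 24.7
total_extension_at_pN = 64.3
# S-minus-I branch separation at F_tr_II; fixes the excess compliance of the
# intermediate branch (its smaller force-position gradient)
second_step_nm = 11.9

hysteretic_pathway_probability = 0.0
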