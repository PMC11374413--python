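# Bagrada hilaris (bagrada bug) -- fitted thermal-response parameters.
# Maturation uses the reduced high-inactivation-only Schoolfield form:
# too few data existed at low temperatures to fit the low-inactivation
# term, and the high-side parameters were assigned biologically
# realistic values rather than estimated.
name = "bagrada"

[birth]
peak = 3.586
t_opt = 306.6
breadth = 3.659

[maturation]
value_at_ref = 0.0168
arrhenius = 10671.0
t_ref = 297.0
a_high = 90000.0
t_half_high = 312.0

[juvenile_mortality]
value_at_ref = 0.0287
arrhenius = 6779.1
t_ref = 297.0

[adult_mortality]
value_at_ref = 0.0926
arrhenius = 12355.6
t_ref = 297.0
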