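# Murgantia histrionica (harlequin bug) -- fitted thermal-response
# parameters.  Maturation uses the full Schoolfield form; the
# low-inactivation pair was pinned at biologically reasonable values
# (half-activity at freezing) rather than estimated.
name = "harlequin"

[birth]
peak = 0.8921
t_opt = 298.3
breadth = 3.085

[maturation]
value_at_ref = 0.0138
arrhenius = 13480.0
t_ref = 297.0
a_low = -100000.0
t_half_low = 273.0
a_high = 48150.0
t_half_high = 303.8

[juvenile_mortality]
value_at_ref = 0.0343
arrhenius = 5743.0
t_ref = 297.0

[adult_mortality]
value_at_ref = 0.0029
arrhenius = 16824.0
t_ref = 297.0
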