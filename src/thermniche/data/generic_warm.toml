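# Generic warm-adapted ectotherm with realistic parameter values, used
# for qualitative model predictions.  Maturation is the plain
# exponential (rising-portion-only) form.
name = "generic_warm"

[birth]
peak = 2.2
t_opt = 302.0
breadth = 3.4

[maturation]
value_at_ref = 0.015
arrhenius = 11500.0
t_ref = 297.0

[juvenile_mortality]
value_at_ref = 0.03
arrhenius = 6260.0
t_ref = 297.0

[adult_mortality]
value_at_ref = 0.048
arrhenius = 14600.0
t_ref = 297.0
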