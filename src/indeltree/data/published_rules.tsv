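# Shipped classification rules for in-frame (3n) amino-acid indels.
# Columns: rule_id, conditions ("feature op value", ";"-joined), class, support, correct.
# The three high-coverage rules carry their training support/correct counts
# (confidence = correct/support).  default-* rules cover the remaining
# feature combinations at confidence 0.5 and may be overridden by editing
# this file or passing --rules.
rule4	pfam_fraction_affected == 0; in_repeat is false; in_disorder is true	neutral	317	291
rule5	pfam_fraction_affected == 0; in_repeat is false; in_disorder is false; left_base_conservation <= 1.405	neutral	82	59
rule10	pfam_fraction_affected > 0; in_disorder is false	damaging	284	254
default-repeat	pfam_fraction_affected == 0; in_repeat is true	damaging	0	0
default-conserved	pfam_fraction_affected == 0; in_repeat is false; in_disorder is false; left_base_conservation > 1.405	damaging	0	0
default-pfam-disordered	pfam_fraction_affected > 0; in_disorder is true	damaging	0	0
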