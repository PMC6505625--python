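happy	8.30
hahaha	7.94
fresh	7.26
cherry	7.04
pancake	6.96
piano	6.94
and	5.22
the	4.98
of	4.94
down	3.66
worse	2.70
crash	2.60
:(	2.36
war	1.80
jail	1.76
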