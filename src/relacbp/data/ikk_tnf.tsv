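# TNFα-induced IKK activity profile (fraction of maximum).
# Reconstruction of the canonical chronic-TNFα IKK input for this module:
# rapid activation peaking near 10 min, adaptation to a low sustained plateau.
# basal=0.005
time_min	ikk_activity
0.0	0.005
5.0	0.60
10.0	1.00
15.0	0.70
20.0	0.45
30.0	0.22
45.0	0.12
60.0	0.08
90.0	0.06
120.0	0.05
240.0	0.05
360.0	0.05
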