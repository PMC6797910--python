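# Synthetic 10-category amino-acid profile set (residue order ACDEFGHIKLMNPQRSTVWY).
# Chemically-motivated class-weighted profiles constructed for this package;
# NOT the published CAT category frequencies.
hydrophobic	0.160000	0.013333	0.013333	0.013333	0.013333	0.013333	0.013333	0.160000	0.013333	0.160000	0.160000	0.013333	0.013333	0.013333	0.013333	0.013333	0.013333	0.160000	0.013333	0.013333
charged	0.012500	0.012500	0.200000	0.200000	0.012500	0.012500	0.012500	0.012500	0.200000	0.012500	0.012500	0.012500	0.012500	0.012500	0.200000	0.012500	0.012500	0.012500	0.012500	0.012500
positive	0.011765	0.011765	0.011765	0.011765	0.011765	0.011765	0.266667	0.011765	0.266667	0.011765	0.011765	0.011765	0.011765	0.011765	0.266667	0.011765	0.011765	0.011765	0.011765	0.011765
negative	0.011111	0.011111	0.400000	0.400000	0.011111	0.011111	0.011111	0.011111	0.011111	0.011111	0.011111	0.011111	0.011111	0.011111	0.011111	0.011111	0.011111	0.011111	0.011111	0.011111
aromatic	0.012500	0.012500	0.012500	0.012500	0.200000	0.012500	0.200000	0.012500	0.012500	0.012500	0.012500	0.012500	0.012500	0.012500	0.012500	0.012500	0.012500	0.012500	0.200000	0.200000
polar	0.012500	0.012500	0.012500	0.012500	0.012500	0.012500	0.012500	0.012500	0.012500	0.012500	0.012500	0.200000	0.012500	0.200000	0.012500	0.200000	0.200000	0.012500	0.012500	0.012500
small	0.200000	0.200000	0.012500	0.012500	0.012500	0.200000	0.012500	0.012500	0.012500	0.012500	0.012500	0.012500	0.012500	0.012500	0.012500	0.200000	0.012500	0.012500	0.012500	0.012500
turn	0.012500	0.012500	0.200000	0.012500	0.012500	0.200000	0.012500	0.012500	0.012500	0.012500	0.012500	0.200000	0.200000	0.012500	0.012500	0.012500	0.012500	0.012500	0.012500	0.012500
hydroxyl	0.011765	0.011765	0.011765	0.011765	0.011765	0.011765	0.011765	0.011765	0.011765	0.011765	0.011765	0.011765	0.011765	0.011765	0.011765	0.266667	0.266667	0.011765	0.011765	0.266667
uniform	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000
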