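# Default SERCA1a segment map (crystal-structure residue numbering).
# TM helix and cytosolic-domain boundaries are conventional approximations;
# override with your own map for a different convention.
M1: [[49, 78]]
M2: [[89, 120]]
M3: [[254, 275]]
M4: [[295, 330]]
M5: [[740, 780]]
M6: [[787, 810]]
M7: [[828, 855]]
M8: [[897, 917]]
M9: [[931, 949]]
M10: [[964, 990]]
A-domain: [[1, 43], [124, 235]]
N-domain: [[360, 600]]
P-domain: [[330, 359], [601, 737]]
TM: [[49, 78], [89, 120], [254, 275], [295, 330], [740, 780], [787, 810], [828, 855], [897, 917], [931, 949], [964, 990]]
headpiece: [[1, 43], [124, 235], [330, 737]]
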