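# RNA nearest-neighbor stacking free energies, Watson-Crick steps
# (Turner 2004 rules, dG37 in kcal/mol). Step notation XY/WZ: top strand
# 5'-XY-3' paired with second strand written 5'-WZ-3', i.e. X pairs Z and
# Y pairs W. The ten unique values expand to all sixteen ordered WC steps
# by duplex flip symmetry.
# version: 1
step	dg
AA/UU	-0.93
AU/AU	-1.10
UA/UA	-1.33
CU/AG	-2.08
CA/UG	-2.11
GU/AC	-2.24
GA/UC	-2.35
CG/CG	-2.36
GG/CC	-3.26
GC/GC	-3.42
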