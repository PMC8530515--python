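# SYNTHETIC fixture: observed proteome synthesis fractions of core
# translation factors for three fast-growing bacteria.  The values are
# constructed, not measured: magnitudes emulate ribosome-profiling-derived
# synthesis fractions at fast growth (EF-Tu a few percent of the proteome,
# release/initiation factors 10-100x lower), and the EF-Tu/EF-G ratios are
# set exactly to the reported species values (E. coli 3.9, B. subtilis 2.7,
# V. natriegens 3.3).  Use for desk-scale testing only.
species	factor	synthesis_fraction
E. coli	EF-Tu	0.0546
E. coli	EF-G	0.0140
E. coli	EF-Ts	0.0042
E. coli	aaRS	0.0200
E. coli	IF1	0.0010
E. coli	IF2	0.0021
E. coli	IF3	0.0008
E. coli	RF1	0.00035
E. coli	RF2	0.00060
E. coli	RF4	0.0012
B. subtilis	EF-Tu	0.03996
B. subtilis	EF-G	0.0148
B. subtilis	EF-Ts	0.0035
B. subtilis	aaRS	0.0180
B. subtilis	IF1	0.0008
B. subtilis	IF2	0.0018
B. subtilis	IF3	0.0007
B. subtilis	RF1	0.00030
B. subtilis	RF2	0.00050
B. subtilis	RF4	0.0010
V. natriegens	EF-Tu	0.0495
V. natriegens	EF-G	0.0150
V. natriegens	EF-Ts	0.0040
V. natriegens	aaRS	0.0190
V. natriegens	IF1	0.0009
V. natriegens	IF2	0.0020
V. natriegens	IF3	0.00075
V. natriegens	RF1	0.00033
V. natriegens	RF2	0.00055
V. natriegens	RF4	0.0011
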