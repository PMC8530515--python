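# Core translation-factor parameter table (defaults).
# Lengths: canonical E. coli gene products (aa); aaRS is the effective mean
# length of the 20 synthetases; RFI is the RF1/RF2 lump; ribosome is the
# summed r-protein content; TC is the ternary complex (protein mass = EF-Tu).
# Diffusion (um^2/s): EF-Tu, ribosome, TC and 50S from in vivo single-molecule
# measurements; empty cells are estimated by cube-root length scaling.
# kon_hat (uM^-1 s^-1): TC<->ribosome is the measured reference (6.4); rates
# for reactions not involving the ribosome (EF-Tu<->aa-tRNA, aaRS<->tRNA,
# EF-Ts<->EF-Tu, 50S<->30S complex) are precomputed from the same diffusion
# scaling with the appropriate partner (free tRNA D = 8.0); empty cells are
# estimated at load time assuming the ribosome as partner.
# kcat_s = inf marks the binding-limited idealization.
name	step	length_aa	diffusion_um2_s	kon_hat_uM_s	kcat_s	codon_specific	per_protein_uses
IF1	initiation	72			inf	0	1
IF2	initiation	890			inf	0	1
IF3	initiation	180			inf	0	1
50S	initiation	4400	0.3	2.0	inf	0	1
EF-Tu	elongation	394	2.6	30.29	inf	0	avg_len
EF-Ts	elongation	283		15.72	inf	0	avg_len
EF-G	elongation	704			inf	0	avg_len
aaRS	elongation	650		29.14	inf	1	avg_len
TC	elongation	394	2.2	6.4	inf	1	avg_len
RFI	termination	362			inf	0	1
RF1	termination	360			inf	0	1
RF2	termination	365			inf	0	1
RF4	termination	185			inf	0	1
ribosome	reference	7300	0.04		inf	0	1
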