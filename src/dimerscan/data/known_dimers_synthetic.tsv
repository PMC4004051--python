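# Synthetic example registry of known dimeric motif complexes.
# These entries are fabricated stand-ins for a literature-curated gold
# standard; motif ids refer to a user-supplied library, orientation is the
# canonical strand pair, spacing may be a single integer or "lo..hi".
motif_id_1	motif_id_2	orientation	spacing	citation
SYN_HLH1	SYN_HLH1	+/-	0	synthetic example: convergent bHLH-like palindrome
SYN_NR1	SYN_NR1	+/+	3	synthetic example: direct-repeat nuclear-receptor-like pair
SYN_NR1	SYN_NR2	+/+	5	synthetic example: heterodimeric direct repeat
SYN_FKH1	SYN_ETS1	+/-	-2	synthetic example: overlapping composite element
SYN_HMG1	SYN_POU1	-/+	1	synthetic example: divergent pair, one intervening bp
SYN_ZF1	SYN_BZIP1	+/+	0..2	synthetic example: semi-rigid spacing range
SYN_BZIP1	SYN_BZIP1	+/-	-3	synthetic example: overlapping homodimeric palindrome
SYN_GATA1	SYN_HLH1	+/+	8	synthetic example: widely spaced heterodimer
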