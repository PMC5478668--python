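species	fa_substrate	fa_product	conversion	activity
Oryzias latipes	18:3n-3	18:4n-3	ND	Δ6
Oryzias latipes	18:2n-6	18:3n-6	ND	Δ6
Oryzias latipes	20:4n-3	20:5n-3	11.8	Δ5
Oryzias latipes	20:3n-6	20:4n-6	2.3	Δ5
Oryzias latipes	22:5n-3	22:6n-3	24.1	Δ4
Oryzias latipes	22:4n-6	22:5n-6	13.7	Δ4
Oreochromis niloticus	18:3n-3	18:4n-3	ND	Δ6
Oreochromis niloticus	18:2n-6	18:3n-6	ND	Δ6
Oreochromis niloticus	20:4n-3	20:5n-3	1.6	Δ5
Oreochromis niloticus	20:3n-6	20:4n-6	0.3	Δ5
Oreochromis niloticus	22:5n-3	22:6n-3	10.8	Δ4
Oreochromis niloticus	22:4n-6	22:5n-6	8.1	Δ4
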