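desaturase_id	conv_24_4n6	conv_24_5n3	control_label	control_product	conv_control	printed_ratio
ScyΔ6Fads2	29.3	34.3	18:3n-3	18:4n-3	41.9	0.82
AgΔ6Fads2	25.4	19.0	18:3n-3	18:4n-3	15.3	1.24
AjΔ6Fads2	14.0	15.8	18:3n-3	18:4n-3	17.8	0.89
DrΔ6Δ5Fads2	10.4	15.8	18:3n-3	18:4n-3	11.9	1.33
CgΔ6Δ5Fads2	29.9	28.1	18:3n-3	18:4n-3	31.5	0.89
SsΔ6Fads2	18.5	26.0	18:3n-3	18:4n-3	23.9	1.09
SsΔ5Fads2	1.4	6.4	20:4n-3	20:5n-3	3.4	1.88
OmΔ6Fads2	7.5	19.7	18:3n-3	18:4n-3	20.4	0.97
CeΔ6Δ5Fads2	4.2	9.0	18:3n-3	18:4n-3	22.9	0.39
CeΔ4Fads2	ND	ND	22:5n-3	22:6n-3	9.9	0.00
ScΔ6Δ5Fads2	6.0	7.4	18:3n-3	18:4n-3	36.4	0.20
ScΔ4Fads2	ND	ND	22:5n-3	22:6n-3	6.9	0.00
SaΔ6Fads2	4.8	6.5	18:3n-3	18:4n-3	15.0	0.43
NmΔ6Fads2	ND	ND	18:3n-3	18:4n-3	10.5	0.00
OnΔ4Fads2	ND	ND	22:5n-3	22:6n-3	4.5	0.00
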