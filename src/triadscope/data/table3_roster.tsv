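homoeolog_id	gene_name	subgenome	chromosome	arm	start_bp	end_bp	group_label
TaPP2C119	TaPP2C119_137_149	A	4A	S	50000	51999	ungrouped
TaPP2C137	TaPP2C119_137_149	B	4B	L	50000	51999	ungrouped
TaPP2C149	TaPP2C119_137_149	D	4D	L	50000	51999	ungrouped
TaPP2C121	TaPP2C121_135_147	A	4A	S	100000	101999	ungrouped
TaPP2C135	TaPP2C121_135_147	B	4B	L	100000	101999	ungrouped
TaPP2C147	TaPP2C121_135_147	D	4D	L	100000	101999	ungrouped
TaPP2C122	TaPP2C122_134_146	A	4A	S	150000	151999	ungrouped
TaPP2C134	TaPP2C122_134_146	B	4B	L	150000	151999	ungrouped
TaPP2C146	TaPP2C122_134_146	D	4D	L	150000	151999	ungrouped
TaPP2C123	TaPP2C123_133_145	A	4A	S	200000	201999	ungrouped
TaPP2C133	TaPP2C123_133_145	B	4B	L	200000	201999	ungrouped
TaPP2C145	TaPP2C123_133_145	D	4D	L	200000	201999	ungrouped
TaPP2C124	TaPP2C124_132_144	A	4A	S	250000	251999	ungrouped
TaPP2C132	TaPP2C124_132_144	B	4B	L	250000	251999	ungrouped
TaPP2C144	TaPP2C124_132_144	D	4D	L	250000	251999	ungrouped
TaPP2C126	TaPP2C126_130_141	A	4A	L	300000	301999	ungrouped
TaPP2C130	TaPP2C126_130_141	B	4B	S	300000	301999	ungrouped
TaPP2C141	TaPP2C126_130_141	D	4D	S	300000	301999	ungrouped
TaPP2C163	TaPP2C163_138_150	A	5A	L	350000	351999	ungrouped
TaPP2C138	TaPP2C163_138_150	B	4B	L	350000	351999	ungrouped
TaPP2C150	TaPP2C163_138_150	D	4D	L	350000	351999	ungrouped
TaPP2C164	TaPP2C164_139_151	A	5A	L	400000	401999	ungrouped
TaPP2C139	TaPP2C164_139_151	B	4B	L	400000	401999	ungrouped
TaPP2C151	TaPP2C164_139_151	D	4D	L	400000	401999	ungrouped
TaPP2C127	TaPP2C127_176_187	A	4A	L	450000	451999	ungrouped
TaPP2C176	TaPP2C127_176_187	B	5B	L	450000	451999	ungrouped
TaPP2C187	TaPP2C127_176_187	D	5D	L	450000	451999	ungrouped
TaPP2C224	TaPP2C224_129_246	A	7A	S	500000	501999	ungrouped
TaPP2C129	TaPP2C224_129_246	B	4A	L	500000	501999	ungrouped
TaPP2C246	TaPP2C224_129_246	D	7D	S	500000	501999	ungrouped
TaPP2C194	TaPP2C194_207_217	A	6A	S	550000	551999	ungrouped
TaPP2C207	TaPP2C194_207_217	B	6B	L	550000	551999	ungrouped
TaPP2C217	TaPP2C194_207_217	D	6D	S	550000	551999	ungrouped
TaPP2C195	TaPP2C195_205_218	A	6A	L	600000	601999	ungrouped
TaPP2C205	TaPP2C195_205_218	B	6B	S	600000	601999	ungrouped
TaPP2C218	TaPP2C195_205_218	D	6D	L	600000	601999	ungrouped
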