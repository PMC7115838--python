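target_accession	other_accession	other_proteome	relation
ACE95141.1	SeriatoporaSp_g7349	S_pistillata_2013	blastp_best_hit
PFX18785.1	aug_v2a.09809.t1	A_digitifera_2016	one_to_one
PFX18785.1	JR987773	A_millepora_2013	one_to_one
PFX18785.1	AGG36340.1	S_pistillata_2013	one_to_one
PFX30903.1	aug_v2a.06327.t1	A_digitifera_2016	one_to_one
PFX30903.1	JR972076.1	A_millepora_2013	one_to_one
PFX30903.1	AGG36350.1	S_pistillata_2013	one_to_one
XP_022779720.1	aug_v2a.08856.t1	A_digitifera_2016	one_to_one
XP_022779720.1	AGG36347.1	S_pistillata_2013	one_to_many
XP_022779720.1	AGG36349.1	S_pistillata_2013	one_to_many
XP_022780690.1	aug_v2a.11068.t1	A_digitifera_2016	one_to_many
XP_022780690.1	JT001945.1	A_digitifera_2016	one_to_many
XP_022780690.1	aug_v2a.01441.t1	A_digitifera_2016	one_to_many
XP_022780690.1	aug_v2a.01440.t1	A_digitifera_2016	one_to_many
XP_022780690.1	JT004498.1	A_digitifera_2016	one_to_many
XP_022780690.1	JR991407.1	A_digitifera_2016	one_to_many
XP_022780690.1	JR991407.1	A_millepora_2013	one_to_many
XP_022780690.1	JT004498.1	A_millepora_2013	one_to_many
XP_022780690.1	AGG36358.1	S_pistillata_2013	one_to_many
XP_022780690.1	AGG36357.1	S_pistillata_2013	one_to_many
XP_022780694.1	JR970990.1	A_millepora_2013	one_to_one
XP_022782398.1	JT001945.1	A_millepora_2013	one_to_one
XP_022782398.1	AGG36357.1	S_pistillata_2013	one_to_one
XP_022783415.1	aug_v2a.05945.t1	A_digitifera_2016	one_to_one
XP_022783415.1	JT016638.1	A_millepora_2013	one_to_one
XP_022783415.1	AGG36341.1	S_pistillata_2013	one_to_many
XP_022783415.1	AGG36335.1	S_pistillata_2013	one_to_many
XP_022783415.1	AGE45658.1	S_pistillata_2013	one_to_many
XP_022783415.1	AGG36343.1	S_pistillata_2013	one_to_many
XP_022786918.1	AGG36338.1	S_pistillata_2013	one_to_one
XP_022788227.1	aug_v2a.24015.t1	A_digitifera_2016	one_to_one
XP_022788227.1	JT019463.1	A_millepora_2013	one_to_one
XP_022794122.1	aug_v2a.18631.t1	A_digitifera_2016	one_to_one
XP_022794122.1	JR976690.1	A_millepora_2013	one_to_one
XP_022794736.1	aug_v2a.09968.t1	A_digitifera_2016	one_to_many
XP_022794736.1	aug_v2a.09969.t1	A_digitifera_2016	one_to_many
XP_022794736.1	JT011118.1	A_millepora_2013	one_to_many
XP_022794736.1	JR994474.1	A_millepora_2013	one_to_many
XP_022794736.1	AGG36355.1	S_pistillata_2013	one_to_many
XP_022794736.1	AGG36356.1	S_pistillata_2013	one_to_many
XP_022794736.1	AGG36345.1	S_pistillata_2013	one_to_many
XP_022796981.1	JT014391.1	A_millepora_2013	one_to_one
XP_022796981.1	AGC24391.1	S_pistillata_2013	one_to_one
XP_022796982.1	AGC24391.1	S_pistillata_2013	one_to_one
XP_022804012.1	aug_v2a.15580.t1	A_digitifera_2016	one_to_many
XP_022804012.1	aug_v2a.06123.t1	A_digitifera_2016	one_to_many
XP_022804012.1	JR980881.1	A_digitifera_2016	one_to_many
XP_022804012.1	aug_v2a.24512.t1	A_digitifera_2016	one_to_many
XP_022804012.1	aug_v2a.06122.t1	A_digitifera_2016	one_to_many
XP_022804012.1	JR980881.1	A_millepora_2013	one_to_one
XP_022804012.1	AGG36344.1	S_pistillata_2013	one_to_many
XP_022804012.1	AGG36352.1	S_pistillata_2013	one_to_many
XP_022806326.1	aug_v2a.07627.t1	A_digitifera_2016	one_to_one
XP_022806326.1	JN631095.1	A_millepora_2013	one_to_one
XP_022806326.1	AGG36346.1	S_pistillata_2013	one_to_one
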