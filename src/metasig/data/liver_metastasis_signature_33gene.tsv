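feature_id	direction	source_probes
MMP3	down_in_HM	205828_at
ACTG2	down_in_HM	202274_at
NDNF	down_in_HM	219747_at
CDH11	down_in_HM	207172_s_at
COL5A3	down_in_HM	52255_s_at
COL7A1	down_in_HM	204136_at
CXCL14	down_in_HM	218002_s_at
CXCL5	down_in_HM	214974_x_at
ESM1	down_in_HM	208394_x_at
IGHD	down_in_HM	216557_x_at
IGHG1	down_in_HM	216557_x_at
IL1B	down_in_HM	39402_at
MAB21L2	down_in_HM	210302_s_at
MCAM	down_in_HM	209086_x_at
OLFML2A	down_in_HM	213075_at
P2RY14	down_in_HM	206637_at
PDE4B	down_in_HM	203708_at
PRKAR2B	down_in_HM	203680_at
PSMB2	down_in_HM	201404_x_at
RGS5	down_in_HM	209070_s_at
RUNX1T1	down_in_HM	205529_s_at
TPSAB1	down_in_HM	215382_x_at
VWF	down_in_HM	202112_at
WNT5A	down_in_HM	205990_s_at;213425_at
ZNF117	down_in_HM	207117_at
CYP1B1	up_in_HM	202437_s_at;202436_s_at
COLEC11	up_in_HM	219873_at
CRP	up_in_HM	205753_at
FGB	up_in_HM	204988_at
HABP2	up_in_HM	206010_at
SERPINA3	up_in_HM	202376_at
SPP1	up_in_HM	209875_s_at
TIMP1	up_in_HM	201666_at
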