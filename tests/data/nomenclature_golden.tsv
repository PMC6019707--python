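input	dialect	canonical
hla_c_834	underscore	C*834
DQB1*58:71Q	colon	DQB1*58:71Q
C*17:24	colon	C*17:24
hla_dqb1_40l	underscore	DQB1*40L
hla_c_14_059_06_008s	underscore	C*14:059:06:008S
hla_dqb1_16l	underscore	DQB1*16L
hla_b_851_58q	underscore	B*851:58Q
B*06:67:28 Q	colon	B*06:67:28Q
B*04S	colon	B*04S
hla_a_046_247_076_87	underscore	A*046:247:076:87
DRB1*746:25S	colon	DRB1*746:25S
hla_c_79_086_38_626n	underscore	C*79:086:38:626N
DRB1*006:35	colon	DRB1*006:35
C*197:69:50:23	colon	C*197:69:50:23
DRB1*692	colon	DRB1*692
DRB1*83 N	colon	DRB1*83N
A*15:710:22:26 S	colon	A*15:710:22:26S
A*33:052:191:90S	colon	A*33:052:191:90S
HLA-A*034:92:40:645Q	colon	A*034:92:40:645Q
hla_c_74_48	underscore	C*74:48
C*02:199 Q	colon	C*02:199Q
hla_c_85_500_78_089	underscore	C*85:500:78:089
C*40L	colon	C*40L
C*025:431Q	colon	C*025:431Q
C*94:68:240N	colon	C*94:68:240N
C*27:84:063:010 S	colon	C*27:84:063:010S
DRB1*882:92	colon	DRB1*882:92
DQB1*98:28Q	colon	DQB1*98:28Q
C*61:80:96:308S	colon	C*61:80:96:308S
HLA-B*98:054	colon	B*98:054
A*21:051	colon	A*21:051
A*084 L	colon	A*084L
B*48:68:026:48 Q	colon	B*48:68:026:48Q
hla_b_05_74_086q	underscore	B*05:74:086Q
A*95:88:324:68Q	colon	A*95:88:324:68Q
HLA-C*08:22:91:114	colon	C*08:22:91:114
HLA-DRB1*23:92:48:062N	colon	DRB1*23:92:48:062N
B*042:75 Q	colon	B*042:75Q
DQB1*073 Q	colon	DQB1*073Q
DRB1*52:31	colon	DRB1*52:31
DRB1*63:77:077:046	colon	DRB1*63:77:077:046
HLA-B*076S	colon	B*076S
hla_a_169_90_599_080n	underscore	A*169:90:599:080N
B*062:71	colon	B*062:71
B*55S	colon	B*55S
hla_a_367s	underscore	A*367S
hla_a_34_067_026_083q	underscore	A*34:067:026:083Q
HLA-DRB1*879:00	colon	DRB1*879:00
DQB1*204:088:51:062Q	colon	DQB1*204:088:51:062Q
hla_drb1_006_003_18_43s	underscore	DRB1*006:003:18:43S
hla_c_53_42l	underscore	C*53:42L
DRB1*48:44 N	colon	DRB1*48:44N
A*65:472:06:110 S	colon	A*65:472:06:110S
DQB1*071:380:45S	colon	DQB1*071:380:45S
HLA-B*072:69	colon	B*072:69
DQB1*035:045:90	colon	DQB1*035:045:90
hla_b_658_099q	underscore	B*658:099Q
HLA-B*14:20:096:756	colon	B*14:20:096:756
hla_a_096_95_719l	underscore	A*096:95:719L
DRB1*069:053:216	colon	DRB1*069:053:216
A*80:081Q	colon	A*80:081Q
A*27S	colon	A*27S
hla_b_79	underscore	B*79
HLA-C*060:42	colon	C*060:42
DRB1*069:92:98:61L	colon	DRB1*069:92:98:61L
HLA-DRB1*75:016N	colon	DRB1*75:016N
hla_a_31_969_54_134s	underscore	A*31:969:54:134S
C*72:82:84Q	colon	C*72:82:84Q
B*092	colon	B*092
B*31:847	colon	B*31:847
B*15:410	colon	B*15:410
hla_dqb1_235	underscore	DQB1*235
DQB1*43	colon	DQB1*43
DRB1*34:086:088:053S	colon	DRB1*34:086:088:053S
C*073	colon	C*073
hla_a_55_82_073_95l	underscore	A*55:82:073:95L
DRB1*084:071Q	colon	DRB1*084:071Q
B*042:70:03:60 S	colon	B*042:70:03:60S
hla_b_69_39_13_17l	underscore	B*69:39:13:17L
A*74:014	colon	A*74:014
A*25:31:78:015 Q	colon	A*25:31:78:015Q
hla_dqb1_087_753q	underscore	DQB1*087:753Q
hla_b_06_25q	underscore	B*06:25Q
hla_a_005s	underscore	A*005S
B*98:750:27:089L	colon	B*98:750:27:089L
A*01:27S	colon	A*01:27S
DRB1*007:56L	colon	DRB1*007:56L
hla_drb1_82_89	underscore	DRB1*82:89
HLA-C*011:48:052:063N	colon	C*011:48:052:063N
hla_dqb1_069q	underscore	DQB1*069Q
C*32:004:634:450	colon	C*32:004:634:450
hla_b_711_22s	underscore	B*711:22S
HLA-B*51:095:97:28N	colon	B*51:095:97:28N
B*032:65:045:052N	colon	B*032:65:045:052N
hla_a_923_029_34_50s	underscore	A*923:029:34:50S
DQB1*283:68:199:053	colon	DQB1*283:68:199:053
HLA-A*009:004:471	colon	A*009:004:471
hla_a_666_462s	underscore	A*666:462S
hla_a_087_448n	underscore	A*087:448N
hla_a_63	underscore	A*63
hla_a_566_66	underscore	A*566:66
C*70:49	colon	C*70:49
DRB1*349:075:410:47	colon	DRB1*349:075:410:47
hla_b_038_86_89l	underscore	B*038:86:89L
C*70:07:89S	colon	C*70:07:89S
HLA-DQB1*60:48:801	colon	DQB1*60:48:801
HLA-DRB1*48:98	colon	DRB1*48:98
A*90:029L	colon	A*90:029L
hla_drb1_069s	underscore	DRB1*069S
HLA-DQB1*013:29:349:40N	colon	DQB1*013:29:349:40N
A*09	colon	A*09
A*32:96:81:430	colon	A*32:96:81:430
HLA-A*064:098:65:037	colon	A*064:098:65:037
HLA-C*305	colon	C*305
hla_b_065n	underscore	B*065N
HLA-B*28:026:76	colon	B*28:026:76
hla_drb1_040_534_90	underscore	DRB1*040:534:90
hla_c_029_02_070l	underscore	C*029:02:070L
DRB1*078:030 L	colon	DRB1*078:030L
hla_c_096_373_94_003s	underscore	C*096:373:94:003S
hla_a_083_54_085_927	underscore	A*083:54:085:927
DRB1*18:227:068	colon	DRB1*18:227:068
DRB1*523:046:029:07 L	colon	DRB1*523:046:029:07L
A*085:076:97:082	colon	A*085:076:97:082
DQB1*005:50:042	colon	DQB1*005:50:042
hla_dqb1_369_43_041_062l	underscore	DQB1*369:43:041:062L
DQB1*90L	colon	DQB1*90L
DRB1*065:007:31:024S	colon	DRB1*065:007:31:024S
HLA-A*370	colon	A*370
hla_b_33_16q	underscore	B*33:16Q
DRB1*23	colon	DRB1*23
hla_dqb1_02_322	underscore	DQB1*02:322
A*05:54 N	colon	A*05:54N
hla_b_05_227_44_059s	underscore	B*05:227:44:059S
A*80:059:09N	colon	A*80:059:09N
DRB1*078Q	colon	DRB1*078Q
hla_drb1_52_328_95_38	underscore	DRB1*52:328:95:38
hla_b_06_072	underscore	B*06:072
DRB1*091:055:34Q	colon	DRB1*091:055:34Q
C*83	colon	C*83
DQB1*067:795:20 N	colon	DQB1*067:795:20N
A*075 L	colon	A*075L
B*72	colon	B*72
C*002:296L	colon	C*002:296L
HLA-A*78:75:93:52 Q	colon	A*78:75:93:52Q
DRB1*43S	colon	DRB1*43S
HLA-DQB1*78L	colon	DQB1*78L
HLA-DQB1*57:084:31:745	colon	DQB1*57:084:31:745
HLA-B*066:036S	colon	B*066:036S
hla_dqb1_46_66_123_064s	underscore	DQB1*46:66:123:064S
C*33:76:49N	colon	C*33:76:49N
HLA-DQB1*44 N	colon	DQB1*44N
DQB1*133	colon	DQB1*133
hla_c_149_866_16	underscore	C*149:866:16
hla_dqb1_031_052	underscore	DQB1*031:052
DQB1*818:53N	colon	DQB1*818:53N
C*52:162 N	colon	C*52:162N
C*56:67	colon	C*56:67
HLA-DRB1*043:08S	colon	DRB1*043:08S
hla_dqb1_91_31s	underscore	DQB1*91:31S
hla_drb1_28_71_71s	underscore	DRB1*28:71:71S
C*178:40	colon	C*178:40
DQB1*88:148:042:027N	colon	DQB1*88:148:042:027N
hla_b_089_13_502	underscore	B*089:13:502
HLA-DQB1*849:38:469 Q	colon	DQB1*849:38:469Q
hla_dqb1_917_25l	underscore	DQB1*917:25L
HLA-DRB1*096:36:002 Q	colon	DRB1*096:36:002Q
B*017:011:52:061N	colon	B*017:011:52:061N
A*006:80:033	colon	A*006:80:033
HLA-C*716:39:039:050	colon	C*716:39:039:050
hla_dqb1_66_427q	underscore	DQB1*66:427Q
HLA-C*05:070:898:041Q	colon	C*05:070:898:041Q
hla_a_071_43_257_31	underscore	A*071:43:257:31
hla_b_055_524_58n	underscore	B*055:524:58N
HLA-DQB1*28:637:17:393L	colon	DQB1*28:637:17:393L
hla_dqb1_70	underscore	DQB1*70
hla_a_04_617_002_043n	underscore	A*04:617:002:043N
A*56:76:384:18	colon	A*56:76:384:18
hla_dqb1_19_333n	underscore	DQB1*19:333N
DRB1*99:80:03L	colon	DRB1*99:80:03L
DRB1*38:85:088:73Q	colon	DRB1*38:85:088:73Q
B*342:842	colon	B*342:842
hla_drb1_878_64n	underscore	DRB1*878:64N
C*00:07:566S	colon	C*00:07:566S
hla_b_90s	underscore	B*90S
hla_drb1_53_17_33s	underscore	DRB1*53:17:33S
HLA-DQB1*11:02:11	colon	DQB1*11:02:11
HLA-DRB1*864 N	colon	DRB1*864N
hla_b_23l	underscore	B*23L
A*020	colon	A*020
DRB1*068:506:025:544L	colon	DRB1*068:506:025:544L
HLA-A*853:909:052:005	colon	A*853:909:052:005
HLA-DRB1*125:506:44L	colon	DRB1*125:506:44L
HLA-DQB1*63	colon	DQB1*63
hla_c_57_77q	underscore	C*57:77Q
hla_a_51_12_26_031	underscore	A*51:12:26:031
DRB1*940:62:178:66	colon	DRB1*940:62:178:66
HLA-DQB1*83	colon	DQB1*83
hla_c_046n	underscore	C*046N
HLA-B*040L	colon	B*040L
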