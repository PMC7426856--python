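category_id,icd10_prefix
MI,I21
MI,I22
MI,I252
CHF,I099
CHF,I110
CHF,I130
CHF,I132
CHF,I255
CHF,I420
CHF,I425
CHF,I426
CHF,I427
CHF,I428
CHF,I429
CHF,I43
CHF,I50
CHF,P290
PVD,I70
PVD,I71
PVD,I731
PVD,I738
PVD,I739
PVD,I771
PVD,I790
PVD,I792
PVD,K551
PVD,K558
PVD,K559
PVD,Z958
PVD,Z959
CVD,G45
CVD,G46
CVD,H340
CVD,I60
CVD,I61
CVD,I62
CVD,I63
CVD,I64
CVD,I65
CVD,I66
CVD,I67
CVD,I68
CVD,I69
DEME,F00
DEME,F01
DEME,F02
DEME,F03
DEME,F051
DEME,G30
DEME,G311
CPD,I278
CPD,I279
CPD,J40
CPD,J41
CPD,J42
CPD,J43
CPD,J44
CPD,J45
CPD,J46
CPD,J47
CPD,J60
CPD,J61
CPD,J62
CPD,J63
CPD,J64
CPD,J65
CPD,J66
CPD,J67
CPD,J684
CPD,J701
CPD,J703
CTD,M05
CTD,M06
CTD,M315
CTD,M32
CTD,M33
CTD,M34
CTD,M351
CTD,M353
CTD,M360
UD,K25
UD,K26
UD,K27
UD,K28
MLD,B18
MLD,K700
MLD,K701
MLD,K702
MLD,K703
MLD,K709
MLD,K713
MLD,K714
MLD,K715
MLD,K717
MLD,K73
MLD,K74
MLD,K760
MLD,K762
MLD,K763
MLD,K764
MLD,K768
MLD,K769
MLD,Z944
DM,E100
DM,E101
DM,E106
DM,E108
DM,E109
DM,E110
DM,E111
DM,E116
DM,E118
DM,E119
DM,E120
DM,E121
DM,E126
DM,E128
DM,E129
DM,E130
DM,E131
DM,E136
DM,E138
DM,E139
DM,E140
DM,E141
DM,E146
DM,E148
DM,E149
HEMI,G041
HEMI,G114
HEMI,G801
HEMI,G802
HEMI,G81
HEMI,G82
HEMI,G830
HEMI,G831
HEMI,G832
HEMI,G833
HEMI,G834
HEMI,G839
DMW,E102
DMW,E103
DMW,E104
DMW,E105
DMW,E107
DMW,E112
DMW,E113
DMW,E114
DMW,E115
DMW,E117
DMW,E122
DMW,E123
DMW,E124
DMW,E125
DMW,E127
DMW,E132
DMW,E133
DMW,E134
DMW,E135
DMW,E137
DMW,E142
DMW,E143
DMW,E144
DMW,E145
DMW,E147
MSRD,I120
MSRD,I131
MSRD,N032
MSRD,N033
MSRD,N034
MSRD,N035
MSRD,N036
MSRD,N037
MSRD,N052
MSRD,N053
MSRD,N054
MSRD,N055
MSRD,N056
MSRD,N057
MSRD,N18
MSRD,N19
MSRD,N250
MSRD,Z490
MSRD,Z491
MSRD,Z492
MSRD,Z940
MSRD,Z992
TUM,C00
TUM,C01
TUM,C02
TUM,C03
TUM,C04
TUM,C05
TUM,C06
TUM,C07
TUM,C08
TUM,C09
TUM,C10
TUM,C11
TUM,C12
TUM,C13
TUM,C14
TUM,C15
TUM,C16
TUM,C17
TUM,C18
TUM,C19
TUM,C20
TUM,C21
TUM,C22
TUM,C23
TUM,C24
TUM,C25
TUM,C26
TUM,C30
TUM,C31
TUM,C32
TUM,C33
TUM,C34
TUM,C37
TUM,C38
TUM,C39
TUM,C40
TUM,C41
TUM,C43
TUM,C45
TUM,C46
TUM,C47
TUM,C48
TUM,C49
TUM,C50
TUM,C51
TUM,C52
TUM,C53
TUM,C54
TUM,C55
TUM,C56
TUM,C57
TUM,C58
TUM,C60
TUM,C61
TUM,C62
TUM,C63
TUM,C64
TUM,C65
TUM,C66
TUM,C67
TUM,C68
TUM,C69
TUM,C70
TUM,C71
TUM,C72
TUM,C73
TUM,C74
TUM,C75
TUM,C76
TUM,C81
TUM,C82
TUM,C83
TUM,C84
TUM,C85
TUM,C88
TUM,C90
TUM,C91
TUM,C92
TUM,C93
TUM,C94
TUM,C95
TUM,C96
TUM,C97
MSLD,I850
MSLD,I859
MSLD,I864
MSLD,I982
MSLD,K704
MSLD,K711
MSLD,K721
MSLD,K729
MSLD,K765
MSLD,K766
MSLD,K767
MST,C77
MST,C78
MST,C79
MST,C80
AIDS,B20
AIDS,B21
AIDS,B22
AIDS,B24
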