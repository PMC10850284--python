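panel	gene	sign	source
IOI_6	ADM	+1	inflammation panel, full six-gene form
IOI_6	CD177	+1	inflammation panel, full six-gene form
IOI_6	FAM20A	+1	inflammation panel, full six-gene form
IOI_6	ITGA7	+1	inflammation panel, full six-gene form
IOI_6	MMP9	+1	inflammation panel, full six-gene form
IOI_6	OLAH	+1	inflammation panel, full six-gene form
IOI_5	ADM	+1	inflammation panel without CD177
IOI_5	FAM20A	+1	inflammation panel without CD177
IOI_5	OLAH	+1	inflammation panel without CD177
IOI_5	ITGA7	+1	inflammation panel without CD177
IOI_5	MMP9	+1	inflammation panel without CD177
IOI_3	ADM	+1	minimal three-gene inflammation panel
IOI_3	FAM20A	+1	minimal three-gene inflammation panel
IOI_3	OLAH	+1	minimal three-gene inflammation panel
IOI_2	FAM20A	+1	minimal two-gene inflammation panel
IOI_2	OLAH	+1	minimal two-gene inflammation panel
SOS_5	CETP	+1	five-gene SIRS/sepsis discriminator (figure signs)
SOS_5	CMTM5	+1	five-gene SIRS/sepsis discriminator (figure signs)
SOS_5	MIA	+1	five-gene SIRS/sepsis discriminator (figure signs)
SOS_5	MPP3	-1	five-gene SIRS/sepsis discriminator (figure signs)
SOS_5	PLA2G7	-1	five-gene SIRS/sepsis discriminator (figure signs)
SOS_5_ALT	CMTM5	+1	five-gene discriminator, table-variant signs (MIA negative)
SOS_5_ALT	CETP	+1	five-gene discriminator, table-variant signs (MIA negative)
SOS_5_ALT	PLA2G7	-1	five-gene discriminator, table-variant signs (MIA negative)
SOS_5_ALT	MIA	-1	five-gene discriminator, table-variant signs (MIA negative)
SOS_5_ALT	MPP3	-1	five-gene discriminator, table-variant signs (MIA negative)
SOS_ABDM	CMTM5	+1	abdominal-sepsis discriminator
SOS_ABDM	ITGB3	+1	abdominal-sepsis discriminator
SOS_ABDM	ARHGEF10L	-1	abdominal-sepsis discriminator
SOS_ABDM	GPR124	-1	abdominal-sepsis discriminator
SOS_ABDM	PLA2G7	-1	abdominal-sepsis discriminator
SOS_PLMN	CETP	+1	pulmonary-sepsis discriminator
SOS_PLMN	MIA	+1	pulmonary-sepsis discriminator
SOS_PLMN	PLXNB3	+1	pulmonary-sepsis discriminator
SOS_PLMN	MPP3	-1	pulmonary-sepsis discriminator
SOS_8A	CMTM5	+1	eight-gene combined discriminator A
SOS_8A	ITGB3	+1	eight-gene combined discriminator A
SOS_8A	PLA2G7	-1	eight-gene combined discriminator A
SOS_8A	ARHGEF10L	-1	eight-gene combined discriminator A
SOS_8A	GPR124	-1	eight-gene combined discriminator A
SOS_8A	CETP	+1	eight-gene combined discriminator A
SOS_8A	MIA	+1	eight-gene combined discriminator A
SOS_8A	MPP3	-1	eight-gene combined discriminator A
SOS_8B	CMTM5	+1	eight-gene combined discriminator B
SOS_8B	ITGB3	+1	eight-gene combined discriminator B
SOS_8B	PLA2G7	-1	eight-gene combined discriminator B
SOS_8B	ARHGEF10L	-1	eight-gene combined discriminator B
SOS_8B	CETP	+1	eight-gene combined discriminator B
SOS_8B	MIA	+1	eight-gene combined discriminator B
SOS_8B	PLXNB3	+1	eight-gene combined discriminator B
SOS_8B	MPP3	-1	eight-gene combined discriminator B
SEPTICYTE	PLAC8	+1	Septicyte Lab signature
SEPTICYTE	PLA2G7	-1	Septicyte Lab signature
SEPTICYTE	LAMP1	+1	Septicyte Lab signature
SEPTICYTE	CEACAM4	-1	Septicyte Lab signature
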