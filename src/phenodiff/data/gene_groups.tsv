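gene	stage	n_patients	inheritance
DPM1	synthesis	3	AR
DPM2	synthesis	3	AR
DPM3	synthesis	2	AR
MPDU1	synthesis	1	AR
PIGA	synthesis	21	XLR
PIGB	synthesis	0
PIGC	synthesis	3	AR
PIGF	synthesis	0
PIGG	synthesis	5	AR
PIGH	synthesis	1	AR
PIGL	synthesis	8	AR
PIGM	synthesis	3	AR
PIGN	synthesis	11	AR
PIGO	synthesis	9	AR
PIGP	synthesis	2	AR
PIGQ	synthesis	1
PIGV	synthesis	13	AR
PIGW	synthesis	3	AR
PIGX	synthesis	0
PIGY	synthesis	4	AR
GPAA1	transamidase_remodeling	10	AR
MPPE1	transamidase_remodeling	0
PGAP1	transamidase_remodeling	7	AR
PGAP2	transamidase_remodeling	10	AR
PGAP3	transamidase_remodeling	22	AR
PIGK	transamidase_remodeling	0
PIGS	transamidase_remodeling	0	AR
PIGT	transamidase_remodeling	10	AD/AR
PIGU	transamidase_remodeling	0
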