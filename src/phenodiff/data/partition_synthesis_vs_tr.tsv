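# partition: synthesis_vs_transamidase_remodeling
gene	group	synonym_of
DPM1	synthesis
DPM2	synthesis
DPM3	synthesis
MPDU1	synthesis
PIGA	synthesis
PIGB	synthesis
PIGC	synthesis
PIGF	synthesis
PIGG	synthesis
PIGH	synthesis
PIGL	synthesis
PIGM	synthesis
PIGN	synthesis
PIGO	synthesis
PIGP	synthesis
PIGQ	synthesis
PIGV	synthesis
PIGW	synthesis
PIGX	synthesis
PIGY	synthesis
GPAA1	transamidase_remodeling
PGAP1	transamidase_remodeling
PGAP2	transamidase_remodeling
PGAP3	transamidase_remodeling
PGAP5	transamidase_remodeling
PIGK	transamidase_remodeling
PIGS	transamidase_remodeling
PIGT	transamidase_remodeling
PIGU	transamidase_remodeling
MPPE1		PGAP5
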