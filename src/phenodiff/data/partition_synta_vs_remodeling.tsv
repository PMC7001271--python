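# partition: synthesis_transamidase_vs_remodeling
gene	group	synonym_of
DPM1	synthesis_transamidase
DPM2	synthesis_transamidase
DPM3	synthesis_transamidase
MPDU1	synthesis_transamidase
PIGA	synthesis_transamidase
PIGB	synthesis_transamidase
PIGC	synthesis_transamidase
PIGF	synthesis_transamidase
PIGG	synthesis_transamidase
PIGH	synthesis_transamidase
PIGL	synthesis_transamidase
PIGM	synthesis_transamidase
PIGN	synthesis_transamidase
PIGO	synthesis_transamidase
PIGP	synthesis_transamidase
PIGQ	synthesis_transamidase
PIGV	synthesis_transamidase
PIGW	synthesis_transamidase
PIGX	synthesis_transamidase
PIGY	synthesis_transamidase
GPAA1	synthesis_transamidase
PIGK	synthesis_transamidase
PIGS	synthesis_transamidase
PIGT	synthesis_transamidase
PIGU	synthesis_transamidase
PGAP1	remodeling
PGAP2	remodeling
PGAP3	remodeling
PGAP5	remodeling
MPPE1		PGAP5
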