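family	clade	core_motifs	tail_rule	tail_motifs	notes
MaSp1	MaSp1	GGAGQGGY	poly_A	SSSVAISL,ISISAAAS	core reconstructed; tails mix poly-A with SSSVAISL/ISISAAAS
MaSp2	MaSp2	GPGSQ,GPGQQ	poly_A		Caerostris MaSp2 uses GPGSQ (QQ->SQ)
MaSp3	MaSp3	SGGRGGY,DGGRGGY	poly_A		SGGRGGY (D->S variant of Araneidae DGGRGGY); tail rule reconstructed
MaSp4	MaSp2	GPGPQ	poly_X	VSVVSTTVS	no poly-A; neutral-residue VSVVSTTVS tail; NTD clusters with MaSp2
MaSp5	MaSp5	GGLGGSG,GSGGR	none		tandem GGLGGSG/GSGGR only; no tail portion
MiSp1B	MiSp	GGAGGYG	poly_GA		core reconstructed; typical MiSp poly-A/GA tail
MiSp1C	MiSp	GGAGGYG	poly_X	VSVVSTTVS	core reconstructed; alternative poly-X tail
MiSp1D	MiSp	GGAGGYG	poly_A		core reconstructed; typical MiSp poly-A/GA tail
Flag	Flag	GPGGA	none		core reconstructed; flagelliform elastic motif
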