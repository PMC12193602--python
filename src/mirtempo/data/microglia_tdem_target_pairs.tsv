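mirna_id	gene_id	phase	mirna_abundant
miR-146a-5p	Camk2d	late	1
miR-155-3p	Dnajb2	early	0
miR-155-5p	Hbp1	late	1
miR-155-5p	Il6ra	late	1
miR-155-5p	Inpp5d	late	1
miR-155-5p	Jarid2	late	1
miR-7a-5p	Mbp	late	1
miR-155-5p	Mfsd6	late	1
miR-365-3p	Mfsd6	late	0
miR-155-3p	Mitf	early	0
miR-146a-5p	Mllt3	late	1
miR-146b-5p	Mllt3	late	0
miR-146b-5p	Nfkb1	late	0
miR-7a-5p	Nlrp3	late	1
miR-146a-5p	Nos2	late	1
miR-7a-5p	Pax6	late	1
miR-132-5p	Pik3r1	early	0
miR-155-5p	Ptprj	late	1
miR-146a-5p	Relb	late	1
miR-155-5p	S1pr1	late	1
miR-132-5p	Tnf	early	0
miR-155-5p	Trp53inp1	late	1
miR-155-5p	Tspan14	late	1
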