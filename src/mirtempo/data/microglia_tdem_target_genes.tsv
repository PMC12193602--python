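gene_id	gene_name	fdr	avg_cpm	fc_3h_to_8h	fc_8h_vs_nt
Camk2d	Calcium/calmodulin-dependent protein kinase II, delta	1.2e-18	47.2	0.50	1.31
Dnajb2	DnaJ heat shock protein family (Hsp40) member B2	1.4e-15	16.0	2.17	1.90
Hbp1	High mobility group box transcription factor 1	3.2e-14	16.3	2.05	0.68
Il6ra	Interleukin 6 receptor, alpha	8.2e-17	18.3	2.58	0.54
Inpp5d	Inositol polyphosphate-5-phosphatase D	5.2e-25	178.1	2.20	1.04
Jarid2	Jumonji, AT rich interactive domain 2	6.5e-21	35.0	0.42	2.29
Mbp	Myelin basic protein	4.7e-21	71.5	2.10	0.54
Mfsd6	Major facilitator superfamily domain containing 6	4.9e-22	116.0	2.06	1.35
Mitf	Melanogenesis associated transcription factor	1.3e-28	354.5	0.34	1.05
Mllt3	Myeloid/lymphoid or mixed-lineage leukemia; translocated to, 3	2.9e-14	12.0	2.41	0.71
Nfkb1	Nuclear factor of kappa light polypeptide gene enhancer in B cells 1, p105	3.6e-26	523.3	0.43	2.59
Nlrp3	NLR family, pyrin domain containing 3	1.6e-29	1000.0	0.25	3.85
Nos2	Nitric oxide synthase 2, inducible	6.0e-17	22.6	3.10	39.13
Pax6	Paired box 6	6.2e-14	12.6	2.53	0.50
Pik3r1	Phosphoinositide-3-kinase regulatory subunit 1	1.2e-20	47.4	2.16	0.81
Ptprj	Protein tyrosine phosphatase, receptor type, J	1.0e-22	392.8	0.42	1.89
Relb	Avian reticuloendotheliosis viral (v-rel) oncogene related B	3.5e-26	56.2	0.34	1.10
S1pr1	Sphingosine-1-phosphate receptor 1	2.1e-15	10.9	4.13	0.30
Tnf	Tumor necrosis factor	4.8e-28	5250.7	0.29	18.92
Trp53inp1	Transformation related protein 53 inducible nuclear protein 1	1.1e-16	18.3	3.24	0.57
Tspan14	Tetraspanin 14	9.2e-20	41.9	2.32	0.94
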