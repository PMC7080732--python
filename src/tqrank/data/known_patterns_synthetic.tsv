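# Synthetic stand-in catalogue of known expression patterns of the
# 16-cell ascidian embryo.  Columns: gene_id, one 0/1 column per cell type
# in canonical order (a5.3 a5.4 b5.3 b5.4 A5.1 A5.2 B5.1 B5.2), then any
# alternate acceptable patterns as 8-character bit strings.  Assembled from
# well-known marker genes for demonstration and testing; not a curated atlas.
gene_id	a5.3	a5.4	b5.3	b5.4	A5.1	A5.2	B5.1	B5.2
Foxa.a	1	1	0	0	1	1	0	0
Hes.a	1	1	1	1	1	1	1	0
Pem-1	0	0	0	0	0	0	0	1
Tbx6-r.b	0	0	0	0	0	0	0	1	00000011
Lefty	0	0	0	0	0	1	1	1
Fgf9/16/20	0	0	0	0	1	1	1	1
FoxD	0	0	0	0	1	1	1	1
KH.C13.98	0	0	0	0	0	0	0	1
KH.C12.212	0	0	0	0	0	0	0	1
KH.C8.450	0	0	0	0	0	0	0	1
KH.S1497.1	1	1	1	1	0	0	0	0
KH.C11.529	1	1	0	0	1	1	0	0
KH.C9.289	1	1	1	1	1	1	1	0
KH.C4.260	1	1	1	1	1	1	1	0
Sox7/17/18	unknown
Dlx.b	1	1	0	0	0	0	0	0
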