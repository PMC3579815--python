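hgvs_c	gene	group	site_type	spliceogenic	mrna_change	up_regulated_isoform	allelic_expression	clinical_class	protein_change	stop_codons
c.441+2T>G	BRCA1	A	donor	yes	r.[380_441del]	no	mono	5	p.Ser127ThrfsX11	137
c.547+2T>A	BRCA1	A	donor	yes	r.[442_547del]	no	mono	5	p.Gln148AspfsX51	198
c.4986+1G>T	BRCA1	A	donor	yes	r.[4986_4987ins4986+1_4986+65;4986+1g>u]	no	not_assessable	4 or 5	p.Met1663ValfsX14	1676
c.4987-1G>A	BRCA1	A	acceptor	yes	r.[4987_5074del]	no	mono	5	p.Val1665SerfsX8	1672
c.5278-2delA	BRCA1	A	acceptor	yes	r.[5278_5332del,5278_5285del]	no	mono	5	p.Phe1761AsnfsX14,p.Ile1760GlyfsX67	1774,1826
c.5332+1G>A	BRCA1	A	donor	yes	r.[5278_5332del]	no	mono	5	p.Phe1761AsnfsX14	1774
c.475+1G>A	BRCA2	A	donor	yes	r.[426_475del]	no	mono	5	p.Pro143GlyfsX23	165
c.476-2A>G	BRCA2	A	acceptor	yes	r.[=,476_516del,426_516del]	no	bi	4	p.Val159GlyfsX10,p.Ser142ArgfsX13	168,154
c.7008-2A>T	BRCA2	A	acceptor	yes	r.[7008_7435del,7008_7017del,7008_7253del]	no	mono	5	p.Thr2337PhefsX17,p.Thr2337AsnfsX27,p.Thr2337ValfsX1001	2353,2363,3337
c.8755-1G>A	BRCA2	A	acceptor	yes	r.[=,8755_8953del,8755_9004del]	no	bi	4	p.Gly2919LeufsX3,p.Gly2919LysfsX26	2921,2944
c.8954-1_8955delGTTinsAA	BRCA2	A	acceptor	yes	r.[8954_9004del,8954_9117del]	no	mono	5	p.Val2985_Thr3001del,p.Val2985GlyfsX4	NA,2988
c.134+3_134+6delAAGT	BRCA1	B	donor	yes	r.[81_134del]	yes	not_assessable	4 or 5	p.Cys27X	27
c.212G>A	BRCA1	B	donor	yes	r.[191_212del]	yes	mono	5	p.Cys64X	64
c.213-11T>G	BRCA1	B	acceptor	yes	r.[212_213ins213-59_213-1;213-11u>g]	no	mono	5	p.Arg71SerfsX11	81
c.548-3delT	BRCA1	B	acceptor	no	r.[=]	no	bi	2	p.=	NA
c.594-4A>G	BRCA1	B	acceptor	no	r.[=]	no	bi	2	p.=	NA
c.4097G>A	BRCA1	B	acceptor	no	r.[4097g>a]	no	bi	2	p.Gly1366Asp	NA
c.4484G>T	BRCA1	B	donor	yes	r.[4358_4484del]	no	mono	5	p.Ala1453GlyfsX10	1462
c.4986+5G>A	BRCA1	B	donor	yes	r.[4986_4987ins4986+1_4986+65;4986+5g>a]	no	mono	5	p.Met1663ValfsX14	1676
c.5333A>G	BRCA1	B	acceptor	no	r.[5333a>g]	no	bi	2	p.Asp1778Gly	NA
c.631G>A	BRCA2	B	donor	yes	r.[517_631del]	no	mono	5	p.Gly173SerfsX19	191
c.8754+3G>C	BRCA2	B	donor	yes	r.[8754_8755ins8754+1_8754+46;8754+4a>g]	no	mono	5	p.Gly2919ValfsX4	2922
c.9116C>T	BRCA2	B	donor	no	r.[9116c>u]	no	bi	2	p.Pro3039Leu	NA
c.9117G>A	BRCA2	B	donor	yes	r.[8954_9117del]	no	mono	5	p.Val2985GlyfsX4	2988
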