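hgvs_c	SSF	MES	NNSPLICE	GS	HSF	NG2	SV	SP	ASSA
c.134+3_134+6delAAGT	-100	-100	-100	-100	-25.7	-100	-100	-100	-99.7
c.212G>A	-100	-81.6	-100	-100	-13.5	-100	-100	-100	-88.3
c.213-11T>G	-100	-100	NA	NA	-4.1	-100	-100	NA	-81.05
c.548-3delT	NA	-39.8	NA	NA	-2.3	NA	NA	0.6	0.0
c.594-4A>G	0.0	1.5	-1.6	13.4	-0.1	-100	0.0	0.1	7.2
c.4097G>A	-4.4	-23.4	-13.9	-12.3	-3.8	NA	-2.4	-0.1	-46.4
c.4484G>T	-13.4	-47.4	-9.8	-100	-11.2	-44.4	-6.7	-100	-89.8
c.4986+5G>A	-100	-100	-100	NA	-15.0	-100	-100	NA	-91.2
c.5333A>G	5.4	12.3	32.5	17.7	3.9	0.0	2.6	0.0	86.6
c.631G>A	-100	-100	-100	NA	-12.7	NA	-100	NA	-87.5
c.8754+3G>C	-6.3	-31.5	-35.5	-100	-7.4	-29.0	-8.0	-100	-95.3
c.9116C>T	NA	-43.6	-100	NA	0.0	NA	0.0	-100	-6.7
c.9117G>A	NA	-100	-100	NA	-14.7	NA	-100	-100	-87.5
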