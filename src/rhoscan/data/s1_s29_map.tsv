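#span=160689203-160692753
# Default 29-SNP map for the 3,551-bp segment at chromosome 5q34.
# Only the segment span and the rs identifiers listed here are literature
# values; positions without an rs id are evenly spaced user-supplied
# placeholders (synthetic), as are all ancestral/derived allele letters.
label	rs_id	position	ancestral	derived	subsegment
S1	rs6556547	160689203	C	T	PreAlu
S2	rs6891988	160689330	G	A	PreAlu
S3	rs1816071	160689457	T	C	PreAlu
S4	rs35351365	160689583	A	G	PreAlu
S5	rs1816072	160689710	C	T	PreAlu
S6	.	160689837	G	A	Alu
S7	.	160689964	T	C	Alu
S8	.	160690090	A	G	Alu
S9	.	160690217	C	T	Alu
S10	.	160690344	G	A	Alu
S11	.	160690471	T	C	Alu
S12	.	160690598	A	G	Alu
S13	.	160690724	C	T	Alu
S14	.	160690851	G	A	Alu
S15	rs13178374	160690978	T	C	Alu
S16	.	160691105	A	G	Alu
S17	.	160691232	C	T	Alu
S18	.	160691358	G	A	Alu
S19	.	160691485	T	C	Alu
S20	.	160691612	A	G	PostAlu
S21	.	160691739	C	T	PostAlu
S22	.	160691866	G	A	PostAlu
S23	.	160691992	T	C	PostAlu
S24	.	160692119	A	G	PostAlu
S25	.	160692246	C	T	PostExon
S26	.	160692373	G	A	PostExon
S27	.	160692499	T	C	PostExon
S28	.	160692626	A	G	PostExon
S29	rs187269	160692753	C	T	PostExon
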