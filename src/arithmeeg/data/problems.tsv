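block	operand1	operation	operand2
A	6	-	2
B	36	-	8
C	3	x	14
D	16	x	6
A	4	-	3
B	3	x	16
C	8	-	2
D	33	-	9
A	9	x	2
B	7	-	3
C	23	-	8
D	8	x	2
A	26	-	7
B	9	-	7
C	4	x	5
D	8	-	5
A	5	x	4
B	22	-	6
C	4	-	2
D	3	x	12
A	35	-	8
B	5	x	3
C	4	x	12
D	14	x	5
A	5	x	13
B	38	-	9
C	7	x	3
D	7	-	2
A	9	-	2
B	3	x	3
C	28	-	9
D	12	x	5
A	12	x	6
B	4	x	15
C	6	-	4
D	9	-	4
A	7	-	5
B	31	-	8
C	2	x	4
D	4	x	13
A	24	-	9
B	6	x	2
C	27	-	8
D	5	-	3
A	2	x	2
B	25	-	8
C	15	x	3
D	24	-	5
A	5	x	15
B	3	-	2
C	33	-	6
D	10	-	4
A	32	-	6
B	15	x	6
C	6	x	3
D	3	x	2
A	3	x	4
B	4	x	4
C	10	-	9
D	34	-	6
A	21	-	8
B	3	x	7
C	13	x	3
D	2	x	7
A	16	x	4
B	6	x	14
C	8	-	4
D	37	-	8
A	6	-	3
B	5	-	2
C	31	-	9
D	8	x	3
A	14	x	4
B	13	x	6
C	5	x	16
D	26	-	8
A	6	x	4
B	10	-	2
C	2	x	5
D	5	x	5
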