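base	is_paired	is_discordant	mapq_high	is_split	R	G	B
A	0	0	0	0	255	0	0
A	0	0	0	1	255	1	1
A	0	0	1	0	255	1	2
A	0	0	1	1	255	2	3
A	0	1	0	0	255	1	4
A	0	1	0	1	255	2	5
A	0	1	1	0	255	2	6
A	0	1	1	1	255	3	7
A	1	0	0	0	255	1	8
A	1	0	0	1	255	2	9
A	1	0	1	0	255	2	10
A	1	0	1	1	255	3	11
A	1	1	0	0	255	2	12
A	1	1	0	1	255	3	13
A	1	1	1	0	255	3	14
A	1	1	1	1	255	4	15
T	0	0	0	0	0	255	0
T	0	0	0	1	1	255	1
T	0	0	1	0	1	255	2
T	0	0	1	1	2	255	3
T	0	1	0	0	1	255	4
T	0	1	0	1	2	255	5
T	0	1	1	0	2	255	6
T	0	1	1	1	3	255	7
T	1	0	0	0	1	255	8
T	1	0	0	1	2	255	9
T	1	0	1	0	2	255	10
T	1	0	1	1	3	255	11
T	1	1	0	0	2	255	12
T	1	1	0	1	3	255	13
T	1	1	1	0	3	255	14
T	1	1	1	1	4	255	15
C	0	0	0	0	0	0	255
C	0	0	0	1	1	1	255
C	0	0	1	0	1	2	255
C	0	0	1	1	2	3	255
C	0	1	0	0	1	4	255
C	0	1	0	1	2	5	255
C	0	1	1	0	2	6	255
C	0	1	1	1	3	7	255
C	1	0	0	0	1	8	255
C	1	0	0	1	2	9	255
C	1	0	1	0	2	10	255
C	1	0	1	1	3	11	255
C	1	1	0	0	2	12	255
C	1	1	0	1	3	13	255
C	1	1	1	0	3	14	255
C	1	1	1	1	4	15	255
G	0	0	0	0	0	0	0
G	0	0	0	1	1	1	1
G	0	0	1	0	1	2	1
G	0	0	1	1	2	3	2
G	0	1	0	0	1	4	1
G	0	1	0	1	2	5	2
G	0	1	1	0	2	6	2
G	0	1	1	1	3	7	3
G	1	0	0	0	1	8	1
G	1	0	0	1	2	9	2
G	1	0	1	0	2	10	2
G	1	0	1	1	3	11	3
G	1	1	0	0	2	12	2
G	1	1	0	1	3	13	3
G	1	1	1	0	3	14	3
G	1	1	1	1	4	15	4
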