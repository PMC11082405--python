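# Synthetic default CFD penalty table.
# Smooth position-dependent mismatch tolerance profile: mismatches near the
# PAM (position 20) retain little activity, PAM-distal mismatches retain most;
# transversions are penalised more than transitions. Canonical NGG PAM keeps
# multiplier 1.0, non-canonical PAMs are strongly down-weighted. Replace via
# --cfd-table to use a preferred published coefficient set.
position	query_base	genomic_base	multiplier
1	A	C	0.7162
1	A	G	0.955
1	A	T	0.7162
1	C	A	0.7162
1	C	G	0.7162
1	C	T	0.955
1	G	A	0.955
1	G	C	0.7162
1	G	T	0.7162
1	T	A	0.7162
1	T	C	0.955
1	T	G	0.7162
2	A	C	0.6825
2	A	G	0.91
2	A	T	0.6825
2	C	A	0.6825
2	C	G	0.6825
2	C	T	0.91
2	G	A	0.91
2	G	C	0.6825
2	G	T	0.6825
2	T	A	0.6825
2	T	C	0.91
2	T	G	0.6825
3	A	C	0.6487
3	A	G	0.865
3	A	T	0.6487
3	C	A	0.6487
3	C	G	0.6487
3	C	T	0.865
3	G	A	0.865
3	G	C	0.6487
3	G	T	0.6487
3	T	A	0.6487
3	T	C	0.865
3	T	G	0.6487
4	A	C	0.615
4	A	G	0.82
4	A	T	0.615
4	C	A	0.615
4	C	G	0.615
4	C	T	0.82
4	G	A	0.82
4	G	C	0.615
4	G	T	0.615
4	T	A	0.615
4	T	C	0.82
4	T	G	0.615
5	A	C	0.5813
5	A	G	0.775
5	A	T	0.5813
5	C	A	0.5813
5	C	G	0.5813
5	C	T	0.775
5	G	A	0.775
5	G	C	0.5813
5	G	T	0.5813
5	T	A	0.5813
5	T	C	0.775
5	T	G	0.5813
6	A	C	0.5475
6	A	G	0.73
6	A	T	0.5475
6	C	A	0.5475
6	C	G	0.5475
6	C	T	0.73
6	G	A	0.73
6	G	C	0.5475
6	G	T	0.5475
6	T	A	0.5475
6	T	C	0.73
6	T	G	0.5475
7	A	C	0.5138
7	A	G	0.685
7	A	T	0.5138
7	C	A	0.5138
7	C	G	0.5138
7	C	T	0.685
7	G	A	0.685
7	G	C	0.5138
7	G	T	0.5138
7	T	A	0.5138
7	T	C	0.685
7	T	G	0.5138
8	A	C	0.48
8	A	G	0.64
8	A	T	0.48
8	C	A	0.48
8	C	G	0.48
8	C	T	0.64
8	G	A	0.64
8	G	C	0.48
8	G	T	0.48
8	T	A	0.48
8	T	C	0.64
8	T	G	0.48
9	A	C	0.4462
9	A	G	0.595
9	A	T	0.4462
9	C	A	0.4462
9	C	G	0.4462
9	C	T	0.595
9	G	A	0.595
9	G	C	0.4462
9	G	T	0.4462
9	T	A	0.4462
9	T	C	0.595
9	T	G	0.4462
10	A	C	0.4125
10	A	G	0.55
10	A	T	0.4125
10	C	A	0.4125
10	C	G	0.4125
10	C	T	0.55
10	G	A	0.55
10	G	C	0.4125
10	G	T	0.4125
10	T	A	0.4125
10	T	C	0.55
10	T	G	0.4125
11	A	C	0.3788
11	A	G	0.505
11	A	T	0.3788
11	C	A	0.3788
11	C	G	0.3788
11	C	T	0.505
11	G	A	0.505
11	G	C	0.3788
11	G	T	0.3788
11	T	A	0.3788
11	T	C	0.505
11	T	G	0.3788
12	A	C	0.345
12	A	G	0.46
12	A	T	0.345
12	C	A	0.345
12	C	G	0.345
12	C	T	0.46
12	G	A	0.46
12	G	C	0.345
12	G	T	0.345
12	T	A	0.345
12	T	C	0.46
12	T	G	0.345
13	A	C	0.3113
13	A	G	0.415
13	A	T	0.3113
13	C	A	0.3113
13	C	G	0.3113
13	C	T	0.415
13	G	A	0.415
13	G	C	0.3113
13	G	T	0.3113
13	T	A	0.3113
13	T	C	0.415
13	T	G	0.3113
14	A	C	0.2775
14	A	G	0.37
14	A	T	0.2775
14	C	A	0.2775
14	C	G	0.2775
14	C	T	0.37
14	G	A	0.37
14	G	C	0.2775
14	G	T	0.2775
14	T	A	0.2775
14	T	C	0.37
14	T	G	0.2775
15	A	C	0.2438
15	A	G	0.325
15	A	T	0.2438
15	C	A	0.2438
15	C	G	0.2438
15	C	T	0.325
15	G	A	0.325
15	G	C	0.2438
15	G	T	0.2438
15	T	A	0.2438
15	T	C	0.325
15	T	G	0.2438
16	A	C	0.21
16	A	G	0.28
16	A	T	0.21
16	C	A	0.21
16	C	G	0.21
16	C	T	0.28
16	G	A	0.28
16	G	C	0.21
16	G	T	0.21
16	T	A	0.21
16	T	C	0.28
16	T	G	0.21
17	A	C	0.1762
17	A	G	0.235
17	A	T	0.1762
17	C	A	0.1762
17	C	G	0.1762
17	C	T	0.235
17	G	A	0.235
17	G	C	0.1762
17	G	T	0.1762
17	T	A	0.1762
17	T	C	0.235
17	T	G	0.1762
18	A	C	0.1425
18	A	G	0.19
18	A	T	0.1425
18	C	A	0.1425
18	C	G	0.1425
18	C	T	0.19
18	G	A	0.19
18	G	C	0.1425
18	G	T	0.1425
18	T	A	0.1425
18	T	C	0.19
18	T	G	0.1425
19	A	C	0.1088
19	A	G	0.145
19	A	T	0.1088
19	C	A	0.1088
19	C	G	0.1088
19	C	T	0.145
19	G	A	0.145
19	G	C	0.1088
19	G	T	0.1088
19	T	A	0.1088
19	T	C	0.145
19	T	G	0.1088
20	A	C	0.075
20	A	G	0.1
20	A	T	0.075
20	C	A	0.075
20	C	G	0.075
20	C	T	0.1
20	G	A	0.1
20	G	C	0.075
20	G	T	0.075
20	T	A	0.075
20	T	C	0.1
20	T	G	0.075
0	NAA	-	0.02
0	NAC	-	0.02
0	NAG	-	0.26
0	NAT	-	0.02
0	NCA	-	0.02
0	NCC	-	0.02
0	NCG	-	0.02
0	NCT	-	0.02
0	NGA	-	0.07
0	NGC	-	0.02
0	NGG	-	1.0
0	NGT	-	0.02
0	NTA	-	0.02
0	NTC	-	0.02
0	NTG	-	0.02
0	NTT	-	0.02
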