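# Synthetic stand-in module assignment for the 62 cranial landmarks,
# constructed from the anatomical landmark descriptions (not a published table).
# Columns: landmark id (1-based), module label.
1 O
2 O
3 N
4 N
5 N
6 N
7 N
8 N
9 M
10 M
11 N
12 OB
13 OB
14 OB
15 OB
16 OB
17 OB
18 OB
19 OB
20 F
21 F
22 F
23 F
24 F
25 F
26 F
27 F
28 F
29 F
30 F
31 F
32 F
33 F
34 F
35 F
36 B
37 O
38 O
39 O
40 M
41 M
42 M
43 M
44 O
45 O
46 M
47 M
48 M
49 B
50 B
51 B
52 B
53 B
54 B
55 B
56 B
57 B
58 B
59 B
60 B
61 B
62 B
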