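# Synthetic stand-in module assignment for the 62 cranial landmarks,
# constructed from the anatomical landmark descriptions (not a published table).
# Columns: landmark id (1-based), module label.
1 AON
2 AON
3 AON
4 AON
5 AON
6 AON
7 AON
8 AON
9 MR
10 MR
11 AON
12 ORB
13 ORB
14 ORB
15 ORB
16 ORB
17 ORB
18 ORB
19 ORB
20 ZP
21 ZP
22 ZP
23 ZP
24 CV
25 CV
26 ZP
27 ZP
28 ZP
29 ZP
30 CV
31 CV
32 CV
33 CV
34 CV
35 CV
36 CB
37 AON
38 AON
39 AON
40 MR
41 MR
42 MR
43 MR
44 AON
45 AON
46 MR
47 ZP
48 ZP
49 CB
50 CB
51 CB
52 CB
53 CB
54 CB
55 CB
56 CB
57 CB
58 CB
59 CB
60 CB
61 CB
62 CB
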