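# Synthetic stand-in module assignment for the 62 cranial landmarks,
# constructed from the anatomical landmark descriptions (not a published table).
# Columns: landmark id (1-based), module label.
1 TE
2 TE
3 TE
4 TE
5 TE
6 TE
7 TE
8 TE
9 TE
10 TE
11 TE
12 BR
13 BR
14 BR
15 BR
16 BR
17 BR
18 BR
19 BR
20 BR
21 BR
22 BR
23 BR
24 BR
25 BR
26 BR
27 BR
28 BR
29 BR
30 BR
31 BR
32 BR
33 BR
34 BR
35 BR
36 BR
37 TE
38 TE
39 TE
40 TE
41 TE
42 TE
43 TE
44 TE
45 TE
46 TE
47 TE
48 TE
49 BR
50 BR
51 BR
52 BR
53 BR
54 BR
55 BR
56 BR
57 BR
58 BR
59 BR
60 BR
61 BR
62 BR
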