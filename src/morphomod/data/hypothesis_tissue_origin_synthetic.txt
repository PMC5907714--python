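# Synthetic stand-in module assignment for the 62 cranial landmarks,
# constructed from the anatomical landmark descriptions (not a published table).
# Columns: landmark id (1-based), module label.
1 NC
2 NC
3 NC
4 NC
5 NC
6 NC
7 NC
8 NC
9 NC
10 NC
11 NC
12 NC
13 NC
14 NC
15 NC
16 NC
17 NC
18 NC
19 NC
20 NC
21 NC
22 NC
23 NC
24 PM
25 PM
26 NC
27 NC
28 NC
29 NC
30 PM
31 PM
32 PM
33 PM
34 PM
35 PM
36 PM
37 NC
38 NC
39 NC
40 NC
41 NC
42 NC
43 NC
44 NC
45 NC
46 NC
47 NC
48 NC
49 PM
50 PM
51 PM
52 PM
53 PM
54 PM
55 PM
56 PM
57 PM
58 PM
59 PM
60 PM
61 PM
62 PM
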