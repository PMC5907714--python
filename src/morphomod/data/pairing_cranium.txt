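# Bilateral landmark pairing for the 62-landmark cranium (1-based indices).
# Two indices per line: a left/right pair; one index: midline landmark.
1 2
3 4
5 6
7 8
9 10
12 13
14 15
16 17
18 19
20 21
22 23
24 25
26 27
28 29
30 31
34 35
38 39
40 42
41 43
47 48
49 51
52 53
54 55
56 57
58 59
61 62
11
32
33
36
37
44
45
46
50
60
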