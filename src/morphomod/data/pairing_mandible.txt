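# Bilateral landmark pairing for the 24-landmark mandible (1-based indices).
# Two indices per line: a left/right pair; one index: midline landmark.
2 3
4 5
7 8
9 10
11 12
13 14
15 16
17 18
19 20
21 22
23 24
1
6
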