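# Malayan butterfly survey (the classic light-trap abundance data).
# Frequency counts f_k for k = 1..14; the final row aggregates the
# 191 species each observed 15 or more times.
# total_species: 620
# total_individuals: 9031
k,f_k
1,118
2,74
3,44
4,24
5,29
6,22
7,20
8,19
9,20
10,15
11,12
12,14
13,6
14,12
15+,191
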