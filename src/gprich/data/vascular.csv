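# Vascular plant survey, southern Appalachians (central region).
# Frequency counts f_k for k = 1..14; the final row aggregates the
# 15 species each observed 15 or more times.
# total_species: 188
# total_individuals: 1008
k,f_k
1,61
2,35
3,18
4,12
5,15
6,4
7,8
8,4
9,5
10,5
11,1
12,2
13,1
14,2
15+,15
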