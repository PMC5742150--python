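c Australian states and mainland territories, 3-coloring instance
c Tasmania is isolated (no land borders)
c label 1 WA
c label 2 NT
c label 3 SA
c label 4 Q
c label 5 NSW
c label 6 V
c label 7 T
p edge 7 9
e 1 2
e 1 3
e 2 3
e 2 4
e 3 4
e 3 5
e 3 6
e 4 5
e 5 6
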