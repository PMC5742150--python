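c Canadian provinces and territories, 3-coloring instance
c Prince Edward Island is isolated (no land borders)
c label 1 YT
c label 2 NT
c label 3 NU
c label 4 BC
c label 5 AB
c label 6 SK
c label 7 MB
c label 8 ON
c label 9 QC
c label 10 NB
c label 11 NS
c label 12 PE
c label 13 NL
p edge 13 15
e 1 2
e 1 4
e 2 3
e 2 4
e 2 5
e 2 6
e 3 7
e 4 5
e 5 6
e 6 7
e 7 8
e 8 9
e 9 10
e 9 13
e 10 11
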