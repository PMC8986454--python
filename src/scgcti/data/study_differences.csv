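subject,MC,AO,AC,MO
2,-19,-9,-6,-7
52,-2,-5,-12,-18
62,38,23,-5,-14
63,4,7,-12,-5
65,-34,16,-20,35
67,-5,-7,-3,-10
68,-17,-18,3,22
69,-21,-9,-19,-27
71,3,-2,-5,-1
72,-20,-3,-13,56
73,5,-5,6,-27
74,-29,-12,-10,5
76,-36,-2,-19,-40
78,-6,-16,-9,-46
84,-74,56,26,44
86,-8,-25,-11,-22
92,-17,-22,-42,4
94,-28,-11,-27,-34
96,-77,9,-61,-36
100,2,9,-25,13
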