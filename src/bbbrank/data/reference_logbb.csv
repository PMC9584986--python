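compound_id,eq1,eq2,eq3,eq4
TP1,-0.94,-0.26,-1.11,-0.99
TP4,-0.54,-0.23,-0.03,0.11
TP5,-0.47,-0.27,0.09,0.19
TP6,-0.33,-0.28,0.23,0.24
TP7,-0.37,-0.27,0.15,0.21
TP8,-0.38,-0.27,0.25,0.29
TP9,-0.59,-0.32,0.00,0.05
TP10,-0.39,-0.21,0.22,0.22
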