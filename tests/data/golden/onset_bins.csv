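bin,count,percent
0-30,13,68.42
31-60,4,21.05
61-90,1,5.26
91-120,1,5.26
121-150,0,0.0
151-180,0,0.0
181-210,0,0.0
211-240,0,0.0
241-270,0,0.0
271-300,0,0.0
301-330,0,0.0
331-360,0,0.0
>360,0,0.0
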