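stage,start_Ma,end_Ma,eutherian_new,eutherian_richness,mammal_new,mammal_richness
Turonian,93.9,89.8,2,10,20,50
Coniacian,89.8,86.3,1,12,25,45
Santonian,86.3,83.6,3,15,30,90
Campanian,83.6,72.1,10,40,40,160
Maastrichtian,72.1,66.0,12,44,40,170
Paleocene,66.0,56.0,42,60,50,120
Ypresian,56.0,47.8,30,80,60,150
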