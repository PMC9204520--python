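muscle,parameter,cv,n_subjects,source
vaslat,MIF,0.28,21,synthetic-default-a
vaslat,MIF,0.22,9,synthetic-default-b
vasmed,MIF,0.26,21,synthetic-default-a
vasint,MIF,0.25,21,synthetic-default-a
recfem,MIF,0.30,21,synthetic-default-a
bflh,MIF,0.27,21,synthetic-default-a
bfsh,MIF,0.29,9,synthetic-default-b
semimem,MIF,0.24,21,synthetic-default-a
semiten,MIF,0.26,9,synthetic-default-b
gasmed,MIF,0.23,21,synthetic-default-a
gaslat,MIF,0.25,9,synthetic-default-b
soleus,MIF,0.22,21,synthetic-default-a
tibant,MIF,0.24,21,synthetic-default-a
glmax,MIF,0.28,21,synthetic-default-a
vaslat,TSL,0.04,12,synthetic-default-c
vasmed,TSL,0.05,12,synthetic-default-c
vasint,TSL,0.04,12,synthetic-default-c
recfem,TSL,0.06,12,synthetic-default-c
bflh,TSL,0.07,12,synthetic-default-c
bfsh,TSL,0.08,12,synthetic-default-c
semimem,TSL,0.06,12,synthetic-default-c
semiten,TSL,0.09,12,synthetic-default-c
gasmed,TSL,0.03,12,synthetic-default-c
gaslat,TSL,0.03,12,synthetic-default-c
soleus,TSL,0.02,12,synthetic-default-c
tibant,TSL,0.05,12,synthetic-default-c
glmax,TSL,0.07,12,synthetic-default-c
vaslat,PEN,0.30,19,synthetic-default-d
vasmed,PEN,0.28,19,synthetic-default-d
vasint,PEN,0.32,19,synthetic-default-d
recfem,PEN,0.26,19,synthetic-default-d
bflh,PEN,0.24,19,synthetic-default-d
semimem,PEN,0.27,19,synthetic-default-d
semiten,PEN,0.29,19,synthetic-default-d
gasmed,PEN,0.22,19,synthetic-default-d
gaslat,PEN,0.25,19,synthetic-default-d
soleus,PEN,0.30,19,synthetic-default-d
tibant,PEN,0.23,19,synthetic-default-d
glmax,PEN,0.26,19,synthetic-default-d
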