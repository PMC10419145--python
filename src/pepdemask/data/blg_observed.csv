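peptide,species,kind,value_type,value
f(9-69/70),ABC,intermediate,d_r,1.5
f(9-40),AB,intermediate,d_r,3.6
f(15-69/70),BC,intermediate,d_r,
f(76-100/101),ABC,intermediate,d_r,3.4
f(76-91),AB,intermediate,d_r,4.4
f(84-100/101),BC,intermediate,d_r,4.7
f(101/102-138),ABC,intermediate,d_r,3.4
f(101/102-135),AB,intermediate,d_r,
f(125-138),BC,intermediate,d_r,6.1
f(9-14),A,final,n,0.68
f(15-40),B,final,n,0.86
f(41-69/70),C,final,n,0.59
f(76-83),A,final,n,1.46
f(84-91),B,final,n,2.37
f(92-100/101),C,final,n,1.40
f(101/102-124),A,final,n,1.13
f(125-135),B,final,n,5.76
f(136-138),C,final,n,5.10
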