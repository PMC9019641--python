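term,level,value
mo,1,0.000
mo,2,0.099
mo,3,0.246
sc,1,0.000
sc,2,0.105
sc,3,0.208
ua,1,0.000
ua,2,0.074
ua,3,0.193
pd,1,0.000
pd,2,0.092
pd,3,0.236
ad,1,0.000
ad,2,0.086
ad,3,0.205
constant,,0.039
n3,,0.022
n3_absent,,0.000
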