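valley,era,n_sites,variable,correlation
Vielha,past,119,yellow,0.482
Vielha,past,119,unbanded,0.517
Vielha,past,119,banded,-0.480
Vielha,present,43,yellow,0.136
Vielha,present,43,unbanded,0.165
Vielha,present,43,banded,0.058
Jueu,past,49,yellow,0.492
Jueu,past,49,unbanded,0.858
Jueu,past,49,banded,-0.834
Jueu,present,17,yellow,0.755
Jueu,present,17,unbanded,0.678
Jueu,present,17,banded,-0.687
Riba,past,34,yellow,-0.321
Riba,present,21,yellow,-0.235
Tort,past,24,yellow,0.338
Tort,past,24,unbanded,-0.164
Tort,past,24,banded,0.170
Tort,present,27,yellow,0.265
Tort,present,27,unbanded,-0.203
Tort,present,27,banded,0.335
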