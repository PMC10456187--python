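,#2,#3,#4,#1/Ek.,Yu.
#2,0,52%,51%,48%,51%
#3,48%,0,42%,38%,46%
#4,52%,58%,0,49%,57%
#1/Ek.,52%,62%,51%,0,64%
Yu.,52%,54%,51%,36%,0
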