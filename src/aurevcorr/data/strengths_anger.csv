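,#1,#2,#3,#4,Ek.,Yu.
#1,0,70%,76%,78%,76%,84%
#2,30%,0,78%,72%,73%,45%
#3,24%,22%,0,52%,51%,33%
#4,22%,28%,48%,0,54%,36%
Ek.,24%,27%,49%,46%,0,34%
Yu.,16%,55%,67%,64%,66%,0
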