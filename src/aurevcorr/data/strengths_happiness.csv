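,#1,#2,#3,#4,Ek.,Yu.
#1,0,16%,75%,70%,82%,63%
#2,84%,0,82%,87%,94%,87%
#3,25%,18%,0,54%,52%,24%
#4,30%,13%,46%,0,46%,25%
Ek.,18%,6%,48%,54%,0,15%
Yu.,37%,13%,76%,75%,85%,0
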