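,#1,#2,#3,#4
#1,0,46%,38%,46%
#2,54%,0,26%,44%
#3,62%,74%,0,76%
#4,54%,56%,24%,0
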