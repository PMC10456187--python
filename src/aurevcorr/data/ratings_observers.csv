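rater_id,item_id,rating
obs1,happy,4
obs2,happy,5
obs3,happy,5
obs4,happy,4
obs1,sad,5
obs2,sad,5
obs3,sad,4
obs4,sad,4
obs1,angry,5
obs2,angry,4
obs3,angry,4
obs4,angry,4
obs1,confident,4
obs2,confident,5
obs3,confident,4
obs4,confident,5
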