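side,modes,tp_c,tp_s,tn_c,tn_s,fp_c,fp_s,fn_c,fn_s
left,1,29,30,29,30,3,1,1,3
left,2,28,31,28,31,2,2,2,2
left,3,29,31,29,31,2,1,1,2
left,4,29,30,29,30,3,1,1,3
left,5,29,31,29,31,2,1,1,2
left,6,29,32,29,32,1,1,1,1
left,7,29,33,29,33,0,1,1,0
left,8,29,33,29,33,0,1,1,0
left,9,29,33,29,33,0,1,1,0
left,10,29,33,29,33,0,1,1,0
right,1,30,32,30,32,1,0,0,1
right,2,29,32,29,32,1,1,1,1
right,3,30,32,30,32,1,0,0,1
right,4,30,32,30,32,1,0,0,1
right,5,30,33,30,33,0,0,0,0
right,6,30,33,30,33,0,0,0,0
right,7,30,33,30,33,0,0,0,0
right,8,30,33,30,33,0,0,0,0
right,9,30,33,30,33,0,0,0,0
right,10,30,32,30,32,1,0,0,1
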