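side,modes,view,sensitivity,specificity,precision,accuracy,f_measure
left,1,C,0.967,0.906,0.906,0.935,0.935
left,1,S,0.909,0.968,0.968,0.938,0.938
left,2,C,0.933,0.933,0.933,0.933,0.933
left,2,S,0.939,0.939,0.939,0.939,0.939
left,3,C,0.967,0.935,0.935,0.951,0.951
left,3,S,0.939,0.969,0.969,0.954,0.954
left,4,C,0.967,0.906,0.906,0.935,0.935
left,4,S,0.909,0.968,0.968,0.938,0.938
left,5,C,0.967,0.935,0.935,0.951,0.951
left,5,S,0.939,0.969,0.969,0.954,0.954
left,6,C,0.967,0.967,0.967,0.967,0.967
left,6,S,0.970,0.970,0.970,0.970,0.970
left,7,C,0.967,1.000,1.000,0.983,0.983
left,7,S,1.000,0.971,0.971,0.985,0.985
left,8,C,0.967,1.000,1.000,0.983,0.983
left,8,S,1.000,0.971,0.971,0.985,0.985
left,9,C,0.967,1.000,1.000,0.983,0.983
left,9,S,1.000,0.971,0.971,0.985,0.985
left,10,C,0.967,1.000,1.000,0.983,0.983
left,10,S,1.000,0.971,0.971,0.985,0.985
right,1,C,1.000,0.968,0.968,0.984,0.984
right,1,S,0.970,1.000,1.000,0.985,0.985
right,2,C,0.967,0.967,0.967,0.967,0.967
right,2,S,0.970,0.970,0.970,0.970,0.970
right,3,C,1.000,0.968,0.968,0.984,0.984
right,3,S,0.970,1.000,1.000,0.985,0.985
right,4,C,1.000,0.968,0.968,0.984,0.984
right,4,S,0.970,1.000,1.000,0.985,0.985
right,5,C,1.000,1.000,1.000,1.000,1.000
right,5,S,1.000,1.000,1.000,1.000,1.000
right,6,C,1.000,1.000,1.000,1.000,1.000
right,6,S,1.000,1.000,1.000,1.000,1.000
right,7,C,1.000,1.000,1.000,1.000,1.000
right,7,S,1.000,1.000,1.000,1.000,1.000
right,8,C,1.000,1.000,1.000,1.000,1.000
right,8,S,1.000,1.000,1.000,1.000,1.000
right,9,C,1.000,1.000,1.000,1.000,1.000
right,9,S,1.000,1.000,1.000,1.000,1.000
right,10,C,1.000,0.968,0.968,0.984,0.984
right,10,S,0.970,1.000,1.000,0.985,0.985
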