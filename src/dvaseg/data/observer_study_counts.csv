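observer,granularity,metric,source,c1,c2,c3,c4
1,slice,grade,reference,7,7,40,138
1,slice,grade,classical,20,7,53,112
1,slice,grade,dvas,17,5,47,123
2,slice,grade,reference,10,11,44,127
2,slice,grade,classical,17,28,90,57
2,slice,grade,dvas,12,25,76,79
3,slice,grade,reference,5,11,42,134
3,slice,grade,classical,11,14,96,71
3,slice,grade,dvas,9,12,81,90
1,scan,grade,reference,0,3,7,3
1,scan,grade,classical,0,3,9,1
1,scan,grade,dvas,0,3,8,2
2,scan,grade,reference,1,2,4,6
2,scan,grade,classical,1,6,6,0
2,scan,grade,dvas,1,3,9,0
3,scan,grade,reference,0,1,11,1
3,scan,grade,classical,0,5,8,0
3,scan,grade,dvas,0,5,8,0
1,scan,rank,reference,7,2,1,3
1,scan,rank,classical,2,7,3,1
1,scan,rank,dvas,6,6,1,0
2,scan,rank,reference,9,2,0,2
2,scan,rank,classical,1,8,4,0
2,scan,rank,dvas,3,9,1,0
3,scan,rank,reference,8,1,1,3
3,scan,rank,classical,1,6,4,2
3,scan,rank,dvas,5,5,3,0
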