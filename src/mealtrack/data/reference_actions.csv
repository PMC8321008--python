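subject,test_number,actions_detected,actions_gt
1,1,5,5
1,2,7,7
1,3,4,5
1,4,3,5
1,5,6,6
2,6,6,6
2,7,3,5
2,8,5,5
2,9,6,6
2,10,4,4
3,11,4,4
3,12,5,5
3,13,3,5
3,14,7,7
3,15,5,5
4,16,5,5
4,17,5,5
4,18,4,4
4,19,7,7
4,20,7,7
5,21,15,15
5,22,27,32
5,23,12,12
5,24,15,15
5,25,11,11
6,26,18,19
6,27,19,19
6,28,13,13
6,29,16,16
6,30,17,18
7,31,18,18
7,32,11,11
7,33,14,14
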