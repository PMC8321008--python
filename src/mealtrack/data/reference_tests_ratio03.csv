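subject,test_number,sf_auto,ef_auto,sf_manual,ef_manual,sf_gt,ef_gt
1,1,171,500,176,500,171,500
1,2,149,500,152,500,149,500
1,3,220,500,218,500,220,500
1,4,211,500,179,500,186,500
1,5,225,500,231,500,225,500
2,6,171,500,183,500,171,500
2,7,100,500,113,500,100,500
2,8,1,500,1,500,1,500
2,9,84,500,88,500,84,500
2,10,130,500,130,500,130,500
3,11,1,500,219,500,180,500
3,12,93,500,110,500,93,500
3,13,147,500,128,500,138,500
3,14,145,500,151,500,145,500
3,15,153,500,145,500,153,500
4,16,147,500,142,500,147,500
4,17,207,500,208,500,207,500
4,18,165,468,165,500,165,472
4,19,113,500,113,500,113,500
4,20,153,500,140,500,153,500
5,21,80,7011,221,7030,218,7011
5,22,7376,20023,7385,20020,7376,20023
5,23,403,5390,403,5390,403,5390
5,24,165,5330,161,5330,165,5390
5,25,6019,8052,6019,8050,6019,8052
6,26,56,3599,90,3600,56,3599
6,27,1,3899,10,3899,1,3899
6,28,270,2639,300,2640,270,2639
6,29,295,5400,300,5400,295,5400
6,30,405,5381,417,5400,405,5381
7,31,158,5224,172,5286,158,5224
7,32,6015,8048,6032,8100,6015,8048
7,33,1,3599,8,3599,1,3599
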