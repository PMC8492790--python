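epoch,loss,accuracy
1,0.7006142982942782,0.5166666666666667
2,0.6888066437059946,0.5166666666666667
3,0.6793313044435727,0.5666666666666667
4,0.6672225826776651,0.5916666666666667
5,0.6848559228829101,0.5333333333333333
6,0.6612596875018663,0.6166666666666667
7,0.6669362591112822,0.5666666666666667
8,0.6713365481474304,0.5666666666666667
9,0.6697994322696824,0.575
10,0.6606588468136975,0.625
11,0.6626517654408983,0.6083333333333333
12,0.650036293592741,0.6833333333333333
13,0.6465036774772455,0.65
14,0.6377166287702567,0.6916666666666667
15,0.6153071712955352,0.7916666666666666
16,0.6254935772560282,0.7416666666666667
17,0.643272163854105,0.6333333333333333
18,0.608125715961279,0.8
19,0.6014053934013901,0.775
20,0.5976294371497015,0.7666666666666667
21,0.5904226598395514,0.8
22,0.5712104496052707,0.8
23,0.5549876465507588,0.85
24,0.5329250711444169,0.875
25,0.5511358552278408,0.8166666666666667
26,0.5178286493241521,0.9333333333333333
27,0.49471667478778225,0.9
28,0.4775083576605296,0.9166666666666666
29,0.45274734467753663,0.9166666666666666
30,0.46080071779359405,0.8833333333333333
31,0.42939149980127306,0.925
32,0.40319408130390305,0.9333333333333333
33,0.408824169613166,0.9333333333333333
34,0.4086953149588579,0.925
35,0.4174557906489943,0.8666666666666667
36,0.3282183955842325,0.9916666666666667
37,0.36386954169810576,0.95
38,0.35157856086651235,0.9166666666666666
39,0.3046010763478822,0.9916666666666667
40,0.3065542606240955,0.9666666666666667
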