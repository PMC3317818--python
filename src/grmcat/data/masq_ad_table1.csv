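item_id,source_id,label,key,a,b1,b2,b3,b4
1,1,Felt cheerful,positive,2.41,-2.50,-1.08,-0.08,0.78
2,14,Felt really happy,positive,2.61,-2.52,-1.44,-0.57,0.18
3,18,Felt optimistic,positive,2.37,-2.74,-1.47,-0.60,0.40
4,21,Felt really bored,negative,0.98,-0.40,0.81,1.86,3.58
5,23,Felt like I was having a lot of fun,positive,2.75,-2.77,-1.51,-0.69,0.08
6,26,Felt withdrawn from other people,negative,1.18,-0.46,0.74,1.44,2.81
7,27,Seemed to move quickly and easily,positive,1.41,-3.05,-1.33,-0.26,0.68
8,30,Looked forward to things with enjoyment,positive,2.55,-2.11,-0.98,-0.25,0.61
9,33,Felt like nothing was very enjoyable,negative,2.08,-0.59,0.26,0.80,1.77
10,35,Felt like I had accomplished a lot,positive,1.74,-3.49,-2.03,-1.07,-0.20
11,36,Felt like I had a lot of interesting things to do,positive,1.94,-3.34,-1.86,-0.98,-0.17
12,39,Felt like it took extra effort to get started,negative,1.08,-1.72,-0.40,0.34,1.93
13,40,Felt like I had a lot to look forward to,positive,2.21,-2.65,-1.43,-0.62,0.27
14,44,Felt like there wasn't anything interesting or fun to do,negative,1.38,-0.72,0.33,1.10,2.39
15,49,Was proud of myself,positive,2.06,-2.84,-1.68,-0.77,0.29
16,53,Felt unattractive,negative,0.90,-0.68,0.57,1.49,2.65
17,58,"Felt really ""up"" or lively",positive,2.90,-2.72,-1.65,-0.81,-0.20
18,66,Felt really slowed down,negative,1.15,-0.75,0.51,1.34,2.75
19,72,Felt like I had a lot of energy,positive,2.01,-3.00,-1.79,-0.84,-0.14
20,78,Felt hopeful about the future,positive,1.96,-2.59,-1.40,-0.53,0.44
21,86,Felt really good about myself,positive,2.63,-2.88,-1.57,-0.69,0.22
22,89,Thought about death or suicide,negative,1.18,0.86,1.71,2.26,3.34
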