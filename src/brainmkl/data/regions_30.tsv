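# synthetic numbered region labels (stand-in for atlas names)
1	R001
2	R002
3	R003
4	R004
5	R005
6	R006
7	R007
8	R008
9	R009
10	R010
11	R011
12	R012
13	R013
14	R014
15	R015
16	R016
17	R017
18	R018
19	R019
20	R020
21	R021
22	R022
23	R023
24	R024
25	R025
26	R026
27	R027
28	R028
29	R029
30	R030
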