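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
31	R031
32	R032
33	R033
34	R034
35	R035
36	R036
37	R037
38	R038
39	R039
40	R040
41	R041
42	R042
43	R043
44	R044
45	R045
46	R046
47	R047
48	R048
49	R049
50	R050
51	R051
52	R052
53	R053
54	R054
55	R055
56	R056
57	R057
58	R058
59	R059
60	R060
61	R061
62	R062
63	R063
64	R064
65	R065
66	R066
67	R067
68	R068
69	R069
70	R070
71	R071
72	R072
73	R073
74	R074
75	R075
76	R076
77	R077
78	R078
79	R079
80	R080
81	R081
82	R082
83	R083
84	R084
85	R085
86	R086
87	R087
88	R088
89	R089
90	R090
91	R091
92	R092
93	R093
94	R094
95	R095
96	R096
97	R097
98	R098
99	R099
100	R100
101	R101
102	R102
103	R103
104	R104
105	R105
106	R106
107	R107
108	R108
109	R109
110	R110
111	R111
112	R112
113	R113
114	R114
115	R115
116	R116
117	R117
118	R118
119	R119
120	R120
121	R121
122	R122
123	R123
124	R124
125	R125
126	R126
127	R127
128	R128
129	R129
130	R130
131	R131
132	R132
133	R133
134	R134
135	R135
136	R136
137	R137
138	R138
139	R139
140	R140
141	R141
142	R142
143	R143
144	R144
145	R145
146	R146
147	R147
148	R148
149	R149
150	R150
151	R151
152	R152
153	R153
154	R154
155	R155
156	R156
157	R157
158	R158
159	R159
160	R160
161	R161
162	R162
163	R163
164	R164
165	R165
166	R166
167	R167
168	R168
169	R169
170	R170
171	R171
172	R172
173	R173
174	R174
175	R175
176	R176
177	R177
178	R178
179	R179
180	R180
181	R181
182	R182
183	R183
184	R184
185	R185
186	R186
187	R187
188	R188
189	R189
190	R190
191	R191
192	R192
193	R193
194	R194
195	R195
196	R196
197	R197
198	R198
199	R199
200	R200
201	R201
202	R202
203	R203
204	R204
205	R205
206	R206
207	R207
208	R208
209	R209
210	R210
211	R211
212	R212
213	R213
214	R214
215	R215
216	R216
217	R217
218	R218
219	R219
220	R220
221	R221
222	R222
223	R223
224	R224
225	R225
226	R226
227	R227
228	R228
229	R229
230	R230
231	R231
232	R232
233	R233
234	R234
235	R235
236	R236
237	R237
238	R238
239	R239
240	R240
241	R241
242	R242
243	R243
244	R244
245	R245
246	R246
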