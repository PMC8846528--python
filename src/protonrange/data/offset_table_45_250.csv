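energy_MeV,bragg_mm,n13_mm,offset_mm
45,17.0,15.0,2.0
50,21.0,19.0,2.0
55,25.0,23.0,2.0
60,29.5,28.0,1.5
65,34.0,32.0,2.0
70,39.0,37.0,2.0
75,44.0,42.0,2.0
80,50.0,48.0,2.0
85,56.0,54.0,2.0
90,62.0,60.0,2.0
95,68.0,66.0,2.0
100,75.0,73.0,2.0
105,81.5,80.0,1.5
110,88.5,87.0,1.5
115,96.0,94.0,2.0
120,103.5,102.0,1.5
125,110.5,109.0,1.5
130,119.0,117.0,2.0
135,127.0,126.0,1.0
140,136.0,134.0,2.0
145,145.0,143.0,2.0
150,153.0,152.0,1.0
155,163.0,161.0,2.0
160,172.0,170.0,2.0
165,181.0,180.0,1.0
170,191.0,189.0,2.0
175,201.0,199.0,2.0
180,211.0,209.0,2.0
185,221.0,219.0,2.0
190,232.0,230.0,2.0
195,242.0,241.0,1.0
200,253.0,251.0,2.0
205,264.0,262.0,2.0
210,275.0,274.0,1.0
215,287.0,285.0,2.0
220,298.0,296.0,2.0
225,310.0,308.0,2.0
230,322.0,320.0,2.0
235,334.0,332.0,2.0
240,345.0,344.0,1.0
245,358.0,356.0,2.0
250,371.0,369.0,2.0
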