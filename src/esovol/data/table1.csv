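patient,bmi,histology,tnm,location,therapy,resected
1,22,SCC,T2N1M0,Middle,Chemoradiotherapy,Yes
2,25,AC,T3N1M0,"Cardia, SII",Chemoradiotherapy,Yes
3,25,AC,T2N0M0,Distal,Chemoradiotherapy,No
4,24,AC,T3N1M0,"Cardia, SII",Chemotherapy,Yes
5,24,AC,T3N1M0,"Cardia, SII",Chemotherapy,Yes
6,22,SCC,T3N1M0,Middle,Chemotherapy,Yes
7,22,SCC,T3N1M0,Middle,Chemotherapy,Yes
8,30,AC,T3N1M0,Distal,Chemoradiotherapy,Yes
9,22,AC,T3N0M0,Cardia,Chemoradiotherapy,No
10,27,SCC,T3N1M0,Middle,Chemoradiotherapy,Yes
11,24,AC,T3N1M0,Distal,Chemotherapy,Yes
12,32,SCC,T3N1M0,Distal,Chemotherapy,Yes
13,33,AC,T3N1M0,"Cardia, SII",Chemoradiotherapy,Yes
14,25,AC,T2N0M0,"Cardia, SI",Chemotherapy,Yes
15,28,AC,T3N1M0,"Cardia, SII",Chemotherapy,Yes
16,23,SCC,T2N1M0,Middle,Chemoradiotherapy,Yes
17,30,AC,T3N0M0,"Cardia, SII",Chemoradiotherapy,Yes
18,21,SCC,T3N1M0,Distal,Chemotherapy,No
19,22,SCC,T3N1MX,Distal,Chemoradiotherapy,Yes
20,34,AC,T2N0M0,"Cardia, SII",Chemotherapy,Yes
21,26,AC,T3N0M0,"Cardia, SII",Chemoradiotherapy,Yes
22,20,AC,T3N1M0,"Cardia, SII",Chemoradiotherapy,Yes
23,23,AC,T3N0M0,"Cardia, SII",Chemoradiotherapy,Yes
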