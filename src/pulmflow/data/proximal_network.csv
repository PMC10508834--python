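name,kind,length_cm,radius_cm,parent,daughters
MPA,artery,4.30,1.350,,LPA;RPA
LPA,artery,2.50,0.900,MPA,LIA;LSA
RPA,artery,5.75,1.100,MPA,RIA;RSA
LIA,artery,2.15,0.842,LPA,LIA D1;LIA D2
LSA,artery,1.23,0.481,LPA,LSA D1;LSA D2
RIA,artery,2.35,0.922,RPA,RIA D1;RIA D2
RSA,artery,1.92,0.755,RPA,RSA D1;RSA D2
LIA D1,artery,1.93,0.757,LIA,LIV D1
LIA D2,artery,1.31,0.514,LIA,LIV D2
LSA D1,artery,1.10,0.433,LSA,LSV D1
LSA D2,artery,0.75,0.293,LSA,LSV D2
RIA D1,artery,2.11,0.829,RIA,RIV D1
RIA D2,artery,1.43,0.562,RIA,RIV D2
RSA D1,artery,1.17,0.460,RSA,RSV D1
RSA D2,artery,1.55,0.610,RSA,RSV D2
LIV,vein,2.15,0.641,,LIV D1;LIV D2
LSV,vein,1.23,0.716,,LSV D1;LSV D2
RIV,vein,2.35,0.864,,RIV D1;RIV D2
RSV,vein,1.92,0.824,,RSV D1;RSV D2
LIV D1,vein,1.93,0.576,LIV,LIA D1
LIV D2,vein,1.31,0.391,LIV,LIA D2
LSV D1,vein,1.10,0.643,LSV,LSA D1
LSV D2,vein,0.75,0.436,LSV,LSA D2
RIV D1,vein,2.11,0.777,RIV,RIA D1
RIV D2,vein,1.43,0.527,RIV,RIA D2
RSV D1,vein,1.73,0.740,RSV,RSA D1
RSV D2,vein,1.17,0.502,RSV,RSA D2
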