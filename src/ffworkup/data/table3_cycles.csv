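cohort,patient_id,arm,n_cycles,mii,two_pn,blastocysts,embryos_transferred,transfer_day,hcg_positive,outcomes
1,P2,ICSI,5,65,5,,3,D2;D3,1,LB
1,P3,ICSI,1,10,0,,0,,0,
1,P4,ICSI,2,10,1,,0,,0,
1,P7,ICSI,4,81,2,,1,D2,0,
1,P9,ICSI,3,18,0,,0,,0,
1,P15,ICSI,3,16,5,,5,D3,0,
1,P18,ICSI,5,62,16,,3,D3,1,M
1,P20,ICSI,2,16,3,,2,D3,0,
1,P21,ICSI,1,8,0,,0,,0,
1,P23,ICSI,4,26,3,,2,D3,1,LB
1,P26,ICSI,1,11,0,,0,,0,
2,P29,ICSI,1,15,2,,1,D3,0,
2,P32,ICSI,1,4,1,,0,,0,
2,P34,ICSI,2,25,0,,0,,0,
2,P35,ICSI,2,15,1,,0,,0,
2,P36,ICSI,2,21,4,,4,D3,1,M
2,P44,ICSI,3,35,7,,3,D3;D5,1,LB
2,P46,ICSI,3,46,4,,1,D3,0,
2,P54,ICSI,2,14,2,,1,D5,0,
1,P2,ICSI_AOA,1,20,8,,5,D3,1,LB
1,P3,ICSI_AOA,8,63,43,,15,D2;D3,1,ND
1,P4,ICSI_AOA,1,6,5,,1,D3,0,
1,P7,ICSI_AOA,1,15,12,6,2,D5,1,LB
1,P9,ICSI_AOA,2,13,4,0,0,,0,
1,P15,ICSI_AOA,3,7,2,2,1,D5,1,BP
1,P18,ICSI_AOA,1,13,8,5,2,D5,2,BP;LB
1,P20,ICSI_AOA,1,13,8,7,5,D5,2,LB;LB
1,P21,ICSI_AOA,1,17,13,5,1,D5,1,LB
1,P23,ICSI_AOA,2,16,10,8,3,D5,1,M
1,P26,ICSI_AOA,1,18,14,10,5,D5,1,BP
2,P29,ICSI_AOA,1,11,9,6,3,D5,2,LB;LB
2,P32,ICSI_AOA,5,25,13,11,6,D5,2,LB;LB
2,P34,ICSI_AOA,1,11,11,8,2,D5,2,LB;BP
2,P35,ICSI_AOA,2,31,14,7,2,D5,1,LB
2,P36,ICSI_AOA,1,7,7,5,1,D5,0,
2,P44,ICSI_AOA,1,9,6,5,1,D5,1,LB
2,P46,ICSI_AOA,1,19,5,3,2,D5,1,Ong
2,P54,ICSI_AOA,1,8,7,6,1,D5,1,Ong
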