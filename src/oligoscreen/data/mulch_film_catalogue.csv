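assignment,type,n,m,mstfa_derivatised,gcms_ions,di_orbitrap,hplc_msms_ions,confirmed,conc_ug_g,conc_sd_ug_g,surrogate_rf,topology,end_group,rep_AA_BD,rep_TA_BD,rep_SeA_BD,rep_LA
ATBC,Plasticiser,,,no,185;129;259,ND,129.01831;185.08102;139.00272,yes,4210,135,no,,,,,,
TBA,NIAS,,,no,113;157;57,ND,139.00261;157.01319;111.00773,no,1400,170,yes,,,,,,
TBC,Plasticiser,,,no,185;129;57,ND,ND,no,104,23,yes,,,,,,
Palmitic acid,Lubricant,,,yes,117;313;129,ND,ND,yes,18,3,yes,,,,,,
Stearic acid,Lubricant,,,yes,117;129;132,ND,ND,yes,4,2,yes,,,,,,
PMP,Unknown,,,yes,191;244;73,detected,357.29994;71.04916;101.05974,no,,,,,,,,,
PMP-LA,Unknown,,,yes,191;244;147,detected,429.32104;83.04915;95.08555,no,,,,,,,,,
PMP-[LA]n,Unknown,2-4,,no,ND,detected,ND,no,,,,,,,,,
PMS,Unknown,,,yes,117;191;73,detected,385.33136;71.04916;83.04916,yes,,,,,,,,,
PMS-LA,Unknown,,,yes,117;191;73,detected,457.35227;83.04912;95.08551,no,,,,,,,,,
PMS-[LA]n,Unknown,2-6,,no,ND,detected,ND,no,,,,,,,,,
[AA-BD],Cyclic/NIAS,,,no,55;129;111,detected,ND,yes,168,32,no,cyclic,none,1,0,0,0
[AA-BD]2,Cyclic/NIAS,,,no,129;111;201,detected,201.11221;111.04412;401.21721,yes,772,5,no,cyclic,none,2,0,0,0
[AA-BD]n,Cyclic/NIAS,3-5,,no,ND,detected,201.11221;111.04412;401.21721,no,,,,cyclic,none,5,0,0,0
[AA-BD]6,Cyclic/NIAS,,,no,ND,detected,ND,no,,,,cyclic,none,6,0,0,0
[AA-BD]-[TA-BD],Cyclic/NIAS,,,no,149;104;221,detected,221.08086;149.02332;111.04408,no,480,12,yes,cyclic,none,1,1,0,0
[AA-BD]m-[TA-BD]n,Cyclic/NIAS,2-3,1,no,ND,detected,387.10743;221.08101;149.02334,no,,,,cyclic,none,1,3,0,0
[AA-BD]m-[TA-BD]n,Cyclic/NIAS,1-3,2-4,no,ND,detected,221.08084;421.18570;149.02333,no,,,,cyclic,none,4,3,0,0
[AA-BD]m-[TA-BD]n,Cyclic/NIAS,1-4,5,no,ND,n = 1-3,221.08083;387.10739;421.18582,no,,,,cyclic,none,5,4,0,0
[AA-BD]m-[TA-BD]n,Cyclic/NIAS,1-3,6,no,ND,n = 1,201.11219;221.08089;401.21704,no,,,,cyclic,none,6,3,0,0
[AA-BD]m-[TA-BD]n,Cyclic/NIAS,1,7,no,ND,-,201.11222;221.08093;401.21714,no,,,,cyclic,none,7,1,0,0
[AA-BD]n-[TA-BD],Linear/NIAS,2-4,,no,ND,detected,ND,no,,,,linear,free,4,1,0,0
BD-[AA-BD]n,Linear/NIAS,2-4,,no,ND,detected,ND,no,,,,linear,bd_capped,4,0,0,0
BD-[AA-BD]m-[TA-BD]n,Linear/NIAS,"1,2",1,no,ND,detected,ND,no,,,,linear,bd_capped,1,2,0,0
BD-[AA-BD]m-[TA-BD]n,Linear/NIAS,"2,3",2,no,ND,detected,ND,no,,,,linear,bd_capped,2,3,0,0
BD-[AA-BD]m-[TA-BD]n,Linear/NIAS,"1,3",3,no,ND,detected,ND,no,,,,linear,bd_capped,3,3,0,0
BD-[AA-BD]m-[TA-BD]n,Linear/NIAS,1-2,4,no,ND,detected,ND,no,,,,linear,bd_capped,4,2,0,0
Me-[LA]7-[AA-BD]n,Linear/NIAS,"0-2,4",,no,ND,detected,ND,no,,,,linear,methyl_capped,4,0,0,7
[TA-BD]2,Cyclic/NIAS,,,no,132;149;104,detected,387.10762;149.02344;369.09713,yes,348,9,no,cyclic,none,0,2,0,0
[TA-BD]3,Cyclic/NIAS,,,no,ND,detected,149.02336;387.10745;589.17051,yes,,,,cyclic,none,0,3,0,0
[TA-BD]-[SeA-BD],Cyclic/NIAS,,,no,149;221;166,detected,149.02332;405.19086;221.08094,no,297,7,yes,cyclic,none,0,1,1,0
[TA-BD]m-[SeA-BD]n,Cyclic/NIAS,2-5,1,no,ND,n = 2-4,149.02336;203.12774;257.17491,no,,,,cyclic,none,0,1,5,0
[TA-BD]m-[SeA-BD]n,Cyclic/NIAS,1-4,2,no,ND,detected,149.02336;203.12774;387.10728,no,,,,cyclic,none,0,2,4,0
[TA-BD]m-[SeA-BD]n,Cyclic/NIAS,1-4,3,no,ND,n = 1-3,149.02336;387.10728;203.12774,no,,,,cyclic,none,0,3,4,0
[SeA-BD],Cyclic/NIAS,,,no,166;98;138,detected,185.11730;257.17473;203.12781,no,588,15,yes,cyclic,none,0,0,1,0
[SeA-BD]2,Cyclic/NIAS,,,no,185;257;166,detected,185.11730;257.17491;513.34218,no,252,3,yes,cyclic,none,0,0,2,0
[SeA-BD]n,Cyclic/NIAS,3-4,,no,ND,detected,257.17487;203.12789;185.11733,no,,,,cyclic,none,0,0,4,0
[LA]2,Cyclic/NIAS,,,no,56;28;43,-,ND,yes,,,,cyclic,none,0,0,0,2
[LA]n,Cyclic/NIAS,6-12,,no,ND,detected,ND,no,,,,cyclic,none,0,0,0,12
[LA]n-Me,Linear/NIAS,2,,no,ND,detected,ND,no,,,,linear,methyl_capped,0,0,0,2
[LA]n-Me,Linear/NIAS,3-10,,no,ND,detected,105.05464;145.04955;89.05973,no,,,,linear,methyl_capped,0,0,0,10
[LA]n-Me,Linear/NIAS,11-20,,no,ND,detected,ND,no,,,,linear,methyl_capped,0,0,0,20
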