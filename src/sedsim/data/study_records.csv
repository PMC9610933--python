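regimen_id,source,sedation_target,recovery_scale,recovery_target,procedure,T_p,T_rs,T_rs_sd
1,study1,not_reported,eye_opening,eye_opening,colonoscopy,25,9.4,12.8
2,study1,not_reported,eye_opening,eye_opening,colonoscopy,25,7.3,7.7
3,study2,moderate,MOAA/S,5,EGD,11,11,3
4,study2,moderate,MOAA/S,5,EGD,12,23,7
5,study3,deep,reversed_OAA/S,1,EGD,8,30,-20
6,study3,deep,reversed_OAA/S,1,colonoscopy,22,30,-20
7,study4,deep,MOAA/S,5,combined_EGD_colonoscopy,25,2.4,2.6
8,study5,moderate,MOAA/S,talking,colonoscopy,16,2.4,1.7
9,study6,moderate,modified_Aldrete,10,ERCP,28,18.37,7.86
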