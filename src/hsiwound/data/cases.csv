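case_id,stage,nurse_lw_cm2,machine_lw_cm2,machine_morph_cm2,outlier
Case 01,2,1.46,2.19,3.60,False
Case 02,3,12.05,10.22,22.60,True
Case 03,unstageable,9.86,7.42,5.00,False
Case 04,2,0.18,0.09,0.30,False
Case 05,3,34.49,26.28,26.10,False
Case 06,3,4.93,5.11,20.70,True
Case 07,unstageable,6.57,14.86,26.50,True
Case 08,unstageable,54.75,40.88,26.80,False
Case 09,4,14.60,10.07,7.90,False
Case 10,3,35.95,11.68,11.60,False
Case 11,2,23.66,11.41,7.00,False
Case 12,2,18.25,8.76,7.10,False
Case 13,2,10.95,8.41,8.80,False
Case 14,3,3.65,3.10,2.70,False
Case 15,unstageable,39.79,36.73,34.40,False
Case 16,2,1.21,5.26,3.80,False
Case 17,3,39.89,35.77,35.40,False
Case 18,3,25.55,15.42,13.70,False
Case 19,2,59.13,35.04,25.70,False
Case 20,2,77.38,29.20,29.60,False
Case 21,1,1.64,7.01,39.10,True
Case 22,3,65.70,33.73,32.60,False
Case 23,1,0.04,0.73,27.20,True
Case 24,2,4.38,4.38,20.40,True
Case 25,3,20.44,13.14,12.10,False
Case 26,2,14.60,6.48,6.50,False
Case 27,3,24.09,21.90,16.10,False
Case 28,2,52.56,2.92,1.10,True
Case 29,2,3.07,0.61,0.50,False
Case 30,2,3.29,0.73,0.70,False
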