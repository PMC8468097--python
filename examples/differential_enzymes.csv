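ec,logFC,PValue,FDR,association
1.1.1.18,0.7416,0.28264726,0.56529452,not_associated
1.1.1.36,1.9612,0.00740668,0.01481336,treatment_1
1.1.1.54,-4.1572,0.00031784,0.00063567,treatment_2
1.4.4.12,2.547,0.00602019,0.01204038,treatment_1
1.4.4.30,-4.7221,0.00701325,0.01402651,treatment_2
1.4.4.48,-3.5214,0.00278191,0.00556383,treatment_2
1.7.7.24,0.6981,0.37323799,0.74647598,not_associated
1.7.7.42,5.8075,0.00336595,0.0067319,treatment_1
1.7.7.6,1.9352,0.00847495,0.01694989,treatment_1
1.7.7.60,0.7297,0.55941669,1.0,not_associated
2.2.2.1,-0.0788,0.32851937,0.65703873,not_associated
2.2.2.19,-0.5774,0.71934324,1.0,not_associated
2.2.2.37,2.5255,0.00289389,0.00578777,treatment_1
2.2.2.55,2.5476,0.00101002,0.00202005,treatment_1
2.5.5.13,4.3606,0.00364833,0.00729666,treatment_1
2.5.5.31,-2.4428,0.00266979,0.00533957,treatment_2
2.5.5.49,0.6091,0.21258172,0.42516343,not_associated
2.8.8.25,0.4623,0.30645044,0.61290087,not_associated
2.8.8.43,0.6846,0.85070932,1.0,not_associated
2.8.8.7,0.8218,0.81479351,1.0,not_associated
3.3.3.2,-1.7978,0.00913136,0.01826272,treatment_2
3.3.3.20,-4.7306,0.00212627,0.00425255,treatment_2
3.3.3.38,-5.4811,0.00642852,0.01285704,treatment_2
3.3.3.56,2.1283,0.00744989,0.01489978,treatment_1
3.6.6.14,-4.8616,0.00428434,0.00856869,treatment_2
3.6.6.32,-3.129,0.00997326,0.01994652,treatment_2
3.6.6.50,3.7208,0.00755782,0.01511565,treatment_1
3.9.9.26,0.6274,0.8024754,1.0,not_associated
3.9.9.44,-1.7859,0.0038162,0.0076324,treatment_2
3.9.9.8,-0.9711,0.86774072,1.0,not_associated
4.1.1.27,4.7432,0.00681711,0.01363421,treatment_1
4.1.1.45,-2.7007,0.00640962,0.01281924,treatment_2
4.1.1.9,3.4564,0.00453724,0.00907449,treatment_1
4.4.4.21,-0.9719,0.77386409,1.0,not_associated
4.4.4.3,-1.9788,0.00625301,0.01250601,treatment_2
4.4.4.39,0.1528,0.77438526,1.0,not_associated
4.4.4.57,-5.0038,0.00530354,0.01060708,treatment_2
4.7.7.15,2.9587,0.00019478,0.00038955,treatment_1
4.7.7.33,-0.2395,0.27882801,0.55765603,not_associated
4.7.7.51,-1.8544,0.00731908,0.01463816,treatment_2
5.2.2.10,0.1284,0.50151826,1.0,not_associated
5.2.2.28,-2.6928,0.00872433,0.01744866,treatment_2
5.2.2.46,-2.4531,0.00539297,0.01078593,treatment_2
5.5.5.22,0.7129,0.42904268,0.85808537,not_associated
5.5.5.4,-0.4381,0.54169705,1.0,not_associated
5.5.5.40,2.5111,0.00338086,0.00676172,treatment_1
5.5.5.58,-2.5355,0.00220218,0.00440436,treatment_2
5.8.8.16,4.34,0.00228943,0.00457885,treatment_1
5.8.8.34,-0.0709,0.2761044,0.55220881,not_associated
5.8.8.52,0.5392,0.73718494,1.0,not_associated
6.3.3.11,-0.243,0.4993243,0.99864859,not_associated
6.3.3.29,-1.9245,0.00658983,0.01317966,treatment_2
6.3.3.47,-3.35,0.00863837,0.01727674,treatment_2
6.6.6.23,4.4405,0.0064618,0.0129236,treatment_1
6.6.6.41,4.777,0.00800593,0.01601185,treatment_1
6.6.6.5,2.3622,0.00536286,0.01072572,treatment_1
6.6.6.59,2.3257,0.00462629,0.00925257,treatment_1
6.9.9.17,0.4431,0.86828165,1.0,not_associated
6.9.9.35,-1.7276,0.00999282,0.01998565,treatment_2
6.9.9.53,0.9264,0.85626095,1.0,not_associated
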