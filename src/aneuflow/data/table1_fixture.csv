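model,outlet,bc1,bc1_dev,bc2,bc2_dev,bc3,bc3_dev,bc4,bc4_dev,bc5
1,1,0.513,41,0.401,25,0.465,35,0.345,13,0.301
1,2,0.209,-9,0.207,-10,0.173,-31,0.239,5,0.227
1,3,0.002,-900,0.016,-25,0.004,-400,0.019,-5,0.020
1,4,0.011,-555,0.054,-33,0.023,-213,0.069,-4,0.072
1,5,0.265,-44,0.322,-18,0.335,-14,0.033,-1055,0.381
2,1,0.397,36,0.295,14,0.351,28,0.255,0,0.254
2,2,0.187,-1,0.143,-31,0.119,-58,0.218,14,0.188
2,3,0.011,-1009,0.030,-307,0.011,-1009,0.139,12,0.122
2,4,0.086,59,0.095,63,0.064,45,0.026,-35,0.035
2,5,0.138,-56,0.181,-19,0.170,-26,0.194,-11,0.215
2,6,0.180,-3,0.256,27,0.284,35,0.167,-11,0.186
3,1,0.164,-62,0.236,-13,0.181,-47,0.274,3,0.266
3,2,0.098,-82,0.182,2,0.123,-45,0.190,6,0.178
3,3,0.738,25,0.581,4,0.697,20,0.536,-4,0.555
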