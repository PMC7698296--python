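farm,semester,x1,x2,numerator,denominator
F00,S0,0.304717,-1.68287,13,20
F00,S1,0.304717,-0.334885,9,20
F00,S2,0.304717,0.162753,10,20
F00,S3,0.304717,0.586222,9,20
F01,S0,-1.039984,0.711227,1,20
F01,S1,-1.039984,0.793347,0,20
F01,S2,-1.039984,-0.348725,1,20
F01,S3,-1.039984,-0.462352,3,20
F02,S0,0.750451,0.857976,7,20
F02,S1,0.750451,-0.191304,12,20
F02,S2,0.750451,-1.275686,15,20
F02,S3,0.750451,-1.133287,11,20
F03,S0,0.940565,-0.919452,8,20
F03,S1,0.940565,0.497161,3,20
F03,S2,0.940565,0.142426,7,20
F03,S3,0.940565,0.690485,4,20
F04,S0,-1.951035,-0.427253,0,20
F04,S1,-1.951035,0.15854,1,20
F04,S2,-1.951035,0.62559,2,20
F04,S3,-1.951035,-0.309347,0,20
F05,S0,-1.30218,0.456775,0,20
F05,S1,-1.30218,-0.661926,1,20
F05,S2,-1.30218,-0.363054,1,20
F05,S3,-1.30218,-0.381738,2,20
F06,S0,0.12784,-1.19584,7,20
F06,S1,0.12784,0.486972,1,20
F06,S2,0.12784,-0.469402,11,20
F06,S3,0.12784,0.012494,4,20
F07,S0,-0.316243,0.480747,3,20
F07,S1,-0.316243,0.446531,7,20
F07,S2,-0.316243,0.665385,3,20
F07,S3,-0.316243,-0.098485,11,20
F08,S0,-0.016801,-0.423298,6,20
F08,S1,-0.016801,-0.079718,6,20
F08,S2,-0.016801,-1.687334,7,20
F08,S3,-0.016801,-1.447112,9,20
F09,S0,-0.853044,-1.3227,4,20
F09,S1,-0.853044,-0.997247,6,20
F09,S2,-0.853044,0.399774,3,20
F09,S3,-0.853044,-0.905479,7,20
F10,S0,0.879398,-0.378163,8,20
F10,S1,0.879398,1.299228,9,20
F10,S2,0.879398,-0.356264,11,20
F10,S3,0.879398,0.737516,2,20
F11,S0,0.777792,-0.933618,3,20
F11,S1,0.777792,-0.205438,4,20
F11,S2,0.777792,-0.950022,10,20
F11,S3,0.777792,-0.339033,8,20
F12,S0,0.066031,0.840308,4,20
F12,S1,0.066031,-1.72732,11,20
F12,S2,0.066031,0.434424,5,20
F12,S3,0.066031,0.237736,8,20
F13,S0,1.127241,-0.59415,12,20
F13,S1,1.127241,-1.446058,10,20
F13,S2,1.127241,0.07213,10,20
F13,S3,1.127241,-0.529493,10,20
F14,S0,0.467509,0.232676,3,20
F14,S1,0.467509,0.021852,5,20
F14,S2,0.467509,1.601779,3,20
F14,S3,0.467509,-0.239356,6,20
F15,S0,-0.859292,-1.023497,4,20
F15,S1,-0.859292,0.179276,2,20
F15,S2,-0.859292,0.219997,4,20
F15,S3,-0.859292,1.359188,0,20
F16,S0,0.368751,0.835111,4,20
F16,S1,0.368751,0.356871,3,20
F16,S2,0.368751,1.463303,2,20
F16,S3,0.368751,-1.188763,7,20
F17,S0,-0.958883,-0.639752,5,20
F17,S1,-0.958883,-0.926576,3,20
F17,S2,-0.958883,-0.38981,0,20
F17,S3,-0.958883,-1.376686,2,20
F18,S0,0.87845,0.635151,3,20
F18,S1,0.87845,-0.222223,12,20
F18,S2,0.87845,-1.470806,12,20
F18,S3,0.87845,-1.015579,7,20
F19,S0,-0.049926,0.313514,0,20
F19,S1,-0.049926,0.838127,0,20
F19,S2,-0.049926,1.996731,3,20
F19,S3,-0.049926,2.913862,0,20
F20,S0,-0.184862,0.414409,5,20
F20,S1,-0.184862,-0.989538,8,20
F20,S2,-0.184862,-2.132046,11,20
F20,S3,-0.184862,0.267711,2,20
F21,S0,-0.68093,-0.812941,6,20
F21,S1,-0.68093,-0.415357,2,20
F21,S2,-0.68093,-0.612097,4,20
F21,S3,-0.68093,-0.140791,2,20
F22,S0,1.222541,1.06598,8,20
F22,S1,1.222541,0.157049,7,20
F22,S2,1.222541,-0.158635,14,20
F22,S3,1.222541,-1.035654,11,20
F23,S0,-0.154529,-1.674683,8,20
F23,S1,-0.154529,-0.486308,6,20
F23,S2,-0.154529,-0.053783,4,20
F23,S3,-0.154529,1.76793,0,20
F24,S0,-0.428328,0.130275,5,20
F24,S1,-0.428328,0.98274,4,20
F24,S2,-0.428328,-0.499296,9,20
F24,S3,-0.428328,-1.184944,8,20
F25,S0,-0.352134,-0.965117,7,20
F25,S1,-0.352134,-0.725226,6,20
F25,S2,-0.352134,2.12847,2,20
F25,S3,-0.352134,-0.821387,3,20
F26,S0,0.532309,0.838489,2,20
F26,S1,0.532309,-0.902927,3,20
F26,S2,0.532309,0.931573,0,20
F26,S3,0.532309,0.384951,1,20
F27,S0,0.365444,-0.156638,4,20
F27,S1,0.365444,-0.040763,3,20
F27,S2,0.365444,-0.654788,7,20
F27,S3,0.365444,0.446072,3,20
F28,S0,0.412733,-0.454983,4,20
F28,S1,0.412733,-1.225606,5,20
F28,S2,0.412733,-1.277938,6,20
F28,S3,0.412733,0.172588,1,20
F29,S0,0.430821,1.579091,3,20
F29,S1,0.430821,0.159992,4,20
F29,S2,0.430821,-0.118638,4,20
F29,S3,0.430821,0.285826,3,20
F30,S0,2.141648,1.306002,12,20
F30,S1,2.141648,0.219383,14,20
F30,S2,2.141648,-0.410927,15,20
F30,S3,2.141648,1.106289,7,20
F31,S0,-0.406415,0.428756,6,20
F31,S1,-0.406415,1.535756,2,20
F31,S2,-0.406415,0.183234,5,20
F31,S3,-0.406415,-1.224469,7,20
F32,S0,-0.512243,-1.368159,2,20
F32,S1,-0.512243,1.650928,2,20
F32,S2,-0.512243,1.723666,1,20
F32,S3,-0.512243,-0.179519,0,20
F33,S0,-0.813773,-0.383187,0,20
F33,S1,-0.813773,1.461444,2,20
F33,S2,-0.813773,-1.107046,1,20
F33,S3,-0.813773,-0.894727,1,20
F34,S0,0.615979,0.643327,3,20
F34,S1,0.615979,-0.394605,4,20
F34,S2,0.615979,-0.005122,5,20
F34,S3,0.615979,-0.163443,5,20
F35,S0,1.128972,0.337575,0,20
F35,S1,1.128972,1.407482,4,20
F35,S2,1.128972,0.090585,7,20
F35,S3,1.128972,0.643939,2,20
F36,S0,-0.113947,-2.050172,3,20
F36,S1,-0.113947,-0.048718,3,20
F36,S2,-0.113947,-0.84323,2,20
F36,S3,-0.113947,-1.218813,2,20
F37,S0,-0.840156,-0.878152,7,20
F37,S1,-0.840156,-0.334123,8,20
F37,S2,-0.840156,0.915903,3,20
F37,S3,-0.840156,-1.326393,3,20
F38,S0,-0.824481,0.030631,5,20
F38,S1,-0.824481,-0.484169,6,20
F38,S2,-0.824481,-0.327673,5,20
F38,S3,-0.824481,1.002758,2,20
F39,S0,0.650593,0.538115,1,20
F39,S1,0.650593,1.337398,3,20
F39,S2,0.650593,-0.154506,9,20
F39,S3,0.650593,-0.695943,5,20
F40,S0,0.743254,-0.223859,1,20
F40,S1,0.743254,0.242497,3,20
F40,S2,0.743254,0.176573,6,20
F40,S3,0.743254,-1.084388,2,20
F41,S0,0.543154,0.09049,7,20
F41,S1,0.543154,0.228228,11,20
F41,S2,0.543154,2.517474,1,20
F41,S3,0.543154,1.876845,2,20
F42,S0,-0.66551,-0.853243,3,20
F42,S1,-0.66551,-0.287383,1,20
F42,S2,-0.66551,-1.463442,7,20
F42,S3,-0.66551,-0.590707,2,20
F43,S0,0.232161,0.315605,4,20
F43,S1,0.232161,1.205854,2,20
F43,S2,0.232161,-0.729084,6,20
F43,S3,0.232161,-0.654146,8,20
F44,S0,0.116686,-2.147289,16,20
F44,S1,0.116686,-0.162666,7,20
F44,S2,0.116686,-1.062414,13,20
F44,S3,0.116686,-0.529439,7,20
F45,S0,0.218689,-0.876861,2,20
F45,S1,0.218689,-0.094263,1,20
F45,S2,0.218689,-1.757728,2,20
F45,S3,0.218689,-1.467045,1,20
F46,S0,0.871429,2.129247,3,20
F46,S1,0.871429,-1.287423,8,20
F46,S2,0.871429,-1.096786,9,20
F46,S3,0.871429,1.836914,2,20
F47,S0,0.223596,2.905067,2,20
F47,S1,0.223596,-1.171567,5,20
F47,S2,0.223596,-0.368249,7,20
F47,S3,0.223596,0.341556,4,20
F48,S0,0.678914,1.728698,1,20
F48,S1,0.678914,-0.986857,6,20
F48,S2,0.678914,-0.245278,3,20
F48,S3,0.678914,0.777338,2,20
F49,S0,0.067579,0.434766,8,20
F49,S1,0.067579,-0.376156,9,20
F49,S2,0.067579,-0.133823,12,20
F49,S3,0.067579,-1.374896,9,20
F50,S0,0.289119,-0.238174,7,20
F50,S1,0.289119,-0.266387,5,20
F50,S2,0.289119,0.23217,6,20
F50,S3,0.289119,-0.555327,5,20
F51,S0,0.631288,0.471539,4,20
F51,S1,0.631288,1.012716,5,20
F51,S2,0.631288,0.155429,11,20
F51,S3,0.631288,0.351756,6,20
F52,S0,-1.457156,0.053155,0,20
F52,S1,-1.457156,8.4e-05,1,20
F52,S2,-1.457156,-0.721558,1,20
F52,S3,-1.457156,0.316494,0,20
F53,S0,-0.319671,-0.097287,7,20
F53,S1,-0.319671,2.093168,2,20
F53,S2,-0.319671,1.573355,2,20
F53,S3,-0.319671,0.385847,3,20
F54,S0,-0.470373,-0.763057,1,20
F54,S1,-0.470373,-1.112411,6,20
F54,S2,-0.470373,1.191143,5,20
F54,S3,-0.470373,0.262749,4,20
F55,S0,-0.638878,0.480143,5,20
F55,S1,-0.638878,-1.744586,7,20
F55,S2,-0.638878,0.927438,2,20
F55,S3,-0.638878,0.45442,3,20
F56,S0,-0.275142,-1.110431,8,20
F56,S1,-0.275142,-0.471525,6,20
F56,S2,-0.275142,0.263717,7,20
F56,S3,-0.275142,0.052467,4,20
F57,S0,1.494941,-0.292171,12,20
F57,S1,1.494941,-0.103488,7,20
F57,S2,1.494941,-0.251977,9,20
F57,S3,1.494941,0.152563,6,20
F58,S0,-0.865831,1.471492,1,20
F58,S1,-0.865831,-2.566658,5,20
F58,S2,-0.865831,-0.23685,5,20
F58,S3,-0.865831,0.176512,3,20
F59,S0,0.968278,0.295994,4,20
F59,S1,0.968278,-0.371915,8,20
F59,S2,0.968278,-1.756722,10,20
F59,S3,0.968278,0.327995,3,20
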