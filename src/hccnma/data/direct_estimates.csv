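horizon,treatment,comparator,hr,ci_low,ci_high
1,TACE+EBRT,TACE,0.73,0.56,0.90
1,TACE+HIFU,TACE,0.24,0.21,0.28
1,TACE+PEI,TACE,0.48,0.41,0.54
1,TACE+RFA,TACE,0.52,0.39,0.66
1,TACE+RT,TACE,0.52,0.45,0.60
1,TACE+SOR,TACE,0.47,0.45,0.49
1,TARE-90Y,TACE,0.88,0.80,0.97
1,DEB-TACE,TACE,0.51,0.46,0.57
1,PEI,TACE,0.91,0.78,1.04
1,RFA,TACE,0.84,0.67,1.00
1,RT,TACE,0.42,0.32,0.52
1,PEI,TACE+PEI,2.04,1.69,2.56
1,RFA,TACE+RFA,2.13,1.92,2.44
1,RT,TACE+RT,6.25,5.00,8.33
1,PEI,PAI,1.33,0.90,2.56
1,RFA,PEI,0.30,0.20,0.41
2,TACE+EBRT,TACE,0.71,0.59,0.83
2,TACE+HIFU,TACE,0.25,0.22,0.28
2,TACE+PEI,TACE,0.51,0.46,0.56
2,TACE+RFA,TACE,0.53,0.42,0.63
2,TACE+RT,TACE,0.53,0.47,0.59
2,TACE+SOR,TACE,0.55,0.50,0.60
2,TARE-90Y,TACE,0.87,0.80,0.94
2,DEB-TACE,TACE,0.52,0.47,0.57
2,RFA,TACE,0.90,0.80,0.99
2,RT,TACE,0.44,0.34,0.54
2,PEI,TACE+PEI,2.02,1.77,2.35
2,RFA,TACE+RFA,1.90,1.66,2.22
2,RT,TACE+RT,5.56,4.44,7.41
2,PEI,PAI,1.78,0.93,1.60
2,RFA,PEI,0.43,0.35,0.50
3,TACE+EBRT,TACE,0.69,0.59,0.80
3,TACE+HIFU,TACE,0.41,0.35,0.48
3,TACE+PEI,TACE,0.50,0.43,0.56
3,TACE+RFA,TACE,0.56,0.46,0.65
3,TACE+RT,TACE,0.54,0.48,0.60
3,TACE+SOR,TACE,0.64,0.56,0.72
3,TARE-90Y,TACE,0.84,0.77,0.90
3,DEB-TACE,TACE,0.50,0.44,0.56
3,RFA,TACE,0.80,0.69,0.91
3,RT,TACE,0.44,0.34,0.54
3,PEI,TACE+PEI,1.39,0.82,4.55
3,RFA,TACE+RFA,1.76,1.56,2.00
3,RT,TACE+RT,5.56,4.44,7.41
3,PEI,PAI,1.14,0.93,1.45
3,RFA,PEI,0.48,0.41,0.55
4,TACE+EBRT,TACE,0.69,0.59,0.80
4,TACE+HIFU,TACE,0.41,0.35,0.48
4,TACE+PEI,TACE,1.29,0.92,1.66
4,TACE+RFA,TACE,0.60,0.50,0.69
4,TACE+RT,TACE,0.55,0.49,0.60
4,TACE+SOR,TACE,0.67,0.57,0.76
4,TARE-90Y,TACE,0.86,0.79,0.93
4,DEB-TACE,TACE,0.94,0.74,1.14
4,RT,TACE,0.44,0.34,0.54
4,PEI,TACE+PEI,1.39,0.82,4.54
4,RFA,TACE+RFA,1.59,1.43,1.79
4,RT,TACE+RT,5.56,4.44,7.41
4,RFA,PEI,0.80,0.65,0.94
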