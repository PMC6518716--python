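patient,position,probe,nivbs_mm,ref_mm
1,anterior,1,4.86,4.83
1,anterior,2,4.67,4.82
1,anterior,3,4.87,4.81
1,anterior,4,4.78,4.85
1,posterior,1,5.12,4.94
1,posterior,2,4.87,4.97
1,posterior,3,4.91,4.99
1,posterior,4,4.88,5.00
1,left,1,3.92,3.79
1,left,2,3.92,3.84
1,left,3,3.73,3.82
1,left,4,3.79,3.77
1,right,1,4.16,3.88
1,right,2,3.89,3.91
1,right,3,3.96,3.93
1,right,4,3.58,3.78
2,anterior,1,4.13,4.10
2,anterior,2,3.99,4.06
2,anterior,3,4.10,3.99
2,anterior,4,4.07,4.01
2,posterior,1,4.16,4.10
2,posterior,2,4.15,4.15
2,posterior,3,4.21,4.20
2,posterior,4,4.16,4.15
2,left,1,3.92,3.73
2,left,2,3.75,3.76
2,left,3,3.58,3.78
2,left,4,3.92,3.75
2,right,1,3.89,3.93
2,right,2,3.73,3.81
2,right,3,3.79,3.83
2,right,4,3.96,3.87
3,anterior,1,3.79,3.72
3,anterior,2,3.54,3.65
3,anterior,3,3.61,3.61
3,anterior,4,3.78,3.68
3,posterior,1,3.86,3.95
3,posterior,2,4.02,3.99
3,posterior,3,3.98,3.94
3,posterior,4,4.04,3.96
3,left,1,3.26,3.49
3,left,2,3.66,3.54
3,left,3,3.74,3.52
3,left,4,3.59,3.55
3,right,1,3.56,3.58
3,right,2,3.57,3.56
3,right,3,3.40,3.51
3,right,4,3.45,3.50
4,anterior,1,3.59,3.63
4,anterior,2,3.52,3.59
4,anterior,3,3.63,3.61
4,anterior,4,3.55,3.59
4,posterior,1,3.77,3.76
4,posterior,2,3.77,3.81
4,posterior,3,3.77,3.74
4,posterior,4,3.79,3.73
4,left,1,3.40,3.51
4,left,2,3.47,3.47
4,left,3,3.51,3.53
4,left,4,3.39,3.49
4,right,1,3.50,3.32
4,right,2,3.15,3.31
4,right,3,3.43,3.38
4,right,4,3.24,3.35
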