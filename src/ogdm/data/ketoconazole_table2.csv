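replicate,fish,treatment_ug_per_L,c_vtg_nmol_per_uL
1,1,0,0.077
1,1,6,0.067
1,1,25,0.065
1,1,100,0.065
1,1,400,0.048
1,2,0,0.054
1,2,6,0.083
1,2,25,0.101
1,2,100,0.084
1,2,400,0.072
1,3,0,0.165
1,3,6,0.142
1,3,25,0.063
1,3,100,0.119
1,3,400,0.090
1,4,0,0.122
1,4,6,0.063
1,4,25,0.066
1,4,100,0.176
1,4,400,0.083
2,1,0,0.059
2,1,6,0.152
2,1,25,0.088
2,1,100,0.085
2,1,400,0.086
2,2,0,0.062
2,2,6,0.162
2,2,25,0.209
2,2,100,0.077
2,2,400,0.081
2,3,0,0.055
2,3,6,0.192
2,3,25,0.073
2,3,100,0.060
2,3,400,0.107
2,4,0,0.133
2,4,6,0.101
2,4,25,0.162
2,4,100,0.086
2,4,400,0.083
3,1,0,0.106
3,1,6,0.176
3,1,25,0.088
3,1,100,0.025
3,1,400,0.108
3,2,0,0.080
3,2,6,0.084
3,2,25,0.088
3,2,100,0.111
3,2,400,0.061
3,3,0,0.128
3,3,6,0.078
3,3,25,0.029
3,3,100,0.104
3,3,400,0.027
3,4,6,0.065
3,4,25,0.069
3,4,100,0.053
4,1,0,0.059
4,1,6,0.188
4,1,25,0.076
4,1,100,0.052
4,1,400,0.054
4,2,0,0.049
4,2,6,0.021
4,2,25,0.066
4,2,100,0.090
4,2,400,0.125
4,3,0,0.057
4,3,6,0.096
4,3,25,0.092
4,3,100,0.046
4,3,400,0.166
4,4,6,0.080
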