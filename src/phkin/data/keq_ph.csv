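reaction,ph,keq
HXK,6,316.979
HXK,6.1,399.052
HXK,6.2,502.377
HXK,6.3,632.456
HXK,6.4,796.214
HXK,6.5,1002.37
HXK,6.6,1261.91
HXK,6.7,1588.66
HXK,6.8,2000
HXK,6.9,2517.85
HXK,7,3169.79
HXK,7.1,3990.52
HXK,7.2,5023.77
HXK,7.3,6324.56
HXK,7.4,7962.14
HXK,7.5,10023.7
HXK,7.6,12619.1
HXK,7.7,15886.6
HXK,7.8,20000
HXK,7.9,25178.5
HXK,8,31697.9
PGI,6,0.264483
PGI,6.1,0.267546
PGI,6.2,0.270644
PGI,6.3,0.273778
PGI,6.4,0.276948
PGI,6.5,0.280155
PGI,6.6,0.283399
PGI,6.7,0.28668
PGI,6.8,0.29
PGI,6.9,0.293358
PGI,7,0.296755
PGI,7.1,0.300191
PGI,7.2,0.303667
PGI,7.3,0.307184
PGI,7.4,0.310741
PGI,7.5,0.314339
PGI,7.6,0.317979
PGI,7.7,0.321661
PGI,7.8,0.325385
PGI,7.9,0.329153
PGI,8,0.332965
PFK,6,200.951
PFK,6.1,238.831
PFK,6.2,283.851
PFK,6.3,337.357
PFK,6.4,400.95
PFK,6.5,476.53
PFK,6.6,566.357
PFK,6.7,673.116
PFK,6.8,800
PFK,6.9,950.802
PFK,7,1130.03
PFK,7.1,1343.04
PFK,7.2,1596.21
PFK,7.3,1897.1
PFK,7.4,2254.71
PFK,7.5,2679.72
PFK,7.6,3184.86
PFK,7.7,3785.21
PFK,7.8,4498.73
PFK,7.9,5346.75
PFK,8,6354.63
ALD,6,0.0573917
ALD,6.1,0.0587285
ALD,6.2,0.0600965
ALD,6.3,0.0614963
ALD,6.4,0.0629287
ALD,6.5,0.0643945
ALD,6.6,0.0658945
ALD,6.7,0.0674294
ALD,6.8,0.069
ALD,6.9,0.0706072
ALD,7,0.0722519
ALD,7.1,0.0739348
ALD,7.2,0.075657
ALD,7.3,0.0774193
ALD,7.4,0.0792226
ALD,7.5,0.0810679
ALD,7.6,0.0829562
ALD,7.7,0.0848885
ALD,7.8,0.0868659
ALD,7.9,0.0888892
ALD,8,0.0909597
TPI,6,21.2042
TPI,6.1,21.3021
TPI,6.2,21.4004
TPI,6.3,21.4992
TPI,6.4,21.5985
TPI,6.5,21.6981
TPI,6.6,21.7983
TPI,6.7,21.8989
TPI,6.8,22
TPI,6.9,22.1015
TPI,7,22.2036
TPI,7.1,22.3061
TPI,7.2,22.409
TPI,7.3,22.5124
TPI,7.4,22.6164
TPI,7.5,22.7208
TPI,7.6,22.8256
TPI,7.7,22.931
TPI,7.8,23.0368
TPI,7.9,23.1432
TPI,8,23.25
GAPDH,6,0.001
GAPDH,6.1,0.00133352
GAPDH,6.2,0.00177828
GAPDH,6.3,0.00237137
GAPDH,6.4,0.00316228
GAPDH,6.5,0.00421697
GAPDH,6.6,0.00562341
GAPDH,6.7,0.00749894
GAPDH,6.8,0.01
GAPDH,6.9,0.0133352
GAPDH,7,0.0177828
GAPDH,7.1,0.0237137
GAPDH,7.2,0.0316228
GAPDH,7.3,0.0421697
GAPDH,7.4,0.0562341
GAPDH,7.5,0.0749894
GAPDH,7.6,0.1
GAPDH,7.7,0.133352
GAPDH,7.8,0.177828
GAPDH,7.9,0.237137
GAPDH,8,0.316228
PGM,6,0.179785
PGM,6.1,0.181031
PGM,6.2,0.182286
PGM,6.3,0.18355
PGM,6.4,0.184822
PGM,6.5,0.186103
PGM,6.6,0.187393
PGM,6.7,0.188692
PGM,6.8,0.19
PGM,6.9,0.191317
PGM,7,0.192643
PGM,7.1,0.193979
PGM,7.2,0.195323
PGM,7.3,0.196677
PGM,7.4,0.19804
PGM,7.5,0.199413
PGM,7.6,0.200795
PGM,7.7,0.202187
PGM,7.8,0.203589
PGM,7.9,0.205
PGM,8,0.206421
ENO,6,5.78196
ENO,6.1,5.88945
ENO,6.2,5.99894
ENO,6.3,6.11047
ENO,6.4,6.22407
ENO,6.5,6.33979
ENO,6.6,6.45765
ENO,6.7,6.57771
ENO,6.8,6.7
ENO,6.9,6.82456
ENO,7,6.95144
ENO,7.1,7.08068
ENO,7.2,7.21232
ENO,7.3,7.3464
ENO,7.4,7.48298
ENO,7.5,7.6221
ENO,7.6,7.76381
ENO,7.7,7.90815
ENO,7.8,8.05517
ENO,7.9,8.20493
ENO,8,8.35747
PYK,6,2152.35
PYK,6.1,2471.23
PYK,6.2,2837.35
PYK,6.3,3257.72
PYK,6.4,3740.36
PYK,6.5,4294.51
PYK,6.6,4930.75
PYK,6.7,5661.26
PYK,6.8,6500
PYK,6.9,7463
PYK,7,8568.67
PYK,7.1,9838.15
PYK,7.2,11295.7
PYK,7.3,12969.2
PYK,7.4,14890.6
PYK,7.5,17096.7
PYK,7.6,19629.7
PYK,7.7,22537.9
PYK,7.8,25877
PYK,7.9,29710.7
PYK,8,34112.5
PDC,6,1905.46
PDC,6.1,2344.23
PDC,6.2,2884.03
PDC,6.3,3548.13
PDC,6.4,4365.16
PDC,6.5,5370.32
PDC,6.6,6606.93
PDC,6.7,8128.31
PDC,6.8,10000
PDC,6.9,12302.7
PDC,7,15135.6
PDC,7.1,18620.9
PDC,7.2,22908.7
PDC,7.3,28183.8
PDC,7.4,34673.7
PDC,7.5,42658
PDC,7.6,52480.7
PDC,7.7,64565.4
PDC,7.8,79432.8
PDC,7.9,97723.7
PDC,8,120226
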