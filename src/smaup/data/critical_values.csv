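rho,alpha,N,value
-0.9,0.01,25,0.83702
-0.9,0.01,100,0.09218
-0.9,0.01,225,0.23808
-0.9,0.01,400,0.05488
-0.9,0.01,625,0.07218
-0.9,0.01,900,0.02621
-0.9,0.05,25,0.83699
-0.9,0.05,100,0.08023
-0.9,0.05,225,0.10962
-0.9,0.05,400,0.04894
-0.9,0.05,625,0.04641
-0.9,0.05,900,0.02423
-0.9,0.1,25,0.69331
-0.9,0.1,100,0.06545
-0.9,0.1,225,0.07858
-0.9,0.1,400,0.04015
-0.9,0.1,625,0.03374
-0.9,0.1,900,0.02187
-0.7,0.01,25,0.83676
-0.7,0.01,100,0.16134
-0.7,0.01,225,0.13402
-0.7,0.01,400,0.06737
-0.7,0.01,625,0.05486
-0.7,0.01,900,0.02858
-0.7,0.05,25,0.83662
-0.7,0.05,100,0.12492
-0.7,0.05,225,0.08643
-0.7,0.05,400,0.05900
-0.7,0.05,625,0.04280
-0.7,0.05,900,0.02459
-0.7,0.1,25,0.79421
-0.7,0.1,100,0.09566
-0.7,0.1,225,0.06777
-0.7,0.1,400,0.05058
-0.7,0.1,625,0.03392
-0.7,0.1,900,0.02272
-0.5,0.01,25,0.83597
-0.5,0.01,100,0.16524
-0.5,0.01,225,0.13446
-0.5,0.01,400,0.06616
-0.5,0.01,625,0.06247
-0.5,0.01,900,0.02851
-0.5,0.05,25,0.83578
-0.5,0.05,100,0.13796
-0.5,0.05,225,0.08679
-0.5,0.05,400,0.05927
-0.5,0.05,625,0.04260
-0.5,0.05,900,0.02658
-0.5,0.1,25,0.68900
-0.5,0.1,100,0.10707
-0.5,0.1,225,0.07039
-0.5,0.1,400,0.05151
-0.5,0.1,625,0.03609
-0.5,0.1,900,0.02411
-0.3,0.01,25,0.83316
-0.3,0.01,100,0.19276
-0.3,0.01,225,0.13396
-0.3,0.01,400,0.06330
-0.3,0.01,625,0.06090
-0.3,0.01,900,0.03696
-0.3,0.05,25,0.78849
-0.3,0.05,100,0.16932
-0.3,0.05,225,0.08775
-0.3,0.05,400,0.05464
-0.3,0.05,625,0.04787
-0.3,0.05,900,0.03042
-0.3,0.1,25,0.73592
-0.3,0.1,100,0.14282
-0.3,0.1,225,0.07076
-0.3,0.1,400,0.04649
-0.3,0.1,625,0.04001
-0.3,0.1,900,0.02614
0.0,0.01,25,0.82370
0.0,0.01,100,0.17925
0.0,0.01,225,0.15514
0.0,0.01,400,0.07732
0.0,0.01,625,0.07988
0.0,0.01,900,0.09301
0.0,0.05,25,0.81952
0.0,0.05,100,0.15746
0.0,0.05,225,0.11126
0.0,0.05,400,0.06961
0.0,0.05,625,0.06066
0.0,0.05,900,0.05234
0.0,0.1,25,0.71632
0.0,0.1,100,0.13621
0.0,0.1,225,0.08801
0.0,0.1,400,0.06112
0.0,0.1,625,0.04937
0.0,0.1,900,0.03759
0.3,0.01,25,0.76472
0.3,0.01,100,0.23404
0.3,0.01,225,0.24640
0.3,0.01,400,0.11588
0.3,0.01,625,0.10715
0.3,0.01,900,0.07070
0.3,0.05,25,0.70466
0.3,0.05,100,0.21088
0.3,0.05,225,0.15360
0.3,0.05,400,0.09766
0.3,0.05,625,0.07938
0.3,0.05,900,0.06461
0.3,0.1,25,0.63718
0.3,0.1,100,0.18239
0.3,0.1,225,0.12101
0.3,0.1,400,0.08324
0.3,0.1,625,0.06347
0.3,0.1,900,0.05549
0.5,0.01,25,0.67337
0.5,0.01,100,0.28921
0.5,0.01,225,0.25535
0.5,0.01,400,0.13992
0.5,0.01,625,0.12975
0.5,0.01,900,0.09856
0.5,0.05,25,0.59461
0.5,0.05,100,0.23497
0.5,0.05,225,0.18244
0.5,0.05,400,0.11682
0.5,0.05,625,0.10129
0.5,0.05,900,0.08860
0.5,0.1,25,0.46548
0.5,0.1,100,0.17541
0.5,0.1,225,0.14248
0.5,0.1,400,0.10008
0.5,0.1,625,0.08137
0.5,0.1,900,0.07701
0.7,0.01,25,0.52155
0.7,0.01,100,0.47399
0.7,0.01,225,0.29351
0.7,0.01,400,0.23923
0.7,0.01,625,0.20321
0.7,0.01,900,0.16250
0.7,0.05,25,0.48958
0.7,0.05,100,0.37226
0.7,0.05,225,0.22280
0.7,0.05,400,0.20540
0.7,0.05,625,0.16144
0.7,0.05,900,0.14123
0.7,0.1,25,0.34720
0.7,0.1,100,0.28774
0.7,0.1,225,0.18170
0.7,0.1,400,0.16442
0.7,0.1,625,0.13395
0.7,0.1,900,0.12354
0.9,0.01,25,0.28599
0.9,0.01,100,0.28938
0.9,0.01,225,0.43520
0.9,0.01,400,0.44060
0.9,0.01,625,0.34437
0.9,0.01,900,0.55967
0.9,0.05,25,0.21580
0.9,0.05,100,0.22532
0.9,0.05,225,0.27122
0.9,0.05,400,0.29043
0.9,0.05,625,0.23648
0.9,0.05,900,0.31424
0.9,0.1,25,0.17640
0.9,0.1,100,0.18835
0.9,0.1,225,0.21695
0.9,0.1,400,0.23031
0.9,0.1,625,0.19435
0.9,0.1,900,0.22411
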