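sex,agemos,L,M,S
female,24,-1.4000,16.4500,0.0800
female,25,-1.4150,16.4244,0.0803
female,26,-1.4300,16.3994,0.0806
female,27,-1.4450,16.3749,0.0809
female,28,-1.4600,16.3509,0.0812
female,29,-1.4750,16.3274,0.0815
female,30,-1.4900,16.3045,0.0818
female,31,-1.5050,16.2821,0.0821
female,32,-1.5200,16.2602,0.0824
female,33,-1.5350,16.2389,0.0827
female,34,-1.5500,16.2181,0.0830
female,35,-1.5650,16.1978,0.0833
female,36,-1.5800,16.1780,0.0836
female,37,-1.5950,16.1588,0.0839
female,38,-1.6100,16.1401,0.0842
female,39,-1.6250,16.1219,0.0845
female,40,-1.6400,16.1042,0.0848
female,41,-1.6550,16.0871,0.0851
female,42,-1.6700,16.0705,0.0854
female,43,-1.6850,16.0544,0.0857
female,44,-1.7000,16.0389,0.0860
female,45,-1.7150,16.0239,0.0863
female,46,-1.7300,16.0094,0.0866
female,47,-1.7450,15.9954,0.0869
female,48,-1.7600,15.9820,0.0872
female,49,-1.7750,15.9691,0.0875
female,50,-1.7900,15.9567,0.0878
female,51,-1.8050,15.9449,0.0881
female,52,-1.8200,15.9336,0.0884
female,53,-1.8350,15.9228,0.0887
female,54,-1.8500,15.9125,0.0890
female,55,-1.8650,15.9028,0.0893
female,56,-1.8800,15.8936,0.0896
female,57,-1.8950,15.8849,0.0899
female,58,-1.9100,15.8767,0.0902
female,59,-1.9250,15.8691,0.0905
female,60,-1.9400,15.8620,0.0908
female,61,-1.9550,15.8554,0.0911
female,62,-1.9700,15.8494,0.0914
female,63,-1.9850,15.8439,0.0917
female,64,-2.0000,15.8389,0.0920
female,65,-2.0150,15.8344,0.0923
female,66,-2.0300,15.8305,0.0926
female,67,-2.0450,15.8271,0.0929
female,68,-2.0600,15.8242,0.0932
female,69,-2.0750,15.8219,0.0935
female,70,-2.0900,15.8201,0.0938
female,71,-2.1050,15.8188,0.0941
female,72,-2.1200,15.8180,0.0944
female,73,-2.1350,15.8178,0.0947
female,74,-2.1500,15.8181,0.0950
female,75,-2.1650,15.8189,0.0953
female,76,-2.1800,15.8202,0.0956
female,77,-2.1950,15.8221,0.0959
female,78,-2.2100,15.8245,0.0962
female,79,-2.2250,15.8274,0.0965
female,80,-2.2400,15.8309,0.0968
female,81,-2.2550,15.8349,0.0971
female,82,-2.2700,15.8394,0.0974
female,83,-2.2850,15.8444,0.0977
female,84,-2.3000,15.8500,0.0980
male,24,-1.5000,16.5700,0.0800
male,25,-1.5150,16.5444,0.0803
male,26,-1.5300,16.5194,0.0806
male,27,-1.5450,16.4949,0.0809
male,28,-1.5600,16.4709,0.0812
male,29,-1.5750,16.4474,0.0815
male,30,-1.5900,16.4245,0.0818
male,31,-1.6050,16.4021,0.0821
male,32,-1.6200,16.3802,0.0824
male,33,-1.6350,16.3589,0.0827
male,34,-1.6500,16.3381,0.0830
male,35,-1.6650,16.3178,0.0833
male,36,-1.6800,16.2980,0.0836
male,37,-1.6950,16.2788,0.0839
male,38,-1.7100,16.2601,0.0842
male,39,-1.7250,16.2419,0.0845
male,40,-1.7400,16.2242,0.0848
male,41,-1.7550,16.2071,0.0851
male,42,-1.7700,16.1905,0.0854
male,43,-1.7850,16.1744,0.0857
male,44,-1.8000,16.1589,0.0860
male,45,-1.8150,16.1439,0.0863
male,46,-1.8300,16.1294,0.0866
male,47,-1.8450,16.1154,0.0869
male,48,-1.8600,16.1020,0.0872
male,49,-1.8750,16.0891,0.0875
male,50,-1.8900,16.0767,0.0878
male,51,-1.9050,16.0649,0.0881
male,52,-1.9200,16.0536,0.0884
male,53,-1.9350,16.0428,0.0887
male,54,-1.9500,16.0325,0.0890
male,55,-1.9650,16.0228,0.0893
male,56,-1.9800,16.0136,0.0896
male,57,-1.9950,16.0049,0.0899
male,58,-2.0100,15.9967,0.0902
male,59,-2.0250,15.9891,0.0905
male,60,-2.0400,15.9820,0.0908
male,61,-2.0550,15.9754,0.0911
male,62,-2.0700,15.9694,0.0914
male,63,-2.0850,15.9639,0.0917
male,64,-2.1000,15.9589,0.0920
male,65,-2.1150,15.9544,0.0923
male,66,-2.1300,15.9505,0.0926
male,67,-2.1450,15.9471,0.0929
male,68,-2.1600,15.9442,0.0932
male,69,-2.1750,15.9419,0.0935
male,70,-2.1900,15.9401,0.0938
male,71,-2.2050,15.9388,0.0941
male,72,-2.2200,15.9380,0.0944
male,73,-2.2350,15.9378,0.0947
male,74,-2.2500,15.9381,0.0950
male,75,-2.2650,15.9389,0.0953
male,76,-2.2800,15.9402,0.0956
male,77,-2.2950,15.9421,0.0959
male,78,-2.3100,15.9445,0.0962
male,79,-2.3250,15.9474,0.0965
male,80,-2.3400,15.9509,0.0968
male,81,-2.3550,15.9549,0.0971
male,82,-2.3700,15.9594,0.0974
male,83,-2.3850,15.9644,0.0977
male,84,-2.4000,15.9700,0.0980
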