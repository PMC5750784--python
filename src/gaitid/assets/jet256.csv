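r,g,b
0.000000,0.000000,0.500000
0.000000,0.000000,0.515686
0.000000,0.000000,0.531373
0.000000,0.000000,0.547059
0.000000,0.000000,0.562745
0.000000,0.000000,0.578431
0.000000,0.000000,0.594118
0.000000,0.000000,0.609804
0.000000,0.000000,0.625490
0.000000,0.000000,0.641176
0.000000,0.000000,0.656863
0.000000,0.000000,0.672549
0.000000,0.000000,0.688235
0.000000,0.000000,0.703922
0.000000,0.000000,0.719608
0.000000,0.000000,0.735294
0.000000,0.000000,0.750980
0.000000,0.000000,0.766667
0.000000,0.000000,0.782353
0.000000,0.000000,0.798039
0.000000,0.000000,0.813725
0.000000,0.000000,0.829412
0.000000,0.000000,0.845098
0.000000,0.000000,0.860784
0.000000,0.000000,0.876471
0.000000,0.000000,0.892157
0.000000,0.000000,0.907843
0.000000,0.000000,0.923529
0.000000,0.000000,0.939216
0.000000,0.000000,0.954902
0.000000,0.000000,0.970588
0.000000,0.000000,0.986275
0.000000,0.001961,1.000000
0.000000,0.017647,1.000000
0.000000,0.033333,1.000000
0.000000,0.049020,1.000000
0.000000,0.064706,1.000000
0.000000,0.080392,1.000000
0.000000,0.096078,1.000000
0.000000,0.111765,1.000000
0.000000,0.127451,1.000000
0.000000,0.143137,1.000000
0.000000,0.158824,1.000000
0.000000,0.174510,1.000000
0.000000,0.190196,1.000000
0.000000,0.205882,1.000000
0.000000,0.221569,1.000000
0.000000,0.237255,1.000000
0.000000,0.252941,1.000000
0.000000,0.268627,1.000000
0.000000,0.284314,1.000000
0.000000,0.300000,1.000000
0.000000,0.315686,1.000000
0.000000,0.331373,1.000000
0.000000,0.347059,1.000000
0.000000,0.362745,1.000000
0.000000,0.378431,1.000000
0.000000,0.394118,1.000000
0.000000,0.409804,1.000000
0.000000,0.425490,1.000000
0.000000,0.441176,1.000000
0.000000,0.456863,1.000000
0.000000,0.472549,1.000000
0.000000,0.488235,1.000000
0.000000,0.503922,1.000000
0.000000,0.519608,1.000000
0.000000,0.535294,1.000000
0.000000,0.550980,1.000000
0.000000,0.566667,1.000000
0.000000,0.582353,1.000000
0.000000,0.598039,1.000000
0.000000,0.613725,1.000000
0.000000,0.629412,1.000000
0.000000,0.645098,1.000000
0.000000,0.660784,1.000000
0.000000,0.676471,1.000000
0.000000,0.692157,1.000000
0.000000,0.707843,1.000000
0.000000,0.723529,1.000000
0.000000,0.739216,1.000000
0.000000,0.754902,1.000000
0.000000,0.770588,1.000000
0.000000,0.786275,1.000000
0.000000,0.801961,1.000000
0.000000,0.817647,1.000000
0.000000,0.833333,1.000000
0.000000,0.849020,1.000000
0.000000,0.864706,1.000000
0.000000,0.880392,1.000000
0.000000,0.896078,1.000000
0.000000,0.911765,1.000000
0.000000,0.927451,1.000000
0.000000,0.943137,1.000000
0.000000,0.958824,1.000000
0.000000,0.974510,1.000000
0.000000,0.990196,1.000000
0.005882,1.000000,0.994118
0.021569,1.000000,0.978431
0.037255,1.000000,0.962745
0.052941,1.000000,0.947059
0.068627,1.000000,0.931373
0.084314,1.000000,0.915686
0.100000,1.000000,0.900000
0.115686,1.000000,0.884314
0.131373,1.000000,0.868627
0.147059,1.000000,0.852941
0.162745,1.000000,0.837255
0.178431,1.000000,0.821569
0.194118,1.000000,0.805882
0.209804,1.000000,0.790196
0.225490,1.000000,0.774510
0.241176,1.000000,0.758824
0.256863,1.000000,0.743137
0.272549,1.000000,0.727451
0.288235,1.000000,0.711765
0.303922,1.000000,0.696078
0.319608,1.000000,0.680392
0.335294,1.000000,0.664706
0.350980,1.000000,0.649020
0.366667,1.000000,0.633333
0.382353,1.000000,0.617647
0.398039,1.000000,0.601961
0.413725,1.000000,0.586275
0.429412,1.000000,0.570588
0.445098,1.000000,0.554902
0.460784,1.000000,0.539216
0.476471,1.000000,0.523529
0.492157,1.000000,0.507843
0.507843,1.000000,0.492157
0.523529,1.000000,0.476471
0.539216,1.000000,0.460784
0.554902,1.000000,0.445098
0.570588,1.000000,0.429412
0.586275,1.000000,0.413725
0.601961,1.000000,0.398039
0.617647,1.000000,0.382353
0.633333,1.000000,0.366667
0.649020,1.000000,0.350980
0.664706,1.000000,0.335294
0.680392,1.000000,0.319608
0.696078,1.000000,0.303922
0.711765,1.000000,0.288235
0.727451,1.000000,0.272549
0.743137,1.000000,0.256863
0.758824,1.000000,0.241176
0.774510,1.000000,0.225490
0.790196,1.000000,0.209804
0.805882,1.000000,0.194118
0.821569,1.000000,0.178431
0.837255,1.000000,0.162745
0.852941,1.000000,0.147059
0.868627,1.000000,0.131373
0.884314,1.000000,0.115686
0.900000,1.000000,0.100000
0.915686,1.000000,0.084314
0.931373,1.000000,0.068627
0.947059,1.000000,0.052941
0.962745,1.000000,0.037255
0.978431,1.000000,0.021569
0.994118,1.000000,0.005882
1.000000,0.990196,0.000000
1.000000,0.974510,0.000000
1.000000,0.958824,0.000000
1.000000,0.943137,0.000000
1.000000,0.927451,0.000000
1.000000,0.911765,0.000000
1.000000,0.896078,0.000000
1.000000,0.880392,0.000000
1.000000,0.864706,0.000000
1.000000,0.849020,0.000000
1.000000,0.833333,0.000000
1.000000,0.817647,0.000000
1.000000,0.801961,0.000000
1.000000,0.786275,0.000000
1.000000,0.770588,0.000000
1.000000,0.754902,0.000000
1.000000,0.739216,0.000000
1.000000,0.723529,0.000000
1.000000,0.707843,0.000000
1.000000,0.692157,0.000000
1.000000,0.676471,0.000000
1.000000,0.660784,0.000000
1.000000,0.645098,0.000000
1.000000,0.629412,0.000000
1.000000,0.613725,0.000000
1.000000,0.598039,0.000000
1.000000,0.582353,0.000000
1.000000,0.566667,0.000000
1.000000,0.550980,0.000000
1.000000,0.535294,0.000000
1.000000,0.519608,0.000000
1.000000,0.503922,0.000000
1.000000,0.488235,0.000000
1.000000,0.472549,0.000000
1.000000,0.456863,0.000000
1.000000,0.441176,0.000000
1.000000,0.425490,0.000000
1.000000,0.409804,0.000000
1.000000,0.394118,0.000000
1.000000,0.378431,0.000000
1.000000,0.362745,0.000000
1.000000,0.347059,0.000000
1.000000,0.331373,0.000000
1.000000,0.315686,0.000000
1.000000,0.300000,0.000000
1.000000,0.284314,0.000000
1.000000,0.268627,0.000000
1.000000,0.252941,0.000000
1.000000,0.237255,0.000000
1.000000,0.221569,0.000000
1.000000,0.205882,0.000000
1.000000,0.190196,0.000000
1.000000,0.174510,0.000000
1.000000,0.158824,0.000000
1.000000,0.143137,0.000000
1.000000,0.127451,0.000000
1.000000,0.111765,0.000000
1.000000,0.096078,0.000000
1.000000,0.080392,0.000000
1.000000,0.064706,0.000000
1.000000,0.049020,0.000000
1.000000,0.033333,0.000000
1.000000,0.017647,0.000000
1.000000,0.001961,0.000000
0.986275,0.000000,0.000000
0.970588,0.000000,0.000000
0.954902,0.000000,0.000000
0.939216,0.000000,0.000000
0.923529,0.000000,0.000000
0.907843,0.000000,0.000000
0.892157,0.000000,0.000000
0.876471,0.000000,0.000000
0.860784,0.000000,0.000000
0.845098,0.000000,0.000000
0.829412,0.000000,0.000000
0.813725,0.000000,0.000000
0.798039,0.000000,0.000000
0.782353,0.000000,0.000000
0.766667,0.000000,0.000000
0.750980,0.000000,0.000000
0.735294,0.000000,0.000000
0.719608,0.000000,0.000000
0.703922,0.000000,0.000000
0.688235,0.000000,0.000000
0.672549,0.000000,0.000000
0.656863,0.000000,0.000000
0.641176,0.000000,0.000000
0.625490,0.000000,0.000000
0.609804,0.000000,0.000000
0.594118,0.000000,0.000000
0.578431,0.000000,0.000000
0.562745,0.000000,0.000000
0.547059,0.000000,0.000000
0.531373,0.000000,0.000000
0.515686,0.000000,0.000000
0.500000,0.000000,0.000000
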