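"set","y","x","z"
1,1,2.287,0.06
1,0,-1.197,0.131
1,0,-0.694,0.942
2,1,-0.412,0.725
2,0,-0.971,0.754
2,0,-0.947,0.454
3,1,0.748,0.43
3,0,-0.117,0.709
3,0,0.153,0.767
4,1,2.19,0.28
4,0,0.357,0.937
4,0,2.717,0.048
5,1,2.281,0.694
5,0,0.324,0.728
5,0,1.896,0.513
6,1,0.468,0.339
6,0,-0.894,0.071
6,0,-0.307,0.676
7,1,-0.005,0.846
7,0,0.988,0.425
7,0,0.84,0.276
8,1,0.705,0.186
8,0,1.306,0.792
8,0,-1.388,0.293
9,1,1.273,0.807
9,0,0.184,0.304
9,0,0.752,0.644
10,1,0.592,0.544
10,0,-0.983,0.872
10,0,-0.276,0.507
11,1,-0.871,0.224
11,0,0.719,0.708
11,0,0.111,0.672
12,1,-0.078,0.395
12,0,-0.42,0.82
12,0,-0.562,0.932
13,1,0.998,0.606
13,0,-1.105,0.41
13,0,-0.142,0.843
14,1,0.315,0.358
14,0,1.219,0.072
14,0,-0.699,0.837
15,1,-0.285,0.191
15,0,-1.312,0.417
15,0,-0.391,0.566
16,1,-0.402,0.051
16,0,1.351,0.582
16,0,0.591,0.174
17,1,0.101,0.685
17,0,0.931,0.279
17,0,-0.263,0.471
18,1,-0.008,0.476
18,0,0.367,0.187
18,0,1.707,0.346
19,1,0.724,0.686
19,0,0.481,0.724
19,0,-1.568,0.633
20,1,0.318,0.049
20,0,0.166,0.136
20,0,-0.9,0.56
21,1,0.076,0.361
21,0,0.159,0.649
21,0,0.544,0.864
22,1,0.705,0.336
22,0,0.319,0.182
22,0,1.109,0.154
23,1,0.769,0.418
23,0,1.153,0.289
23,0,1.261,0.751
24,1,0.701,0.557
24,0,0.433,0.212
24,0,-0.923,0.828
25,1,-0.616,0.056
25,0,-0.867,0.824
25,0,-1.64,0.881
26,1,-1.326,0.813
26,0,-0.889,0.889
26,0,-0.558,0.427
27,1,-0.062,0.496
27,0,2.423,0.812
27,0,0.343,0.635
28,1,0.004,0.966
28,0,0.029,0.538
28,0,-0.393,0.168
29,1,-0.793,0.503
29,0,-0.312,0.944
29,0,-0.346,0.771
30,1,-0.305,0.615
30,0,-1.786,0.851
30,0,0.587,0.32
31,1,1.636,0.375
31,0,-0.645,0.922
31,0,0.619,0.627
32,1,0.236,0.629
32,0,0.847,0.753
32,0,-0.574,0.389
33,1,1.118,0.626
33,0,-1.54,0.251
33,0,-0.438,0.028
34,1,-0.151,0.324
34,0,0.519,0.01
34,0,0.588,0.438
35,1,-0.079,0.685
35,0,-1.174,0.187
35,0,0.309,0.881
36,1,-1.604,0.472
36,0,0.991,0.098
36,0,1.023,0.394
37,1,0.84,0.731
37,0,0.12,0.687
37,0,-0.426,0.601
38,1,0.459,0.357
38,0,0.645,0.767
38,0,0.612,0.052
39,1,-0.889,0.907
39,0,1.544,0.343
39,0,-1.242,0.558
40,1,1.103,0.436
40,0,0.983,0.275
40,0,0.304,0.117
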