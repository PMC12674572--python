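location,category,metric,mean,sd
thigh,lying,MAI,6,31
thigh,lying,ENMO,11,13
thigh,lying,MAD,2,11
thigh,lying,CPM,59,703
thigh,sitting,MAI,9,20
thigh,sitting,ENMO,7,7
thigh,sitting,MAD,4,8
thigh,sitting,CPM,26,321
thigh,standing,MAI,56,64
thigh,standing,ENMO,12,14
thigh,standing,MAD,13,17
thigh,standing,CPM,404,892
thigh,adl,MAI,132,131
thigh,adl,ENMO,35,50
thigh,adl,MAD,48,59
thigh,adl,CPM,1812,2230
thigh,climbing_stairs,MAI,467,157
thigh,climbing_stairs,ENMO,208,107
thigh,climbing_stairs,MAD,308,98
thigh,climbing_stairs,CPM,6119,2076
thigh,walking,MAI,466,182
thigh,walking,ENMO,228,141
thigh,walking,MAD,293,159
thigh,walking,CPM,4740,1529
thigh,jogging,MAI,1295,326
thigh,jogging,ENMO,936,362
thigh,jogging,MAD,839,242
thigh,jogging,CPM,12986,3992
thigh,cycling,MAI,259,107
thigh,cycling,ENMO,99,65
thigh,cycling,MAD,158,82
thigh,cycling,CPM,5634,2961
hip,lying,MAI,6,23
hip,lying,ENMO,8,8
hip,lying,MAD,2,8
hip,lying,CPM,41,542
hip,sitting,MAI,8,13
hip,sitting,ENMO,13,7
hip,sitting,MAD,3,3
hip,sitting,CPM,12,202
hip,standing,MAI,51,60
hip,standing,ENMO,21,18
hip,standing,MAD,18,24
hip,standing,CPM,271,672
hip,adl,MAI,103,94
hip,adl,ENMO,32,28
hip,adl,MAD,39,42
hip,adl,CPM,1365,2022
hip,climbing_stairs,MAI,353,136
hip,climbing_stairs,ENMO,145,78
hip,climbing_stairs,MAD,254,103
hip,climbing_stairs,CPM,4944,1975
hip,walking,MAI,304,104
hip,walking,ENMO,118,53
hip,walking,MAD,193,83
hip,walking,CPM,3200,1263
hip,jogging,MAI,1005,231
hip,jogging,ENMO,519,152
hip,jogging,MAD,745,159
hip,jogging,CPM,8928,2000
hip,cycling,MAI,125,53
hip,cycling,ENMO,51,25
hip,cycling,MAD,69,29
hip,cycling,CPM,1021,1152
chest,lying,MAI,8,26
chest,lying,ENMO,8,8
chest,lying,MAD,4,8
chest,lying,CPM,51,632
chest,sitting,MAI,15,9
chest,sitting,ENMO,19,8
chest,sitting,MAD,7,6
chest,sitting,CPM,32,362
chest,standing,MAI,70,78
chest,standing,ENMO,30,21
chest,standing,MAD,28,33
chest,standing,CPM,560,1308
chest,adl,MAI,119,102
chest,adl,ENMO,34,25
chest,adl,MAD,42,38
chest,adl,CPM,1945,2930
chest,climbing_stairs,MAI,332,127
chest,climbing_stairs,ENMO,146,76
chest,climbing_stairs,MAD,259,102
chest,climbing_stairs,CPM,5242,2152
chest,walking,MAI,248,92
chest,walking,ENMO,105,45
chest,walking,MAD,174,73
chest,walking,CPM,2787,1569
chest,jogging,MAI,983,242
chest,jogging,ENMO,501,150
chest,jogging,MAD,794,191
chest,jogging,CPM,10301,2331
chest,cycling,MAI,113,53
chest,cycling,ENMO,50,24
chest,cycling,MAD,66,28
chest,cycling,CPM,441,774
ankle,lying,MAI,6,34
ankle,lying,ENMO,12,17
ankle,lying,MAD,3,15
ankle,lying,CPM,67,679
ankle,sitting,MAI,10,31
ankle,sitting,ENMO,6,12
ankle,sitting,MAD,4,12
ankle,sitting,CPM,49,515
ankle,standing,MAI,31,39
ankle,standing,ENMO,9,13
ankle,standing,MAD,9,13
ankle,standing,CPM,204,649
ankle,adl,MAI,150,176
ankle,adl,ENMO,63,108
ankle,adl,MAD,80,113
ankle,adl,CPM,2229,3121
ankle,climbing_stairs,MAI,678,245
ankle,climbing_stairs,ENMO,420,217
ankle,climbing_stairs,MAD,525,150
ankle,climbing_stairs,CPM,11479,3768
ankle,walking,MAI,626,219
ankle,walking,ENMO,446,212
ankle,walking,MAD,511,194
ankle,walking,CPM,10062,4029
ankle,jogging,MAI,1438,351
ankle,jogging,ENMO,1330,484
ankle,jogging,MAD,1082,238
ankle,jogging,CPM,28539,7072
ankle,cycling,MAI,387,208
ankle,cycling,ENMO,175,123
ankle,cycling,MAD,258,136
ankle,cycling,CPM,9728,6037
wrist,lying,MAI,11,55
wrist,lying,ENMO,9,17
wrist,lying,MAD,4,17
wrist,lying,CPM,158,1318
wrist,sitting,MAI,44,85
wrist,sitting,ENMO,10,19
wrist,sitting,MAD,14,24
wrist,sitting,CPM,607,2112
wrist,standing,MAI,336,481
wrist,standing,ENMO,164,291
wrist,standing,MAD,200,300
wrist,standing,CPM,6382,9775
wrist,adl,MAI,339,273
wrist,adl,ENMO,99,118
wrist,adl,MAD,142,120
wrist,adl,CPM,7292,6912
wrist,climbing_stairs,MAI,398,172
wrist,climbing_stairs,ENMO,160,93
wrist,climbing_stairs,MAD,253,103
wrist,climbing_stairs,CPM,7469,3849
wrist,walking,MAI,286,151
wrist,walking,ENMO,138,103
wrist,walking,MAD,171,76
wrist,walking,CPM,4983,4111
wrist,jogging,MAI,1479,556
wrist,jogging,ENMO,841,358
wrist,jogging,MAD,891,332
wrist,jogging,CPM,22902,8436
wrist,cycling,MAI,167,100
wrist,cycling,ENMO,80,52
wrist,cycling,MAD,106,46
wrist,cycling,CPM,1435,2426
upper_arm,lying,MAI,9,40
upper_arm,lying,ENMO,10,14
upper_arm,lying,MAD,3,12
upper_arm,lying,CPM,101,952
upper_arm,sitting,MAI,24,38
upper_arm,sitting,ENMO,9,10
upper_arm,sitting,MAD,9,11
upper_arm,sitting,CPM,143,750
upper_arm,standing,MAI,179,251
upper_arm,standing,ENMO,73,130
upper_arm,standing,MAD,94,148
upper_arm,standing,CPM,2312,3761
upper_arm,adl,MAI,210,161
upper_arm,adl,ENMO,55,58
upper_arm,adl,MAD,80,67
upper_arm,adl,CPM,3914,4085
upper_arm,climbing_stairs,MAI,370,142
upper_arm,climbing_stairs,ENMO,143,82
upper_arm,climbing_stairs,MAD,247,104
upper_arm,climbing_stairs,CPM,6206,2441
upper_arm,walking,MAI,249,85
upper_arm,walking,ENMO,91,43
upper_arm,walking,MAD,149,56
upper_arm,walking,CPM,3098,1872
upper_arm,jogging,MAI,1212,400
upper_arm,jogging,ENMO,652,276
upper_arm,jogging,MAD,724,224
upper_arm,jogging,CPM,17765,6689
upper_arm,cycling,MAI,196,69
upper_arm,cycling,ENMO,74,34
upper_arm,cycling,MAD,108,36
upper_arm,cycling,CPM,1796,1741
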